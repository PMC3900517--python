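"""Parameter sweeps and the headline decoder comparison.

Each experiment emits a tidy table (pandas DataFrame).  Within an
experiment every decoder sees the identical seed resamples and train/test
partitions, so comparisons across decoders are paired.  Exogenous
(stimulus-position) decoding trains at the 125 ms visual response peak,
endogenous (attention-position) decoding at the 245 ms attention peak.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from popdecode.classifiers import DecoderSpec
from popdecode.evaluate import (
    aggregate_seeds,
    decode_timecourse,
    permutation_null,
    randomize_labels,
    run_decoding,
)
from popdecode.preprocess import impose_imbalance, make_seeds, select_cells, subsample_cells
from popdecode.rng import child_seed, substream
from popdecode.synth import SpikeDataset

T_TRAIN_MS = {"exogenous": 125, "endogenous": 245}

DEFAULT_SIZE_GRID = (4, 9, 16, 25, 50, 75, 100, 131)
DEFAULT_TRIAL_GRID = (10, 20, 30, 40, 60, 84)
DEFAULT_IMBALANCE_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)

#: sweep defaults exclude the non-linear network estimator, whose training
#: cost is orders of magnitude above the others for no performance benefit.
DEFAULT_SWEEP_KINDS = ("svm", "reservoir", "r_ole", "bayes", "ann_ole")


def default_specs(kinds=DEFAULT_SWEEP_KINDS, rng_seed: int = 0, **param_overrides):
    """One DecoderSpec per kind, sharing an rng seed."""
    return [
        DecoderSpec(kind, params=dict(param_overrides.get(kind, {})), rng_seed=rng_seed)
        for kind in kinds
    ]


def restrict_dataset(dataset: SpikeDataset, cell_ids) -> SpikeDataset:
    """A dataset containing only the given cells (ids re-enumerated)."""
    cell_ids = np.asarray(cell_ids, dtype=int)
    cells = [
        replace(dataset.cells[i], cell_id=k) for k, i in enumerate(cell_ids)
    ]
    return SpikeDataset(
        cells,
        [dataset.spikes[i] for i in cell_ids],
        [dataset.labels[i] for i in cell_ids],
        dataset.trial_duration,
    )


def _subset_ids(dataset: SpikeDataset, cell_subset, rng) -> np.ndarray | None:
    """Resolve a cell-subset request to explicit ids (None = all cells)."""
    if cell_subset in (None, "all"):
        return None
    if cell_subset == "selective":
        return dataset.selective_cells("attention")
    if isinstance(cell_subset, tuple) and cell_subset[0] == "random":
        k = int(cell_subset[1])
        return np.sort(rng.choice(dataset.n_cells, size=k, replace=False))
    return np.asarray(cell_subset, dtype=int)


def compare_decoders(
    dataset: SpikeDataset,
    specs: list[DecoderSpec],
    variable: str,
    cell_subset="all",
    master_seed: int = 0,
    n_seeds: int = 20,
    n_perm: int = 50,
    n_target: int = 60,
) -> pd.DataFrame:
    """Absolute and relative readout performance per decoder.

    Returns one row per decoder with the across-seed mean and s.e. of the
    absolute performance, the decoder-specific permutation 95% upper
    limit, the relative performance (absolute - upper95), and the
    significance flag.
    """
    t_train = T_TRAIN_MS[variable]
    ids = _subset_ids(dataset, cell_subset, substream(master_seed, "cell-subset"))
    data = dataset if ids is None else restrict_dataset(dataset, ids)
    seeds = make_seeds(
        data, child_seed(master_seed, f"seeds-{variable}"), n_seeds=n_seeds,
        n_target=n_target,
    )
    rows = []
    for spec in specs:
        results = [run_decoding(s, spec, t_train) for s in seeds]
        mean, se = aggregate_seeds(results)
        null = permutation_null(
            data, spec, t_train,
            substream(master_seed, f"null-{variable}-{spec.kind}"),
            n_perm=n_perm, n_seeds=n_seeds, n_target=n_target,
        )
        rows.append(
            dict(
                decoder=spec.kind,
                variable=variable,
                mean_pct=mean,
                se_pct=se,
                upper95_pct=null.upper95,
                relative_pct=mean - null.upper95,
                significant=mean > null.upper95,
                n_seeds=n_seeds,
            )
        )
    return pd.DataFrame(rows)


def per_seed_table(
    dataset: SpikeDataset,
    specs: list[DecoderSpec],
    variable: str,
    master_seed: int = 0,
    n_seeds: int = 20,
    n_target: int = 60,
) -> pd.DataFrame:
    """Per-seed paired performances (one row per decoder x seed).

    Decoders share the identical seeds, so rows pair by ``seed_id``; feed
    pairs of columns to :func:`popdecode.evaluate.paired_permutation_test`
    for across-decoder inference.
    """
    t_train = T_TRAIN_MS[variable]
    seeds = make_seeds(
        dataset, child_seed(master_seed, f"seeds-{variable}"), n_seeds=n_seeds,
        n_target=n_target,
    )
    rows = [
        dict(decoder=spec.kind, seed_id=s.seed_id,
             performance_pct=run_decoding(s, spec, t_train).percent)
        for spec in specs
        for s in seeds
    ]
    return pd.DataFrame(rows)


def pairwise_tests(
    table: pd.DataFrame, rng: np.random.Generator, n_perm: int = 10_000
) -> pd.DataFrame:
    """Paired permutation test for every decoder pair in a per-seed table."""
    from popdecode.evaluate import paired_permutation_test

    wide = table.pivot(index="seed_id", columns="decoder",
                       values="performance_pct")
    rows = []
    decoders = list(wide.columns)
    for i, a in enumerate(decoders):
        for b in decoders[i + 1 :]:
            rows.append(
                dict(
                    decoder_a=a, decoder_b=b,
                    mean_diff_pct=float((wide[a] - wide[b]).mean()),
                    p_value=paired_permutation_test(wide[a], wide[b], rng, n_perm),
                )
            )
    return pd.DataFrame(rows)


def sweep_population_size(
    dataset: SpikeDataset,
    spec: DecoderSpec,
    sizes=DEFAULT_SIZE_GRID,
    master_seed: int = 0,
    n_draws: int = 20,
    n_seeds: int = 20,
    n_perm: int = 10,
    variable: str = "endogenous",
    n_target: int = 60,
) -> pd.DataFrame:
    """Readout performance as a function of population size.

    Per size, ``n_draws`` random cell subsets are decoded on the shared
    seeds; the chance level per size comes from a permutation null on one
    random subset of that size.
    """
    t_train = T_TRAIN_MS[variable]
    seeds = make_seeds(
        dataset, child_seed(master_seed, f"seeds-{variable}"), n_seeds=n_seeds,
        n_target=n_target,
    )
    draw_rng = substream(master_seed, "size-draws")
    null_rng = substream(master_seed, "size-nulls")
    rows = []
    for size in sizes:
        perfs = []
        for _ in range(n_draws):
            sub_seeds = [subsample_cells(s, size, draw_rng) for s in seeds]
            perfs.extend(run_decoding(s, spec, t_train).percent for s in sub_seeds)
        mean, se = aggregate_seeds(perfs)
        null_ids = np.sort(null_rng.choice(dataset.n_cells, size=size, replace=False))
        null = permutation_null(
            restrict_dataset(dataset, null_ids), spec, t_train, null_rng,
            n_perm=n_perm, n_seeds=n_seeds, n_target=n_target,
        )
        rows.append(
            dict(
                size=size, mean_pct=mean, se_pct=se, upper95_pct=null.upper95,
                significant=mean > null.upper95,
            )
        )
    return pd.DataFrame(rows)


def _reduced_train(seed, k: int, rng) -> object:
    """Shuffle the train partition and keep its first k trials."""
    shuffled = rng.permutation(seed.train_idx)
    return seed.with_train_idx(np.sort(shuffled[:k]))


def sweep_trial_number(
    dataset: SpikeDataset,
    spec: DecoderSpec,
    train_sizes=DEFAULT_TRIAL_GRID,
    master_seed: int = 0,
    n_seeds: int = 20,
    n_perm: int = 10,
    variable: str = "endogenous",
    n_target: int = 60,
) -> pd.DataFrame:
    """Readout performance as a function of available training trials.

    The test partition stays fixed; training uses the first k trials of
    the shuffled train partition.
    """
    t_train = T_TRAIN_MS[variable]
    seeds = make_seeds(
        dataset, child_seed(master_seed, f"seeds-{variable}"), n_seeds=n_seeds,
        n_target=n_target,
    )
    rng = substream(master_seed, "trial-sweep")
    rows = []
    for k in train_sizes:
        perfs = [
            run_decoding(_reduced_train(s, k, rng), spec, t_train).percent
            for s in seeds
        ]
        mean, se = aggregate_seeds(perfs)
        rows.append(dict(n_train=k, mean_pct=mean, se_pct=se))
    return pd.DataFrame(rows)


def sweep_joint(
    dataset: SpikeDataset,
    spec: DecoderSpec,
    size_grid=DEFAULT_SIZE_GRID,
    trial_grid=DEFAULT_TRIAL_GRID,
    master_seed: int = 0,
    n_seeds: int = 10,
    n_perm: int = 5,
    n_draws: int = 1,
    variable: str = "endogenous",
    n_target: int = 60,
    with_nulls: bool = True,
) -> dict:
    """Performance over the population-size x training-trials grid.

    Returns the raw performance matrix, the per-cell permutation upper95
    matrix (when ``with_nulls``), and a tidy long-format table.  Display
    smoothing is available separately via :func:`smooth_matrix`; the raw
    matrix is always the contract.
    """
    t_train = T_TRAIN_MS[variable]
    seeds = make_seeds(
        dataset, child_seed(master_seed, f"seeds-{variable}"), n_seeds=n_seeds,
        n_target=n_target,
    )
    draw_rng = substream(master_seed, "joint-draws")
    null_rng = substream(master_seed, "joint-nulls")
    perf = np.zeros((len(size_grid), len(trial_grid)))
    upper = np.full_like(perf, np.nan)
    rows = []
    for a, size in enumerate(size_grid):
        for b, k in enumerate(trial_grid):
            perfs = []
            for _ in range(n_draws):
                for s in seeds:
                    s2 = _reduced_train(subsample_cells(s, size, draw_rng), k, draw_rng)
                    perfs.append(run_decoding(s2, spec, t_train).percent)
            perf[a, b] = np.mean(perfs)
            if with_nulls:
                ids = np.sort(null_rng.choice(dataset.n_cells, size=size, replace=False))
                null = permutation_null(
                    restrict_dataset(dataset, ids), spec, t_train, null_rng,
                    n_perm=n_perm, n_seeds=max(2, n_seeds // 2), n_target=n_target,
                )
                upper[a, b] = null.upper95
            rows.append(dict(size=size, n_train=k, mean_pct=perf[a, b],
                             upper95_pct=upper[a, b]))
    return dict(
        performance=perf, upper95=upper, table=pd.DataFrame(rows),
        size_grid=tuple(size_grid), trial_grid=tuple(trial_grid),
    )


def smooth_matrix(matrix: np.ndarray, sigma: float = 7.0) -> np.ndarray:
    """Gaussian display smoothing (reflective edges; raw data untouched)."""
    return gaussian_filter(np.asarray(matrix, dtype=float), sigma=sigma, mode="nearest")


def sweep_imbalance(
    dataset: SpikeDataset,
    specs: list[DecoderSpec],
    imbalance_grid=DEFAULT_IMBALANCE_GRID,
    master_seed: int = 0,
    n_seeds: int = 20,
    variable: str = "endogenous",
    n_target: int = 60,
) -> pd.DataFrame:
    """Performance drop (balanced minus unbalanced) per decoder and level.

    The same reduced train partitions are shared across decoders at each
    imbalance level; the drop is aggregated over per-seed paired
    differences.
    """
    t_train = T_TRAIN_MS[variable]
    seeds = make_seeds(
        dataset, child_seed(master_seed, f"seeds-{variable}"), n_seeds=n_seeds,
        n_target=n_target,
    )
    rows = []
    for frac in imbalance_grid:
        rng = substream(master_seed, f"imbalance-{frac}")
        reduced = [impose_imbalance(s, frac, rng) for s in seeds]
        for spec in specs:
            balanced = np.array(
                [run_decoding(s, spec, t_train).percent for s in seeds]
            )
            unbalanced = np.array(
                [run_decoding(s, spec, t_train).percent for s in reduced]
            )
            drops = balanced - unbalanced
            rows.append(
                dict(
                    decoder=spec.kind,
                    imbalance=frac,
                    drop_pct=float(drops.mean()),
                    drop_se_pct=float(
                        drops.std(ddof=1) / np.sqrt(len(drops)) if len(drops) > 1 else 0.0
                    ),
                    balanced_pct=float(balanced.mean()),
                    unbalanced_pct=float(unbalanced.mean()),
                )
            )
    return pd.DataFrame(rows)


def memory_analysis(
    dataset: SpikeDataset,
    narrow_spec: DecoderSpec | None = None,
    wide_spec: DecoderSpec | None = None,
    master_seed: int = 0,
    n_seeds: int = 20,
    n_perm: int = 5,
    t_train: int = T_TRAIN_MS["endogenous"],
    times: tuple[int, int] = (70, 500),
    n_target: int = 60,
) -> pd.DataFrame:
    """Sustained decoding with a wide-window memory reservoir.

    Compares the static reservoir trained on its 75 ms window around
    ``t_train`` (narrow) with the leaky tanh reservoir trained on the
    whole 70-500 ms post-cue window (wide).  Performance is the exact
    per-time-point fraction correct — no 100 ms averaging — with a
    per-time-point permutation significance trace.
    """
    narrow_spec = narrow_spec or DecoderSpec("reservoir")
    wide_spec = wide_spec or DecoderSpec("reservoir_memory")
    tt = np.arange(times[0], times[1] + 1)
    seeds = make_seeds(
        dataset, child_seed(master_seed, "seeds-memory"), n_seeds=n_seeds,
        n_target=n_target,
    )
    frames = []
    for label, spec in (("narrow", narrow_spec), ("wide", wide_spec)):
        curves = np.stack(
            [decode_timecourse(s, spec, t_train, tt) for s in seeds]
        ) * 100.0
        null_rng = substream(master_seed, f"memory-null-{label}")
        null_points = []
        for _ in range(n_perm):
            shuffled = randomize_labels(dataset, null_rng)
            master = int(null_rng.integers(2**31 - 1))
            for s in make_seeds(shuffled, master, n_seeds=max(2, n_seeds // 4),
                                n_target=n_target):
                null_points.append(decode_timecourse(s, spec, t_train, tt) * 100.0)
        upper95 = np.percentile(np.stack(null_points), 95, axis=0)
        mean = curves.mean(axis=0)
        se = (
            curves.std(axis=0, ddof=1) / np.sqrt(len(seeds))
            if len(seeds) > 1
            else np.zeros_like(mean)
        )
        frames.append(
            pd.DataFrame(
                dict(
                    time_ms=tt, variant=label, mean_pct=mean, se_pct=se,
                    upper95_pct=upper95, significant=mean > upper95,
                )
            )
        )
    return pd.concat(frames, ignore_index=True)
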