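"""Cross-validated decoding runs, window-averaged performance, and
permutation-test chance levels.

A decoding run trains once on a seed's 84 training trials at the training
reference time (the reservoir variants on their training window) and tests
the 36 held-out trials at each of the 100 one-ms-stepped time points in the
100 ms window around the reference; readout performance is the fraction
correct averaged over those 100 test windows.

The chance level is decoder-specific: condition labels are redrawn per
cell (sampling with replacement) before seed construction, the full
pipeline is re-run, and the 95th percentile of the resulting chance
distribution (50 permutations x 20 seeds = 1000 points at production
scale) is the significance boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from popdecode.classifiers import DecoderSpec, sign_pm, train_decoder
from popdecode.preprocess import SeedDataset, make_seeds
from popdecode.synth import SpikeDataset

TEST_HALFWIDTH_MS = 50
N_PERMUTATIONS = 50


@dataclass
class DecodingResult:
    """Readout performance of one decoder on one seed."""

    kind: str
    seed_id: int
    performance: float  # fraction correct in [0, 1]
    n_test: int
    per_time: np.ndarray | None = None  # fraction correct per test window

    @property
    def percent(self) -> float:
        return 100.0 * self.performance


@dataclass
class NullDistribution:
    """Decoder-specific chance-performance distribution (percent scale)."""

    points: np.ndarray
    upper95: float

    @classmethod
    def from_points(cls, points: np.ndarray) -> "NullDistribution":
        points = np.asarray(points, dtype=float)
        # linear-interpolation (type-7) empirical quantile
        return cls(points, float(np.percentile(points, 95)))


def _decoder_rng(spec: DecoderSpec, seed_id: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(spec.rng_seed, spawn_key=(1_000 + seed_id,))
    )


def _test_values(decoder, spec: DecoderSpec, seed: SeedDataset, times: np.ndarray) -> np.ndarray:
    """Decision values for the test partition, (n_test, len(times))."""
    if spec.is_time_resolved:
        traces = seed.X_window(0, seed.duration, seed.test_idx)
        return decoder.decision_over_time(traces, times)
    X = seed.X_window(times[0], times[-1] + 1, seed.test_idx)
    n, m, L = X.shape
    values = decoder.decision_values(X.reshape(n, m * L))
    return values.reshape(m, L)


def run_decoding(
    seed: SeedDataset,
    spec: DecoderSpec,
    t_train: int,
    test_halfwidth: int = TEST_HALFWIDTH_MS,
) -> DecodingResult:
    """One train/test run; performance averaged over the test windows.

    The test windows are t_train - halfwidth .. t_train + halfwidth - 1
    inclusive (100 points at the default halfwidth of 50 ms); a halfwidth
    of 0 degenerates to plain test accuracy at ``t_train``.
    """
    if test_halfwidth > 0:
        times = np.arange(t_train - test_halfwidth, t_train + test_halfwidth)
    else:
        times = np.array([t_train])
    if times[0] < 0 or times[-1] >= seed.duration:
        raise ValueError("test window exceeds trial bounds")
    decoder = train_decoder(spec, seed, t_train, rng=_decoder_rng(spec, seed.seed_id))
    values = _test_values(decoder, spec, seed, times)
    y_test = seed.y[seed.test_idx]
    correct = sign_pm(values) == y_test[:, None]
    per_time = correct.mean(axis=0)
    return DecodingResult(
        kind=spec.kind,
        seed_id=seed.seed_id,
        performance=float(per_time.mean()),
        n_test=y_test.size,
        per_time=per_time,
    )


def decode_timecourse(
    seed: SeedDataset, spec: DecoderSpec, t_train: int, times: np.ndarray
) -> np.ndarray:
    """Per-time-point fraction correct (no window averaging)."""
    times = np.asarray(times)
    decoder = train_decoder(spec, seed, t_train, rng=_decoder_rng(spec, seed.seed_id))
    values = _test_values(decoder, spec, seed, times)
    y_test = seed.y[seed.test_idx]
    return (sign_pm(values) == y_test[:, None]).mean(axis=0)


def aggregate_seeds(performances) -> tuple[float, float]:
    """Across-seed mean and standard error, on the percent scale.

    Accepts DecodingResults or plain percent values.
    """
    vals = np.array(
        [p.percent if isinstance(p, DecodingResult) else float(p) for p in performances]
    )
    if vals.size == 0:
        raise ValueError("no decoding results to aggregate")
    if vals.size == 1:
        return float(vals[0]), 0.0
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(vals.size))


def randomize_labels(
    dataset: SpikeDataset, rng: np.random.Generator
) -> SpikeDataset:
    """Redraw each cell's condition labels with replacement from {-1, +1}."""
    labels = [
        rng.choice(np.array([-1, 1], dtype=np.int8), size=lab.size)
        for lab in dataset.labels
    ]
    return dataset.with_labels(labels)


def permutation_null(
    dataset: SpikeDataset,
    spec: DecoderSpec,
    t_train: int,
    rng: np.random.Generator,
    n_perm: int = N_PERMUTATIONS,
    n_seeds: int = 20,
    n_target: int = 60,
    test_halfwidth: int = TEST_HALFWIDTH_MS,
) -> NullDistribution:
    """Decoder-specific chance distribution via label randomization.

    Per permutation the labels are redrawn per cell (with replacement),
    the seed-construction pipeline is re-run from scratch, and every seed
    is decoded, yielding n_perm * n_seeds chance points.
    """
    points = []
    for _ in range(n_perm):
        shuffled = randomize_labels(dataset, rng)
        master = int(rng.integers(2**31 - 1))
        for seed in make_seeds(shuffled, master, n_seeds=n_seeds, n_target=n_target):
            res = run_decoding(seed, spec, t_train, test_halfwidth)
            points.append(res.percent)
    return NullDistribution.from_points(np.array(points))


def relative_performance(performance_pct: float, null: NullDistribution) -> float:
    """Absolute performance minus the 95% chance upper limit (may be < 0)."""
    return float(performance_pct - null.upper95)


def is_significant(performance_pct: float, null: NullDistribution) -> bool:
    """True when performance exceeds the null's 95th percentile (p < 0.05)."""
    return performance_pct > null.upper95


def paired_permutation_test(
    perf_a,
    perf_b,
    rng: np.random.Generator,
    n_perm: int = 10_000,
) -> float:
    """Two-sided sign-flip permutation p-value for a paired comparison.

    ``perf_a`` and ``perf_b`` are per-seed performances of two decoders on
    the identical seeds; under the null of no difference the sign of each
    per-seed difference is exchangeable.
    """
    d = np.asarray(perf_a, dtype=float) - np.asarray(perf_b, dtype=float)
    if d.size < 2:
        raise ValueError("paired test needs at least two seeds")
    observed = abs(d.mean())
    flips = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
    null = np.abs((flips * d).mean(axis=1))
    return float((np.sum(null >= observed - 1e-12) + 1) / (n_perm + 1))
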