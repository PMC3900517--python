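"""Smoothing, trial balancing and pseudo-population seed construction.

Raw spike trains are smoothed with a 100 ms sliding window (1 ms step);
each cell is brought to exactly 60 trials per condition (random subsample,
or random duplication when fewer are available); single-trial responses are
then combined at random across cells into 60 virtual population responses
per condition.  One such random combination plus its stratified 70/30
train/test partition is a *seed*; the whole procedure is repeated (20 seeds
by default) and the identical seeds are handed to every classifier so the
comparison is paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from popdecode.rng import substream
from popdecode.synth import SpikeDataset

DEFAULT_WINDOW_MS = 100
DEFAULT_N_TARGET = 60
DEFAULT_N_SEEDS = 20
TRAIN_FRACTION = 0.7


def smooth(spike_train: np.ndarray, window_ms: int = DEFAULT_WINDOW_MS) -> np.ndarray:
    """Sliding-window firing rate (spikes/s) at 1 ms resolution.

    The value at t is the mean spike count in the window of ``window_ms``
    samples centred at t (offsets -(w-1)//2 .. +w//2), converted to
    spikes/s.  At the edges the window is truncated to the available
    samples and the mean taken over the shorter window, so a constant
    spike train maps to a constant rate everywhere.
    """
    spike_train = np.asarray(spike_train)
    T = spike_train.shape[-1]
    if window_ms < 1:
        raise ValueError("window_ms must be >= 1")
    if window_ms > T:
        raise ValueError("smoothing window longer than the trial")
    left = (window_ms - 1) // 2
    right = window_ms // 2
    c = np.concatenate(
        [
            np.zeros(spike_train.shape[:-1] + (1,)),
            np.cumsum(spike_train, axis=-1, dtype=float),
        ],
        axis=-1,
    )
    t = np.arange(T)
    lo = np.maximum(0, t - left)
    hi = np.minimum(T, t + right + 1)
    counts = c[..., hi] - c[..., lo]
    lengths = hi - lo
    return counts / lengths * 1000.0


def balance_trials(
    labels: np.ndarray, n_target: int, rng: np.random.Generator, cell_id: int | None = None
) -> dict[int, np.ndarray]:
    """Trial indices giving exactly ``n_target`` trials per condition.

    Conditions with more trials are subsampled without replacement; with
    fewer, every original trial is kept once and the remainder are random
    duplicates (sampled with replacement).  Returns {-1: idx, +1: idx}.
    """
    labels = np.asarray(labels)
    out: dict[int, np.ndarray] = {}
    for cond in (-1, 1):
        idx = np.flatnonzero(labels == cond)
        if idx.size == 0:
            who = f"cell {cell_id}" if cell_id is not None else "a cell"
            raise ValueError(f"{who} has no trials for condition {cond:+d}")
        if idx.size >= n_target:
            chosen = rng.choice(idx, size=n_target, replace=False)
        else:
            extra = rng.choice(idx, size=n_target - idx.size, replace=True)
            chosen = np.concatenate([idx, extra])
        out[cond] = chosen
    return out


@dataclass
class BalancedTraces:
    """Smoothed, per-cell balanced trials, ordered [condition -1 | +1].

    ``traces`` is (n_cells, 2*n_target, T) float32; rows 0..n_target-1 of
    axis 1 are condition -1 trials, the rest condition +1.
    """

    traces: np.ndarray
    n_target: int

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def duration(self) -> int:
        return self.traces.shape[2]


def prepare_traces(
    dataset: SpikeDataset,
    rng: np.random.Generator,
    n_target: int = DEFAULT_N_TARGET,
    window_ms: int = DEFAULT_WINDOW_MS,
) -> BalancedTraces:
    """Smooth every trial and balance each cell to ``n_target``/condition."""
    n_cells = dataset.n_cells
    T = dataset.trial_duration
    traces = np.empty((n_cells, 2 * n_target, T), dtype=np.float32)
    for i in range(n_cells):
        sel = balance_trials(dataset.labels[i], n_target, rng, cell_id=i)
        picked = np.concatenate([sel[-1], sel[1]])
        traces[i] = smooth(dataset.spikes[i][picked], window_ms)
    return BalancedTraces(traces, n_target)


@dataclass
class SeedDataset:
    """One pseudo-population resample with its train/test partition.

    Virtual trial v of a condition takes, for every cell, the smoothed
    trace of one randomly assigned balanced trial of that condition (a
    per-cell permutation: a bijection between balanced trials and virtual
    trials).  The assignment is shared across all time points.  Labels are
    [-1]*n_target + [+1]*n_target; the partition is stratified 70/30.
    """

    seed_id: int
    balanced: BalancedTraces
    assignment: np.ndarray  # (n_cells, 2*n_target) balanced-trial index
    train_idx: np.ndarray
    test_idx: np.ndarray
    cell_idx: np.ndarray = field(default=None)  # view onto a cell subset

    def __post_init__(self) -> None:
        if self.cell_idx is None:
            self.cell_idx = np.arange(self.balanced.n_cells)

    @property
    def n_cells(self) -> int:
        return self.cell_idx.size

    @property
    def n_virtual(self) -> int:
        return self.assignment.shape[1]

    @property
    def y(self) -> np.ndarray:
        n = self.balanced.n_target
        return np.repeat([-1, 1], n)

    @property
    def duration(self) -> int:
        return self.balanced.duration

    def X_at(self, t: int, trials: np.ndarray | None = None) -> np.ndarray:
        """Population response matrix (n_cells, m) at time bin t."""
        if trials is None:
            trials = np.arange(self.n_virtual)
        cells = self.cell_idx
        return self.balanced.traces[
            cells[:, None], self.assignment[np.ix_(cells, trials)], t
        ].astype(float)

    def X_window(
        self, t0: int, t1: int, trials: np.ndarray | None = None
    ) -> np.ndarray:
        """Time-resolved tensor (n_cells, m, t1-t0) over [t0, t1)."""
        if trials is None:
            trials = np.arange(self.n_virtual)
        cells = self.cell_idx
        tt = np.arange(t0, t1)
        return self.balanced.traces[
            cells[:, None, None],
            self.assignment[np.ix_(cells, trials)][:, :, None],
            tt[None, None, :],
        ].astype(float)

    def with_train_idx(self, train_idx: np.ndarray) -> "SeedDataset":
        return SeedDataset(
            self.seed_id, self.balanced, self.assignment,
            np.asarray(train_idx), self.test_idx, self.cell_idx,
        )


def _stratified_partition(
    n_target: int, rng: np.random.Generator, train_fraction: float = TRAIN_FRACTION
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified split of the 2*n_target virtual trials (e.g. 42/42, 18/18)."""
    n_train_per = round(train_fraction * n_target)
    train, test = [], []
    for cond in range(2):
        perm = rng.permutation(n_target) + cond * n_target
        train.append(perm[:n_train_per])
        test.append(perm[n_train_per:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def build_seeds(
    balanced: BalancedTraces,
    rng: np.random.Generator,
    n_seeds: int = DEFAULT_N_SEEDS,
    train_fraction: float = TRAIN_FRACTION,
) -> list[SeedDataset]:
    """Construct ``n_seeds`` independent pseudo-population resamples."""
    n_cells, n_balanced = balanced.traces.shape[:2]
    n_target = balanced.n_target
    seeds = []
    for s in range(n_seeds):
        assignment = np.empty((n_cells, 2 * n_target), dtype=np.int32)
        for i in range(n_cells):
            assignment[i, :n_target] = rng.permutation(n_target)
            assignment[i, n_target:] = n_target + rng.permutation(n_target)
        train_idx, test_idx = _stratified_partition(n_target, rng, train_fraction)
        seeds.append(SeedDataset(s, balanced, assignment, train_idx, test_idx))
    return seeds


def make_seeds(
    dataset: SpikeDataset,
    master_seed: int,
    n_seeds: int = DEFAULT_N_SEEDS,
    n_target: int = DEFAULT_N_TARGET,
    window_ms: int = DEFAULT_WINDOW_MS,
) -> list[SeedDataset]:
    """Full pipeline: smooth, balance, and resample into seeds."""
    balanced = prepare_traces(
        dataset, substream(master_seed, "balance"), n_target, window_ms
    )
    return build_seeds(balanced, substream(master_seed, "seeds"), n_seeds)


def impose_imbalance(
    seed: SeedDataset,
    imbalance: float,
    rng: np.random.Generator,
    reduce_condition: int = 1,
) -> SeedDataset:
    """Drop training trials of one condition to emulate a biased subject.

    Condition ``reduce_condition`` keeps round((1 - imbalance) * n1)
    training trials, n1 being the other condition's count (rounding half
    away from zero); the test partition is untouched.  imbalance = 0.5
    leaves one class with half as many training trials as the other.
    """
    if not 0.0 <= imbalance <= 0.5:
        raise ValueError("imbalance must lie in [0, 0.5]")
    y = seed.y
    train = seed.train_idx
    keep_mask = y[train] != reduce_condition
    kept = train[keep_mask]
    reduced = train[~keep_mask]
    n1 = kept.size
    n2 = int(np.floor((1.0 - imbalance) * n1 + 0.5))
    chosen = rng.choice(reduced, size=n2, replace=False)
    return seed.with_train_idx(np.sort(np.concatenate([kept, chosen])))


def subsample_cells(
    seed: SeedDataset, n_cells_keep: int, rng: np.random.Generator
) -> SeedDataset:
    """Restrict a seed to a random subset of its cells (labels unchanged)."""
    if n_cells_keep > seed.n_cells:
        raise ValueError("cannot keep more cells than available")
    chosen = np.sort(rng.choice(seed.cell_idx, size=n_cells_keep, replace=False))
    return SeedDataset(
        seed.seed_id, seed.balanced, seed.assignment,
        seed.train_idx, seed.test_idx, chosen,
    )


def select_cells(seed: SeedDataset, cell_ids: np.ndarray) -> SeedDataset:
    """Restrict a seed to an explicit list of cell ids."""
    return SeedDataset(
        seed.seed_id, seed.balanced, seed.assignment,
        seed.train_idx, seed.test_idx, np.asarray(cell_ids, dtype=int),
    )
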