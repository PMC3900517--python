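"""Synthetic event-aligned spiking populations with known ground truth.

The generator emulates a heterogeneous prefrontal (frontal eye field-like)
population recorded one cell at a time: most cells respond transiently to a
visual event with a peak around 125 ms, a minority carry an
attention-instruction signal peaking around 245 ms that is partly sustained
afterwards, and the rest are unselective.  Trial-to-trial variability is
independent Poisson per cell — pseudo-populations assembled from
non-simultaneous recordings carry no noise correlations, and neither does
the generator.

Every cell's selectivity is known by construction, so each downstream stage
(smoothing, resampling, decoding, permutation nulls) can be tested against
ground truth without any recorded data.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from popdecode.rng import substream

SelectivityClass = Literal["visual", "attention", "mixed", "none"]

#: canonical response-peak latencies (ms after event onset)
VISUAL_PEAK_MS = 125.0
ATTENTION_PEAK_MS = 245.0


@dataclass(frozen=True)
class CellProfile:
    """Ground-truth response profile of one synthetic cell.

    ``response_width`` is the s.d. (ms) of the Gaussian response transient;
    ``sustain_fraction`` is the fraction of the peak gain maintained after
    the transient (sustained attention signal for the memory analysis).
    ``secondary_latency`` is set for mixed cells, which carry both a visual
    transient and an attention response.
    """

    cell_id: int
    selectivity_class: SelectivityClass
    preferred_condition: int  # -1 or +1
    baseline_rate: float  # spikes/s
    response_gain: float  # spikes/s
    peak_latency: float  # ms
    response_width: float  # ms (Gaussian s.d.)
    sustain_fraction: float = 0.0
    secondary_latency: float | None = None

    def __post_init__(self) -> None:
        if self.preferred_condition not in (-1, 1):
            raise ValueError("preferred_condition must be -1 or +1")
        if self.baseline_rate < 0 or self.response_gain < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.sustain_fraction <= 1.0:
            raise ValueError("sustain_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Population and trial-count structure of a synthetic dataset.

    Defaults emulate a 131-cell population in which 111 cells are visually
    selective and 21 carry the attention instruction (111 + 21 > 131: with
    ``allow_overlap`` one cell belongs to both sets and is generated as a
    mixed cell).  ``n_trials_mean``/``n_trials_sd`` set the per-cell trial
    count per condition; use :meth:`for_variable` for the per-variable
    presets (endogenous: 112 +/- 33 usable trials; exogenous: 295 +/- 107).
    """

    n_cells: int = 131
    fraction_visual: float = 111 / 131
    fraction_attention: float = 21 / 131
    variable: Literal["exogenous", "endogenous"] = "endogenous"
    trial_duration: int = 700  # ms post-event
    n_trials_mean: float = 112.0
    n_trials_sd: float = 33.0
    min_trials: int = 10
    baseline_rate: float = 10.0  # spikes/s
    visual_gain: float = 10.0  # spikes/s
    attention_gain: float = 6.0  # spikes/s
    visual_width: float = 35.0  # ms
    attention_width: float = 50.0  # ms
    visual_sustain: float = 0.0
    attention_sustain: float = 0.5
    max_rate: float = 200.0  # spikes/s cap on baseline + gain
    rate_jitter: float = 0.25  # relative s.d. of per-cell gain/baseline spread
    allow_overlap: bool = True
    noise: Literal["poisson", "none"] = "poisson"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fraction_visual < 0 or self.fraction_attention < 0:
            raise ValueError("fractions must be non-negative")
        n_vis = round(self.n_cells * self.fraction_visual)
        n_att = round(self.n_cells * self.fraction_attention)
        if n_vis + n_att > self.n_cells and not self.allow_overlap:
            raise ValueError(
                "selective fractions exceed the population without overlap"
            )
        if n_vis > self.n_cells or n_att > self.n_cells:
            raise ValueError("a selectivity fraction exceeds 1")

    @classmethod
    def for_variable(
        cls, variable: Literal["exogenous", "endogenous"], **overrides
    ) -> "GeneratorConfig":
        """Preset trial-count statistics for the two decoded variables."""
        if variable == "exogenous":
            base = dict(variable="exogenous", n_trials_mean=295.0, n_trials_sd=107.0)
        elif variable == "endogenous":
            base = dict(variable="endogenous", n_trials_mean=112.0, n_trials_sd=33.0)
        else:
            raise ValueError(f"unknown variable {variable!r}")
        base.update(overrides)
        return cls(**base)


@dataclass
class SpikeDataset:
    """Event-aligned single-trial spike trains for a recorded population.

    ``spikes[i]`` is a (n_trials_i, trial_duration) uint8 raster for cell i
    at 1 ms resolution, t = 0 at event onset; ``labels[i]`` holds the trial
    condition labels in {-1, +1}.  Trial counts may differ across cells
    (cells were not recorded simultaneously).
    """

    cells: list[CellProfile]
    spikes: list[np.ndarray]
    labels: list[np.ndarray]
    trial_duration: int

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_ids_of_class(self, cls_name: SelectivityClass) -> np.ndarray:
        return np.array(
            [c.cell_id for c in self.cells if c.selectivity_class == cls_name],
            dtype=int,
        )

    def selective_cells(self, which: Literal["visual", "attention"]) -> np.ndarray:
        """Indices of cells carrying the given signal (mixed cells included)."""
        return np.array(
            [
                c.cell_id
                for c in self.cells
                if c.selectivity_class in (which, "mixed")
            ],
            dtype=int,
        )

    def with_labels(self, labels: list[np.ndarray]) -> "SpikeDataset":
        return SpikeDataset(self.cells, self.spikes, labels, self.trial_duration)


def assign_cell_classes(config: GeneratorConfig) -> list[CellProfile]:
    """Assign selectivity classes and response parameters to the population.

    Exact counts round(n_cells * fraction) per class; when the visual and
    attention sets overlap (sum of counts exceeds n_cells and overlap is
    allowed) the excess cells are generated as mixed cells carrying both
    signals.  Preferred conditions alternate within each class so both
    conditions are represented evenly.  Per-cell baselines and gains are
    jittered around the config values to make the population heterogeneous.
    """
    n_vis = round(config.n_cells * config.fraction_visual)
    n_att = round(config.n_cells * config.fraction_attention)
    n_mixed = max(0, n_vis + n_att - config.n_cells) if config.allow_overlap else 0
    n_vis_pure = n_vis - n_mixed
    n_att_pure = n_att - n_mixed
    n_none = config.n_cells - n_vis_pure - n_att_pure - n_mixed

    rng = substream(config.rng_seed, "profiles")

    def jitter(value: float) -> float:
        if value == 0:
            return 0.0
        factor = 1.0 + config.rate_jitter * rng.standard_normal()
        return float(np.clip(value * factor, 0.05 * value, config.max_rate))

    profiles: list[CellProfile] = []
    class_plan: list[tuple[SelectivityClass, int]] = [
        ("visual", n_vis_pure),
        ("attention", n_att_pure),
        ("mixed", n_mixed),
        ("none", n_none),
    ]
    cell_id = 0
    for cls_name, count in class_plan:
        for k in range(count):
            preferred = 1 if k % 2 == 0 else -1
            if cls_name == "attention":
                gain = jitter(config.attention_gain)
                peak, width = ATTENTION_PEAK_MS, config.attention_width
                sustain, secondary = config.attention_sustain, None
            elif cls_name == "mixed":
                gain = jitter(config.attention_gain)
                peak, width = ATTENTION_PEAK_MS, config.attention_width
                sustain, secondary = config.attention_sustain, VISUAL_PEAK_MS
            elif cls_name == "visual":
                gain = jitter(config.visual_gain)
                peak, width = VISUAL_PEAK_MS, config.visual_width
                sustain, secondary = config.visual_sustain, None
            else:  # unselective: condition-independent response
                gain = jitter(0.3 * config.visual_gain)
                peak, width = VISUAL_PEAK_MS, config.visual_width
                sustain, secondary = 0.0, None
            baseline = jitter(config.baseline_rate)
            gain = min(gain, config.max_rate - baseline)
            profiles.append(
                CellProfile(
                    cell_id=cell_id,
                    selectivity_class=cls_name,
                    preferred_condition=preferred,
                    baseline_rate=baseline,
                    response_gain=gain,
                    peak_latency=peak,
                    response_width=width,
                    sustain_fraction=sustain,
                    secondary_latency=secondary,
                )
            )
            cell_id += 1
    return profiles


def _component(
    t: np.ndarray, gain: float, peak: float, width: float, sustain: float
) -> np.ndarray:
    """Gaussian transient plus sustained plateau after the peak, in spikes/s."""
    bump = gain * np.exp(-0.5 * ((t - peak) / width) ** 2)
    plateau = gain * sustain * (t > peak)
    return bump + plateau


def rate_function(
    profile: CellProfile,
    condition: int,
    duration: int,
    secondary_condition: int | None = None,
) -> np.ndarray:
    """Analytic firing rate (spikes/s) of the cell over a trial.

    ``condition`` is the state of the cell's own encoded variable;
    selective cells add their response component only when it matches
    their preference, while unselective cells respond identically to both
    conditions.  Mixed cells additionally carry a visual transient at
    ``secondary_latency`` driven by ``secondary_condition`` (defaults to
    ``condition``).  The rate is clipped to [0, 1000] spikes/s (at most
    one spike per 1 ms bin).
    """
    t = np.arange(duration, dtype=float)
    rate = np.full(duration, profile.baseline_rate)
    driven = (
        profile.selectivity_class == "none"
        or condition == profile.preferred_condition
    )
    if driven:
        rate = rate + _component(
            t,
            profile.response_gain,
            profile.peak_latency,
            profile.response_width,
            profile.sustain_fraction,
        )
    if profile.secondary_latency is not None:
        secondary = condition if secondary_condition is None else secondary_condition
        if secondary == profile.preferred_condition:
            rate = rate + _component(
                t, profile.response_gain, profile.secondary_latency,
                profile.response_width, 0.0,
            )
    return np.clip(rate, 0.0, 1000.0)


def generate_trial(
    profile: CellProfile,
    condition: int,
    duration: int,
    rng: np.random.Generator,
    noise: Literal["poisson", "none"] = "poisson",
    secondary_condition: int | None = None,
) -> np.ndarray:
    """Simulate one event-aligned spike train (uint8, 1 ms bins).

    ``noise="poisson"``: independent Bernoulli per 1 ms bin with
    p = rate(t) * 1 ms (an inhomogeneous Poisson process at this
    resolution).  ``noise="none"``: deterministic integrate-and-fire
    thinning of the same rate — a spike whenever the accumulated rate
    crosses an integer — yielding identical trains on every trial of a
    condition (for noise-free separability tests).
    """
    if duration < profile.peak_latency + profile.response_width:
        raise ValueError("trial too short for the cell's response transient")
    p = rate_function(profile, condition, duration, secondary_condition) / 1000.0
    if noise == "poisson":
        train = (rng.random(duration) < p).astype(np.uint8)
    elif noise == "none":
        acc = np.cumsum(p)
        train = (np.diff(np.floor(acc), prepend=0.0) > 0).astype(np.uint8)
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return train


#: which variable each selectivity class encodes (mixed cells encode both:
#: their attention component is primary, the visual transient secondary)
_CLASS_VARIABLE = {
    "visual": "exogenous",
    "attention": "endogenous",
    "mixed": "endogenous",
    "none": None,
}


def generate_dataset(config: GeneratorConfig) -> SpikeDataset:
    """Generate the full synthetic dataset described by ``config``.

    The trial labels describe ``config.variable``.  A cell's response is
    driven by the state of the variable it encodes: cells selective for
    the *other* variable respond to an independent random nuisance state
    drawn per trial, so e.g. visual cells carry no information about the
    attention label (mixed cells carry both, each component driven by its
    own variable).  Per-cell trial counts per condition are drawn from a
    normal distribution (mean ``n_trials_mean``, s.d. ``n_trials_sd``),
    rounded and floored at ``min_trials``.  Bit-reproducible given
    ``rng_seed``.
    """
    profiles = assign_cell_classes(config)
    count_rng = substream(config.rng_seed, "trial-counts")
    spike_rng = substream(config.rng_seed, "spikes")

    spikes: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for profile in profiles:
        n_per_cond = int(
            max(
                config.min_trials,
                round(
                    config.n_trials_mean
                    + config.n_trials_sd * count_rng.standard_normal()
                ),
            )
        )
        cell_labels = np.repeat([-1, 1], n_per_cond).astype(np.int8)
        encodes = _CLASS_VARIABLE[profile.selectivity_class]
        cell_spikes = np.empty((cell_labels.size, config.trial_duration), np.uint8)
        for j, lab in enumerate(cell_labels):
            nuisance = int(spike_rng.choice([-1, 1]))
            if encodes is None or encodes == config.variable:
                primary = int(lab)
            else:
                primary = nuisance
            if profile.selectivity_class == "mixed":
                # visual transient follows the exogenous state
                secondary = int(lab) if config.variable == "exogenous" else nuisance
                # attention component follows the endogenous state
                primary = int(lab) if config.variable == "endogenous" else nuisance
            else:
                secondary = None
            cell_spikes[j] = generate_trial(
                profile, primary, config.trial_duration, spike_rng,
                config.noise, secondary_condition=secondary,
            )
        spikes.append(cell_spikes)
        labels.append(cell_labels)
    return SpikeDataset(profiles, spikes, labels, config.trial_duration)


# ---------------------------------------------------------------------------
# Directory layout for raster exchange: one plain-text raster per cell plus a
# trial table, so recorded data in the same layout can be substituted.

def save_dataset(dataset: SpikeDataset, path: str | Path) -> None:
    """Write rasters (cell_XXX.txt, rows of 0/1) + trials.csv + cells.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "trial_duration": dataset.trial_duration,
        "cells": [
            {
                "cell_id": c.cell_id,
                "selectivity_class": c.selectivity_class,
                "preferred_condition": c.preferred_condition,
                "baseline_rate": c.baseline_rate,
                "response_gain": c.response_gain,
                "peak_latency": c.peak_latency,
                "response_width": c.response_width,
                "sustain_fraction": c.sustain_fraction,
                "secondary_latency": c.secondary_latency,
            }
            for c in dataset.cells
        ],
    }
    (path / "cells.json").write_text(json.dumps(meta, indent=1))
    with open(path / "trials.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cell_id", "trial_id", "condition"])
        for i, labs in enumerate(dataset.labels):
            for j, lab in enumerate(labs):
                writer.writerow([i, j, int(lab)])
    for i, raster in enumerate(dataset.spikes):
        np.savetxt(path / f"cell_{i:03d}.txt", raster, fmt="%d", delimiter="")


def load_dataset(path: str | Path) -> SpikeDataset:
    """Read a dataset written by :func:`save_dataset`."""
    path = Path(path)
    meta = json.loads((path / "cells.json").read_text())
    cells = [CellProfile(**c) for c in meta["cells"]]
    labels_by_cell: dict[int, list[int]] = {}
    with open(path / "trials.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            labels_by_cell.setdefault(int(row["cell_id"]), []).append(
                int(row["condition"])
            )
    spikes = []
    labels = []
    for i in range(len(cells)):
        lines = (path / f"cell_{i:03d}.txt").read_text().split()
        raster = np.array(
            [[int(ch) for ch in line] for line in lines], dtype=np.uint8
        )
        spikes.append(raster)
        labels.append(np.array(labels_by_cell[i], dtype=np.int8))
    return SpikeDataset(cells, spikes, labels, int(meta["trial_duration"]))
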