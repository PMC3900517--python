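# Methods

## The decoding problem

`popdecode` treats binary decoding from spiking populations as a paired
benchmark: given event-aligned single-trial spike trains from n cells
recorded *non-simultaneously*, how reliably can different classifiers
recover a binary condition label, and how does that reliability depend on
the population, the trials, and the temporal structure of the signal? Two
signal types are modelled after prefrontal (FEF-like) physiology: an
exogenous, stimulus-driven signal carried by most cells with a transient
peaking ~125 ms after stream onset, and an endogenous attention signal
carried by a small subset of cells, peaking ~245 ms after the cue and
partly sustained afterwards.

## Synthetic populations

The generator produces, per cell, an inhomogeneous Bernoulli spike train at
1 ms resolution with rate

    r(t) = baseline + gain · 1[c = c*] · G(t; t_peak, w) + gain · s · 1[t > t_peak] · 1[c = c*]

where `G` is a Gaussian bump (s.d. `w`), `c*` the cell's preferred
condition, and `s` the sustained fraction. Rates are clipped to [0, 1000]
spikes/s. Key defaults, chosen once to emulate the physiological regime and
then left alone:

| parameter | default | rationale |
| --- | --- | --- |
| n_cells | 131 | population size of the emulated recordings |
| visual / attention cells | 111 / 21 | one cell carries both signals (the counts overlap by one) |
| baseline rate | 10 spikes/s | typical prefrontal baseline |
| visual gain, width | 10 spikes/s, 35 ms | yields near-ceiling (~95–100%) exogenous decoding |
| attention gain, width | 6 spikes/s, 50 ms | yields ~75–85% endogenous decoding, the interesting regime |
| sustain fraction | 0 (visual), 0.5 (attention) | attention must persist from cue to target; gives the memory analysis signal to find |
| trials/condition | N(112, 33²) endogenous, N(295, 107²) exogenous, floor 10 | usable-trial statistics differ per variable |
| trial duration | 700 ms | covers the 70–500 ms memory window plus test margins |

Per-cell baselines and gains are log-jittered (~25% spread) for
heterogeneity. Each cell's response is driven by the label of *its own*
variable; cells selective for the other variable respond to an independent
nuisance state drawn per trial. This is essential: without it, visual cells
would trivially "carry" the attention label and the endogenous analyses
(including the memory comparison) would be contaminated by a shortcut that
does not exist in the recordings.

Noise is independent Poisson across cells — pseudo-populations built from
non-simultaneous recordings have no noise correlations, and neither does
the generator (a correlation knob is deliberately out of scope). A
deterministic `noise="none"` mode (integrate-and-fire thinning of the same
rate) produces identical trials per condition for exact-separability tests.

What the generator does **not** emulate: noise correlations, non-Poisson
count statistics (bursting, refractoriness), response latency jitter across
trials, drift across a session, and the behavioral task itself (cue
validity enters only as it would through label noise). Passing tests
therefore certify the *pipeline* — not that real FEF data will produce
these exact numbers.

## Pre-processing and resampling

Spike trains are smoothed by a 100 ms sliding window (mean count in the
window centred at t, converted to spikes/s; edge windows are truncated and
normalized by their actual length, so a constant train stays constant).
Each cell is balanced to 60 trials per condition: subsampling without
replacement when abundant, otherwise all originals plus random duplicates.
Within a seed, each cell's 60 balanced trials are assigned to the 60
virtual trials of its condition by a random bijection (the most literal
reading of "randomly combined"), the same assignment at every time point.
The 70/30 partition is stratified (42/42 train, 18/18 test) to keep the
test sets balanced by construction. Imbalance experiments then drop
training trials of one condition to round((1−f)·n₁), rounding half away
from zero, with f up to 0.5.

All randomness flows from one master seed through named CRC32-keyed
substreams (generation, balancing, seed construction, partitions,
permutations, decoder initialisation), making every result table
bit-reproducible.

## Decoders: numerical choices

- **r_ole.** Ridge on the centred design with an unpenalized bias. λ grid
  10⁻⁶…10³ (13 points, log-spaced); selected per fit by stratified 5-fold
  inner CV accuracy, ties resolving to the *largest* λ. The tie rule
  matters: near the interpolation threshold (training trials ≈ cells)
  weakly regularized solutions are unstable and produced a visible
  double-descent dip in the trial-number sweep before ties favoured
  regularization.
- **ann_ole / ann_nle.** tanh output (and tanh hidden layer of n/2 units
  for the NLE); cost λ·mse + (1−λ)·msw with λ = 0.5, msw the mean square
  over all weights and biases. Optimized by L-BFGS (a limited-memory
  quasi-Newton method — full BFGS is quadratic in the ~8·10³ NLE
  parameters), 200 iterations, gradient tolerance 10⁻⁶, one random
  restart, best cost wins; non-convergence returns best-so-far with a
  logged warning. The NLE is implemented and tested but excluded from
  sweep defaults: it is by far the slowest fit and never outperforms.
- **bayes.** Log-space naive Bayes with class-specific per-cell
  variances; equal priors always (the design is balanced; this is also
  why it is structurally insensitive to training imbalance). Standard
  deviations are floored at 10⁻³ of the pooled s.d. across cells and
  classes (absolute floor 10⁻⁶ if everything is degenerate) so duplicated
  or noise-free trials cannot produce infinite likelihoods.
- **reservoir.** Input weights U(0, 1)·10^−1.2, 500 uncoupled identity
  nodes, τ = 1 (no leak): algebraically a ridge regression on the
  projected inputs, which is exactly how it is unit-tested. Readout by
  ridge normal equations (λ = 10⁻⁶) over all 75 time steps of the
  training window, each step targeting the constant trial label. The
  memory variant: tanh transfer, input scale 10^−3.8, τ = 55 under
  x(t) = (1−1/τ)x(t−1) + (1/τ)f(W_in u(t)) (the leak convention; states
  integrate from t = 0 with x(−1) = 0), trained on 70–500 ms.
- **svm.** scikit-learn's libsvm binding; grids cost 2⁻⁵…2¹⁵ and
  γ 2⁻¹⁵…2³ in steps of 2², 5-fold stratified CV on the training set,
  ties to the first (smallest) grid entry. Decision values are verified
  against the explicit support-vector kernel expansion.
- Inputs are z-scored per cell with training statistics for the network,
  reservoir and SVM fits; r_ole and bayes operate on raw rates with their
  own bias/mean terms. The global tie rule is sign(0) = +1.

## Evaluation and inference

Readout performance = fraction correct on the 36 held-out virtual trials,
averaged over the 100 test windows t_train − 50 … t_train + 49 ms. The
chance level is computed per decoder by redrawing every cell's labels with
replacement (as opposed to shuffling — the literal procedure, which can
leave null training sets slightly unbalanced) and re-running the entire
pipeline; the 95th percentile (linear-interpolation quantile) of the
1000-point chance distribution gates significance. Nulls are never shared
across decoders: high-variance decoders earn themselves a higher bar. For
across-decoder inference the package emits per-seed paired tables and a
paired permutation test rather than re-implementing repeated-measures
ANOVA machinery; the inference target ("is decoder A better than B on the
same seeds") is unchanged. In the memory analysis performance is reported
per time point with no window averaging, with a per-time-point permutation
significance trace.

One subtlety discovered while calibrating the chance machinery: when a
cell has barely 60 trials per condition, label randomization makes one
class scarce and balancing duplicates trials; a duplicate can then land in
both a train and a test virtual trial, and high-capacity decoders read the
leak, lifting the *empirical* chance level above 50%. This is precisely
why the chance level must be computed by the full pipeline rather than
assumed — the calibration tests use abundant-trial populations where no
duplication occurs, and real analyses should compare against the empirical
null, never against 50%.

## Problem sizes in tests and scripts

The test suite and `scripts/acceptance.py` run everything at reduced but
scientifically meaningful sizes, chosen as the package's own defaults for
a single-core desk run: 10–20 cell populations for calibration (with 1000
chance points where a mean must be pinned to ~0.5%), a 40-cell population
for sweeps, a 60-cell population for the memory analysis (at ≥80 cells the
leaky reservoir's integration advantage overtakes the wide-training
dilution and the peak-time ordering reverses — 60 cells keeps both effects
visible), and 5–10 seeds with 5–10 permutations per null. The acceptance
script runs the full 131-cell composition with 10 seeds and 5
permutations per null, except the memory comparison, which it reports at
the 60-cell condition for the reason above.

## Known limitations

- Chance distributions at reduced permutation counts are noticeably
  correlated within a permutation (all seeds share one labeling), so their
  means wander ±1–2% unless hundreds of points are used.
- The ANN cost surface is non-convex; two starts suffice for the
  population sizes used here but give no global guarantee.
- The degenerate check "memory variant with τ = 1 equals the static
  variant" cannot be exact because the variants differ in transfer
  function; at the memory variant's input scale tanh is linear to ~10⁻⁹,
  which is how the near-equality is tested.
- Reservoir results depend on the random projection; per-seed decoder RNGs
  are derived from the spec seed and seed id, so this variability is
  frozen and reproducible, and is part of what the decoder-specific null
  absorbs.
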