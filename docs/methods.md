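# Methods

## The scientific setting

Larval zebrafish swim in discrete bouts (~100–200 ms) separated by
stationary interbout intervals (~0.5–1.8 s) and thermoregulate by modulating
swim initiation and kinematics. In a closed-loop "thermal plaid" paradigm an
infrared laser couples the water temperature experienced by a freely
swimming fish to its position through a doubly periodic sinusoidal power
field, so every swim generates thermosensory feedback; a yoked "replay" fish
passively receives the identical temperature sequence, breaking the
feedback loop while preserving the stimulus. The analysis question is how
sensorimotor feedback changes the transformation from thermal stimuli to
swim initiation, and what neural representation would let downstream
circuits detect the presence of feedback.

This package implements the full analysis chain on simulated data: a
generative virtual-fish model, bout detection from tail-angle traces, a
small convolutional network encoding swim probability, receptive-field
extraction by network differentiation, conversion of receptive fields to
bout-frequency modulation, feedback decoding from simulated
mixed-selectivity neurons, and fish-level bootstrap statistics.

## The thermal field and calibration

Laser power at position (x, y) in mm (origin at the field's top-left
corner) is

    P(x, y) = 750 mW · (0.5·sin(2πx/15) + 0.5·sin(2πy/15)) + 1250 mW,

spanning 500–2000 mW with axis period 15 mm; the repeat distance along the
(1,1) diagonal is 15·√2 ≈ 21.2 mm. Power maps to temperature through an
affine calibration anchored at 500 mW → 25 °C and 2000 mW → 28 °C, the
simplest map consistent with the stimulus range; the physical calibration
procedure of the original rig is out of scope. Temperature is treated as an
instantaneous function of laser power (no thermal lag filter).

The package exposes both period readouts (`axis_period_mm`,
`diagonal_period_mm`) without arbitrating between the two ways "period" can
be quoted for a diagonal plaid.

## The generative swim policy

Bout initiation is a logistic point process on 40 ms bins (25 Hz):

    p(t) = σ( b₀ + k_T·(T_hist(t) − T_ref) + k_B·B_hist(t) )

with a strictly causal 25-bin (1 s) temperature history `T_hist` (°C,
centred on T_ref = 26.5 °C), a binary 25-bin history of bout *ends*
`B_hist`, and baseline log-odds b₀ (default logit(0.04) → 1 bout/s). Kernel
index 0 is the most recent lag (40 ms). With both kernels zero the process
is homogeneous Bernoulli — the oracle used to test the simulator's rate.
Draws occur in every bin; a start drawn during an ongoing bout truncates
it, keeping the marginal start rate exactly the per-bin rate.
Refractoriness is carried by the bout-history kernel (strongly negative at
lags < 320 ms in the default policy), and the default temperature kernel is
derivative-like with a realistic sensorimotor latency: warming ~240 ms
before the bin promotes swimming, warmth ~0.7 s ago suppresses it (a
zero-lag excitatory peak would model an implausibly instant reaction, and
receptive fields extracted from real fish concentrate their influence
several hundred ms before the swim). `sample_fish_policy` draws
individual-fish policies around this default — latency, thermosensory
gain, refractory strength and baseline rate all jittered — because real
groups are heterogeneous and identical clones synchronize unrealistically
when driven by a shared replayed stimulus.

Bout kinematics: duration uniform 100–200 ms; displacement lognormal with
2 mm median; turn angle a mixture of straight swims (60 %, sd 5°) and
±30°±10° turns; reflective heading at the 50 mm arena wall (no thigmotaxis
model — analyses exclude the edge region anyway).

Delivered temperature includes an Ornstein–Uhlenbeck fluctuation
(sd 0.115 °C, correlation time 0.2 s — a fast, measurement-like timescale)
standing in for thermal/laser dynamics. Its scale is set so that the
median |ΔT| over bout-length windows for a stationary fish is ≈ 0.08 °C,
matching the reported interbout temperature changes of the physical
paradigm; without it a stationary simulated fish would experience exactly
zero temperature change and the contrast between closed- and open-loop
conditions would be unrealistically sharp. The fluctuation is part of the
recorded trace and is therefore replayed bitwise to the yoked twin.

What the generator does *not* emulate: directed thermotaxis (turn
directions are independent of the gradient), habituation or slow
behavioral drift, tracking noise in positions, and between-fish policy
heterogeneity. Consequences for interpretation are flagged below where
they matter.

## Bout detection

Swim vigor is the population SD of the cumulative tail-bend angle over a
trailing 10-frame window at 250 Hz (partial windows at the trace start). A
bout opens when vigor crosses 0.1 rad/frame upward and closes when it falls
below; a bout open at the trace end closes there. Displacement is the
distance between 5-frame mean positions flanking the bout; the turn angle
is the difference of mean-vector headings mapped to [0°, 180°]. Bouts whose
flanking frames fall outside the trace keep NaN kinematics for timing-only
analyses. Analysis bouts must start ≥ 4 mm from the wall. No pre-smoothing
is applied to the tail angle before thresholding. Synthetic tail traces
(30 Hz sinusoidal beating at 1 rad amplitude inside bouts, Gaussian noise
elsewhere) give ≥ 95 % start recovery within ±2 frames at noise sd
0.02 rad, with zero false positives on noise-only traces.

## The swim-probability network

Inputs are the two 25-bin histories per 40 ms bin (temperature averaged
within bins; bout-end channel binary), standardized with training-split
statistics. The architecture is one *linear* convolutional layer of 20
units spanning the full history of both channels (a learned temporal
basis), two 64-unit dense layers with Swish activation, dropout 0.5 after
each layer (off at inference), and a linear output approximating the
log-odds of a bout. Training minimizes binary cross-entropy plus an L2
penalty of 1e-5 with Adam (step 1e-3, batch 256), on an 80/20 per-
experiment contiguous split whose held-out block position, initialization,
dropout and batch order all derive from the per-fit seed. No class
reweighting is used.

The output bias is initialized at the empirical base-rate log-odds. With a
~2–4 % positive class, a zero-initialized output forces training to push
the densely populated input region down by ~4 log-odds units, which leaves
spurious positive gradients along the sparse bout-history directions;
starting at the base rate removes this artifact (verified on
independent-label controls).

The circular-permutation control rotates labels by 1/3 of each experiment
relative to both input channels, conserving label counts and marginals.

## Receptive fields and their behavioral effect

The receptive field is the gradient of the scalar log-odds output with
respect to each input bin — the Taylor-expansion analogue of a
spike-triggered average that remains unbiased for strongly autocorrelated,
self-generated stimuli — averaged over a random 10,000-sample subset of the
data and returned in natural units (per °C, per bout event). Analytic
gradients are verified against central finite differences at rtol 1e-4.
An identity-activation network configuration makes the whole net exactly
linear, giving a closed-form oracle for the extraction.

The effect of the thermosensory field k on behavior uses the logistic
transform around the mean bout probability p̄ (estimated on the training
split):

    Δlp(t) = k·(s(t) − s̄),   lp̄ = log(p̄/(1−p̄)),
    Δp(t) = σ(Δlp(t) + lp̄) − p̄,   Δbf(t) = Δp(t) · 25 s⁻¹.

Δp is exactly 0 when Δlp = 0 and floors at −p̄ for strongly suppressive
stimuli; Δbf converts per-bin probability into bouts/s. Receptive fields
from two conditions are compared per lag with two-sided rank-sum tests
across fit replicates, Bonferroni-corrected over the 25 lags (significance
at corrected p ≤ α), and their behavioral effects with per-experiment SDs
of Δbf under a paired Wilcoxon signed-rank test (identical fields are
reported as statistic 0, p = 1 rather than an error).

History length: 1 s at 25 Hz (25 bins) throughout — consistent with the
25 s⁻¹ conversion factor and the 25-lag multiple-comparison convention; the
window is a configuration knob.

## Mixed-selectivity neurons and feedback decoding

Neuron stand-ins respond at 5 Hz to a drive
`ws·f(dT/dt) + wm·bouts + wc·f(dT/dt)·bouts` (f = half-wave rectification
when enabled), convolved with an exponential calcium kernel (unit peak,
tau ~1.5–3.5 s) plus Gaussian noise (sd 0.05). Populations mix sensory-
only, motor-only, additive and coincidence types; the "nonlinear
mixed-selectivity" subset (wc ≠ 0 or rectified) feeds the decoder. These
are parameterized stand-ins constructed for this package — not fitted
models of real neurons — chosen to express the hypothesized coincidence
computation in its simplest form.

Decoding: pooled-population PCA (full SVD, 10 components), then a
ridge-penalized logistic regression classifying individual 5 Hz bins as
plaid vs replay. Splits are always by experiment (two thirds train,
stratified by condition, partition seeded by group membership so label
naming is irrelevant), the ridge penalty is chosen by 5-fold inner CV over
seven values log-spaced 1e-3…1e3, and the whole procedure repeats over 100
random splits. Experiment-level AUCs (mean bin score per experiment) are
reported alongside bin-level AUCs. Comparison decoders operate on the raw
inputs (temperature, swim starts, displacement, turn) over integration
windows: the current bin alone has 4+1 = 5 parameters, the 10 s window
4·50+1 = 201. All windows share valid bins and split partitions so
split-paired differences are meaningful.

A structural caveat established while validating this module: with a shared
generative policy and sign-symmetric gradient steps, plaid and replay
conditions differ only in *second-order* (coincidence) statistics of the
inputs, so a linear input decoder is pinned at chance for every window
while the coincidence-neuron decoder performs well. Matching the two — as
observed in real data, where fish groups also differ in first-order
behavioral statistics — would require between-group marginal differences
the simulation deliberately does not inject.

## Fish-level statistics

Bout-derived quantities cluster by fish, so two-sample comparisons use a
bootstrapped KS test with the *fish* as the resampling unit: the observed
statistic is the ordinary KS distance between pooled values; null variates
draw fish (with replacement) from the combined pool into two groups of the
original fish counts. p-values are the fraction of null statistics ≥
observed, floored at 1/n_boot. An optional flag additionally resamples
values within each drawn fish. Type-I error at α = 0.05 calibrates to
[0.03, 0.07] in simulation. Binned densities carry fish-level bootstrap
SEs, each replicate renormalized. Rank-sum and signed-rank tests delegate
to scipy (`ranksums`, `wilcoxon` with the smaller-rank-sum convention).

## Problem sizes used by the test suite

Chosen as this package's standard working scale: parameter recovery uses 10
plaid experiments of 10 min with ground-truth bout labels, 30 training
epochs and 10 fits (asserting median kernel correlation ≥ 0.8); the
permuted-null control uses 16 experiments of 10 min with detected,
edge-filtered bouts and 15 epochs; the decoder comparison uses 8
plaid/replay pairs of 4 min, 120 sampled neurons and 100 splits; the
per-bout temperature analysis uses 20 heterogeneous pairs of 4 min; KS
calibration uses 500 replicate tests of 10-fish groups at 250 bootstrap
draws. Ground-truth labels are used for parameter recovery because edge
filtering and detection merging would otherwise delete ~25 % of true bout
starts — real behavior under the spatially uniform policy — and visibly
degrade kernel recovery; detection quality is tested separately.

## Known limitations

- The encoder's null-control receptive fields are *flat relative to the
  signal* but not exactly zero-mean across fits: all fits share one
  fixed-shift permuted dataset, so its finite-sample chance coupling (the
  noise floor the control is designed to measure) appears consistently in
  every fit. Across-fit confidence intervals therefore concentrate on a
  small nonzero floor rather than on zero.
- Condition differences in first-order behavioral statistics between
  simulated plaid and replay groups are weaker than in real data (see the
  decoding caveat above).
- Because replay fish are temperature-reactive — their own thermosensory
  receptive field is nonzero, as in real data — their bouts carry a small
  (~10 % of the interbout median) |ΔT| enrichment over random intervals.
  Any reactive point process on an autocorrelated stimulus has this
  property; with many low-variance simulated fish it is statistically
  detectable, whereas the larger between-fish variability of real datasets
  masks it at the same sample size.
- Bout chaining (a start drawn during an ongoing bout) produces occasional
  sub-100 ms interbout intervals that merge under vigor-threshold
  detection; the renewal-style `sample_bout_train` generator provides
  non-overlapping trains when detection itself is under test.
- The logistic policy acts on binned (40 ms) inputs; sub-bin latencies are
  not modeled.
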