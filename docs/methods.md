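# Methods

This note documents the models, numerical choices and known limitations
of `reflexmri`, in the order data flows through the package.

## Perturbation protocol and silent-window timing

A session consists of ten 5 s isometric contractions (alternating
flexion/extension, used for EMG normalization) followed by 60
ramp-and-hold perturbations: six signed velocities (±50, ±125,
±200 deg/s), ten repetitions each, in a seeded random permutation.
Positive rotations stretch the wrist flexor (FCR); negative rotations
stretch the extensor (ECU). Each trial draws a torque-hold time uniform
on [0.4, 0.8] s and a post-perturbation rest uniform on [7, 10] s,
followed by a 25 deg/s return movement and 4 s extra rest, giving
sessions of roughly 15–17 minutes.

The fMRI sequence is modeled as TR = 1.225 s with a 225 ms silent gap at
the end of each TR. Perturbation onsets are snapped forward to the next
admissible slot 25 ms after a volume's acquisition ends, so the 200 ms
measurement window always falls inside a silent gap. This is a
simplification of the hardware behavior (where the torque trigger and
the scanner clock free-run and the robot waits for the next window); it
preserves the property that matters downstream — alignment of every
analysed window with artifact-free time.

## Synthetic EMG generator

**Clean signal.** EMG is modeled as band-limited (20–250 Hz) unit
Gaussian noise amplitude-modulated by an envelope `a(t)`:
`background_level` (default 0.05 of the contraction level) everywhere,
the contraction level (1.0) during active isometric blocks, plus two
Hann-shaped bursts per trial — a short-latency burst on [25, 50) ms and
a long-latency burst on [50, 100] ms. Burst areas are normalized
numerically so the generative LLR area is exact:
`true_H = llr_gain · |v| · (1 + ε)`, `ε ~ N(0, llr_cv²)`, with
`llr_gain = 0.1` normalized-EMG·ms per deg/s and `llr_cv = 0.2`
(a typical trial-to-trial reflex coefficient of variation). Trials that
shorten a muscle scale its bursts by 0.2. Because rectification and the
60 Hz envelope stage scale the modulated carrier and the contraction
normalization constant by the same rectified-Gaussian factor √(2/π),
measured H approximates `true_H` plus a constant background area
(≈ 2.5). Amplitude-modulated noise is used instead of a physiological
motor-unit model precisely so the band-pass stage passes the signal
essentially unchanged and ground truth has a closed form.

**Motion artifact.** A shared motion source `m(t)` is the 50 Hz
low-passed encoder velocity (minimum-jerk ramps matching the commanded
velocity over the 200 ms perturbation), normalized to ≈1 at the fastest
perturbation, plus motion-gated broadband jitter
(`jitter_level · |m| ·` band-limited noise, 20–150 Hz) representing
wire vibration. The two measurement channels see different
nonlinearities with memory:

    w = smooth_50Hz(1.0·m + 0.3·m³)      (measurement channel)
    r = smooth_70Hz(0.8·m + 0.2·m²)      (reference channel)

so `w` and `r` are strongly correlated but not affinely related —
subtraction is imperfect and the canceller has a learnable nonlinear,
weakly dynamic relationship. Amplitude is calibrated so the peak of `w`
*within the 20–250 Hz analysis band* is `artifact_gain = 5` times the
largest LLR envelope peak; calibrating in-band is deliberate, since the
high-pass removes most of the smooth commanded-motion component and the
in-band residue is what the pipelines actually fight. The conservation
`y = x + w` holds sample-wise by construction, and a constant encoder
trajectory produces zero artifact.

Sampling rate defaults to 2000 Hz (≥4× the 250 Hz analysis band; the
amplifier's true rate is not a modeled quantity).

**What the generator does not emulate:** gradient/RF noise (excluded by
design via silent windows), physiological habituation, motor-unit
synchronization structure, impedance drift, and torque-control dynamics
of the robot. Passing tests therefore demonstrate correctness of the
*processing* under the stated interference model, not hardware fidelity.

## EMG processing

Segments are 200 ms (`round(0.2·fs)` samples) starting at the
perturbation-onset marker. All filters are Butterworth applied
zero-phase (forward–backward, doubling the effective order): band-pass
20–250 Hz order 4 on both channels, then rectification and low-pass
60 Hz order 4, clipped at zero. Zero-phase filtering is the default
because the [50, 100] ms window depends on burst latency; causal
filtering is available via a flag.

The normalization constant per muscle is the mean processed envelope
over the central 3 s of each active-direction contraction block
(flexion→FCR, extension→ECU), averaged across blocks, computed with the
standard pipeline (contractions are isometric, so no perturbation
artifact is expected). H is the trapezoidal integral of the normalized
envelope over t ∈ [50, 100] ms inclusive, time in ms (exact for the
constant and ramp oracles at fs = 2000; O(Δt²) otherwise).

## The ANFIS canceller

`AnfisRegressor` is a first-order Takagi–Sugeno system on the inputs
(r, ṙ, θ): generalized-bell membership functions on a grid partition
(centers equally spaced over each input's observed range, width =
range/(2(m−1)), slope 2), product T-norm, normalized firing strengths,
and per-rule affine consequents. Training is hybrid: per epoch the
consequents are solved exactly by linear least squares given the current
premises (minimum-norm solution; ridge λ=1e-8 fallback if the system is
degenerate), then one normalized full-batch gradient step updates the
premise parameters, with the classic adaptive step schedule (×1.1 after
four consecutive error drops, ×0.9 on oscillation). A contiguous
validation interval (20% of samples) is redrawn at a seeded random start
each epoch, and the returned model is the epoch snapshot with minimum
validation RMSE — the guard against the system fitting the muscle signal
buried in its training target.

Defaults: **2 membership functions per input** (8 rules, 32 consequent
coefficients), 10 epochs, one model per trial segment (the artifact is
position-dependent). Two MFs is the classic grid-partition default and
is deliberate: with 3 MFs (27 rules, 108 coefficients) the consequent
solve on a 400-sample window absorbs roughly a quarter of the in-sample
EMG energy, which biases H low enough to lose to plain subtraction.
With the default configuration the accuracy ordering
ANC < SUB < STD (mean |H − truth|) holds in 20/20 seeded sessions.
A segment whose reference channel is identically flat carries no
interference evidence; the canceller then returns the input unchanged,
which makes all three pipelines exactly equal on artifact-free sessions.

When the artifact is affine in the inputs the exact solution lies in the
consequent span regardless of premises, so one least-squares step
reproduces ordinary least-squares artifact regression to machine
precision — the package's strongest internal oracle.

Known limitation: because the consequent solve sees `y = x + w`, a small
fraction of the EMG is inevitably absorbed into `ŵ`, biasing H slightly
low (≈2 normalized-EMG·ms under default conditions). This is inherent to
per-trial adaptive cancellation, is far smaller than the artifact biases
of STD/SUB, and is visible in the validation replica as a small negative
Bland–Altman bias.

## Agreement statistics

Cell means H̄ (per participant, session, filter, muscle, velocity) are
paired across sessions by inner join and split by stimulus direction.
Bland–Altman uses bias ± 1.96·SD limits of agreement; confidence
intervals use the classical t-based forms (bias ± t·SD/√n,
LoA ± t·SD·√(3/n)). Bias differences are compared with a two-sided
normal z-test on independent bias estimates, Bonferroni-adjusted. The
Jaccard index of two LoA intervals is intersection over union (0 for
disjoint intervals; degenerate intervals score 1 only if identical); its
uncertainty comes from a parametric bootstrap drawing each LoA endpoint
independently from Normal(estimate, SE). Per-trial z-scores standardize
each H by the matched (participant, muscle, velocity) reference-cell
mean and sample SD (n−1; the estimator is configurable because the
source description is ambiguous between sample and population forms).

Two caveats discovered on synthetic data and worth knowing when
interpreting σ_v summaries: (i) with 10-trial reference cells, even
identically distributed sessions give σ_v ≈ 1.19 rather than 1
(dividing by a noisy SD inflates the spread by √((1+1/n)(n−1)/(n−3)));
the [0.8, 1.25] acceptance band absorbs this for stretch responses.
(ii) shortening responses are background-dominated and skewed in the
generator, inflating their σ_v further (≈1.5 at the lowest speed); the
per-direction tables report them, but normal-theory bands should not be
applied there. Bartlett tests at n ≈ 700 detect even the canceller's
small genuine residual variance, so the meaningful multi-method summary
is the ordering of variance inflation (ANC < SUB < STD), which is what
the replica test asserts alongside the stretch-direction significance
pattern.

## BOLD model and phantoms

Event regressors place 50 ms boxcars at perturbation onset + 50 ms with
height H̃ (the stretch-trial amplitudes of one muscle) on a 5 ms
microtime grid, convolve with a peak-normalized double-gamma HRF
(difference of gamma densities, shape = delay/dispersion,
scale = dispersion, undershoot scaled by 1/ratio, 32 s kernel), and
sample at volume start times. Two parameter sets are built in: standard
(peak 6 s, undershoot 16 s, ratio 6) and brainstem (peak 4.5 s,
undershoot 10 s, ratio 15). Amplitudes are not mean-centered by default.

Designs add per-session mean columns (when concatenating runs), optional
6-column head-motion nuisance blocks, and a discrete-cosine high-pass
basis of order floor(2T/cutoff) for the 128 s cutoff. Fitting is
voxelwise OLS (pseudo-inverse; df = rows − rank); contrasts give
one-sided t-maps; thresholding is voxelwise (uncorrected p or Bonferroni
over the mask — random-field small-volume correction is intentionally
out of scope, Bonferroni being nearly equivalent at these smoothness
levels) with optional 6-connected cluster-extent cuts. AR(1) noise in
phantoms is deliberately *not* prewhitened by the fitter; with the
default lag-1 correlation this mildly miscalibrates OLS p-values, so the
false-positive-control checks use white-noise phantoms, and analyses of
autocorrelated phantoms should read t-maps comparatively.

Phantoms specify effect size as the expected peak t of the generating
contrast (default 8): β is derived at generation time from the design
and noise SD, which keeps "strong but not trivial" effects well-defined
across protocols. Active voxels form rectangular 3×3×3 clusters at
opposite corners for the two muscles; truth maps are carried alongside.

## Reliability

Dice overlap applies the configured threshold (default uncorrected
p < 0.001) to both maps; S is defined 0 (flagged) when both maps are
empty. ICC(3,1) uses the two-way ANOVA consistency form
(BMS − EMS)/(BMS + EMS) with targets random and session fixed — voxels
within an ROI at participant level, subjects at group level (computed
voxelwise, summarized by ROI medians). Targets with non-finite values
are dropped listwise. The consistency form is invariant to a constant
session offset, and for two sessions equals the sum/difference-variance
closed form on session-centered columns; both identities are tested.

## Problem sizes and seeds

Default study conditions are used throughout the test suite and the
acceptance script: 60-trial sessions at 2000 Hz, 12 synthetic
participants for the validation replica, 20 seeded sessions for the
accuracy-ranking study, 40 phantom realizations (16×16×10 voxels,
~810 volumes) pooling ≥10⁵ voxel-tests for false-positive control, and
2000 replicates for Bartlett calibration. All randomness flows from
explicit seeds through named substreams (participant × session × stage),
so every reported number is reproducible bit-for-bit.

A quantitative footnote on the σ_v center: with 10-trial reference
cells, Var(z) = (1 + 1/n)·(n−1)/(n−3) = 1.414 exactly under normality,
so σ_v is expected at 1.19 with a sampling SE of about 0.07 at 240
scores per set — individual sets can exceed 1.25 by chance alone, which
is worth remembering before reading a single σ_v table as evidence of
measurement error.
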