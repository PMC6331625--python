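# Methods

This note documents the models, defaults and numerical choices behind
`eegreversal`, in the order the pipeline runs them. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic EEG generator

The generator produces the statistical structure the analysis chain
assumes, with ground truth recorded for recovery testing. Each trial is a
noise cube (trials × channels × timepoints, unit variance per channel)
plus, per feature dimension, an additive discriminative component

x(trial, ·, t) ± ½ · snr · √C · **p** · exp(−(t − τ)² / 2w²),

where **p** is a unit-norm spatial pattern (the two patterns mutually
orthogonal), C the channel count, τ the per-trial component centre and w
the temporal width (SD). The sign follows the trial's class on that
dimension.

* **SNR convention.** `component_snr` is the per-channel RMS deflection
  of the component relative to the per-channel noise SD (hence the √C
  factor on the unit-norm pattern). Under this convention multichannel
  discriminability grows with sensor count, as for a fixed scalp
  topography read by more electrodes; an SNR-1 component is decodable on
  single trials, weakly visible per channel.
* **Noise.** Default is a 50/50 variance mix of white noise and
  spectrally shaped 1/f ("pink") noise, produced by FFT-domain amplitude
  shaping with exact unit-variance normalization; circular filtering
  keeps it stationary. Channels are spatially independent — no head
  model, no artifact simulation.
* **Geometry.** Defaults: 20 participants × 96 trials × 32 channels at
  256 Hz (fidelity to a 128-channel/1024 Hz recording is configurable,
  not default). Labels are crossed and balanced across the four
  perceptual × semantic cells; every generator call derives
  per-participant RNG streams deterministically from one seed.
* **Latencies.** Encoding (stimulus-locked): perceptual component at
  +150 ms, semantic at +300 ms, width 50 ms, per-trial latency jitter
  SD 50 ms. Retrieval (button-press-locked): semantic at −1800 ms,
  perceptual at −1600 ms, width 100 ms, jitter SD 200 ms — reinstatement
  is modelled as broader and more variable in time than feed-forward
  encoding. The jitter SDs are modelling choices, not measured values.
* **Retrieval RTs** are gamma with mean 3046 ms, SD 830 ms (matching the
  recall-task descriptives this design emulates), so roughly half the
  trials survive the RT ≥ 3 s inclusion rule — the analysis is validated
  under that attrition.
* **Behaviour.** The 2 × 2 mixed design (task between participants ×
  question within) plants the crossover in gamma RT cell means
  795/842/2502/2334 ms (SDs 235/185/561/534), with additive participant
  intercepts (SD 150 ms) and Bernoulli accuracy per cell with
  participant intercepts on the logit scale (SD 0.5).

Because noise is spatially white and components are exactly Gaussian in
time, passing recovery tests shows the pipeline recovers planted order
under realistic SNR and trial attrition — not that it is robust to
correlated noise, artifacts, or non-stationary spectra of real EEG.

## Preprocessing

Fixed order: filter → baseline → common average reference → smoothing
(all linear; CAR and baseline are idempotent, smoothing commutes with
CAR). Filters are zero-phase (forward–backward) 4th-order Butterworth
per band edge — zero-phase is mandatory here because peak *latency* is
the scientific quantity. The 0.1 Hz high-pass has an impulse response
far longer than an epoch, so it is applied with Gustafsson's
initial-condition matching rather than reflection padding; the low-pass
and 48–52 Hz band-stop use second-order sections with reflection
padding. Smoothing uses a unit-area Gaussian (FWHM 24 ms) truncated at
±3 SD and renormalized over its valid support near epoch edges, so
near-boundary peaks are not attenuated toward the interior.

One consequence of the whole-trial baseline used for retrieval epochs
(chosen because post-response signal still carries object information):
subtracting the trial mean of a signal-bearing epoch spreads a small
constant, condition-dependent offset (the component's temporal integral
divided by the epoch length) across the entire epoch. ERP contrasts on
such data can therefore show weak but consistent differences far from
the component; the component peak itself remains an order of magnitude
larger, so peak-time extraction is unaffected.

## Decoding

Features at a timepoint are that timepoint's channel amplitudes — no
temporal feature windows. The classifier is LDA with the pooled
within-class scatter shrunk toward ν I (ν = mean eigenvalue); when λ is
not fixed it is selected per training fold by the analytic Ledoit–Wolf
rule for the ν I target (computed on class-centred data with the 1/n
biased covariance). Decision values are geometric distances: weights are
normalized to unit length and the hyperplane passes through the
class-mean midpoint, making d values comparable across timepoints — the
empirical-null threshold requires that consistent scale.

Undersampling to the minority class happens once per classifier per
participant (trial-set level, not per timepoint), and sign alignment
(inverting the negative class's d values) is an explicit separate step
that refuses double application.

**Exhaustive leave-one-out, made affordable.** For every timepoint the
label-independent *total* scatter T is eigendecomposed once. Each fold's
pooled within-class scatter is exactly

S₍ᵢ₎ = T − aᵢaᵢᵀ − bᵢbᵢᵀ,

where aᵢ removes the held-out trial from the total scatter and bᵢ is the
between-class component of the training set; both are rank one, so the
shrunk system solves in closed form in the shared eigenbasis (Woodbury
identity with a 2 × 2 capacitance matrix), and the Ledoit–Wolf statistics
downdate exactly through the same algebra. The eigenbasis, the trials
expressed in it, and the Gram matrices are shared across the real-label
run and all shuffled-label runs on the same epochs — this sharing is
what makes 30–150 null decodings per participant tractable. A direct
per-fold reference implementation (retrain from scratch) is kept in the
code base and the test suite asserts agreement to 1e-8. The
leave-one-out property — the held-out trial's label cannot influence its
own d value — holds exactly in exact arithmetic; floating-point
summation order differs between label assignments, so integrity tests
assert |Δd| < 1e-9 rather than bitwise equality.

**Decoding grid.** The pipeline decodes on a strided grid: every 2nd
sample at encoding (128 Hz effective) and every 4th at retrieval
(64 Hz). After 24 ms FWHM smoothing the signal is band-limited well
below either Nyquist rate, and peak-latency quantization (≤ 15.6 ms) is
small against the smoothing kernel and the planted latency differences.
Windows: decode −100…+500 ms (encoding) and −3000…0 ms (retrieval);
peak selection 0…+500 ms and −3000…0 ms.

## Empirical null and threshold

Shuffled-label runs use balanced random pseudo-splits: each true
category (photograph, drawing, animate, inanimate) is divided about
evenly between the two pseudo-classes — count difference below 8% of the
category count, with a floor of one trial for odd counts. (Balance is
defined relative to the category split rather than within pseudo-class
composition because the latter is unsatisfiable once the parent trial
set is itself imbalanced, e.g. after RT filtering; for balanced parents
the two readings coincide.) Splits are drawn by rejection sampling so
the accepted split is uniform over the constraint set.

The bootstrap draws, per participant, one of the n_runs + 1 outputs —
the real run included, which makes the null conservative — and records
the group-average d per timepoint; 10,000 draws at full scale, 1,000 in
the desk-scale configuration (30 shuffles instead of 150). Percentiles
use linear interpolation between order statistics (stated because it
changes thresholds for small nulls). Two threshold modes exist:

* `group_average` (default, the literal procedure): the scalar threshold
  is the window maximum of the per-timepoint 95th percentiles of the
  bootstrap group-average distribution;
* `single_trial_pool`: the 95th percentile of the pooled single-trial
  peak d values from the shuffled runs — matched in variance to the
  quantity actually being thresholded, hence far stricter.

The default follows the group-average construction even though it is
thresholding single-trial peaks; since group averages have much smaller
variance, essentially all genuine single-trial peaks pass, which matches
the near-zero exclusion rates this analysis reports in practice.

## Peak analysis

Per trial and classifier: the maximum *positive* d in the selection
window, earliest-time tie-breaking (deterministic, and biased identically
for both classifiers so paired differences are unaffected). Where the
method's descriptions diverge — "absolute peak" versus "maximum
positive" — the maximum-positive reading is used, because the downstream
threshold is defined on positive chance exceedance. All-negative trials
are flagged absent. Thresholding is strict (peak_d > d\*); trials failing
for either classifier are excluded from pairing. The RT ≥ 3000 ms filter
is applied to retrieval epochs *before* decoding: the d values of
excluded trials are never used, and training sets then match the
analysed trial population.

## Group statistics

* **Clustered Wilcoxon signed rank.** Ranks of |Δ| pooled across
  clusters (ties averaged, zeros discarded), statistic = sum of signed
  ranks, null from jointly flipping each participant's signs (2000
  draws), add-one p value — exactly valid under cluster-level sign
  symmetry. With singleton clusters this reduces to the ordinary
  permutation signed-rank test (verified against exhaustive
  enumeration). At least two clusters are required.
* **Mixed models.** statsmodels has no frequentist gamma-family
  random-effects GLMM, so the module's contract is implemented with GEE:
  gamma/identity (latencies, RTs) or binomial/logit (accuracy) marginal
  models with an exchangeable — compound-symmetry — working correlation
  over participant clusters and cluster-robust standard errors; Wald
  statistics are referred to t/F with n_clusters − n_params denominator
  degrees of freedom as a small-sample guard. If the exchangeable fit
  fails the model falls back to an independence working correlation (the
  analogue of dropping a random structure that cannot be estimated).
  Constant-response cells raise an explicit degeneracy error rather than
  a numerical crash. Joint encoding + retrieval peak models first
  z-score latencies within phase and add 1000 ms (the two phases' scales
  differ by an order of magnitude; the offset keeps the gamma response
  positive).
* **Repeated-measures ANOVA.** The 2 × 2 interaction F is the squared
  paired t of the per-participant double-difference contrast, df
  (1, n − 1); cross-checked against statsmodels' AnovaRM. Zero error
  variance is reported as an exact fit (F = ∞, p = 0) or F = 0 for
  identical cells.
* **RT outliers.** Correct trials only, then ±2.5 SD around the group
  mean per task; zero SD removes nothing.

## ERP cluster permutation

Per participant, condition-mean difference maps; paired t across
participants per channel × timepoint. Cluster forming threshold: the
two-tailed paired-t critical value at α = 0.05 (the conventional default
of this family of tests). Suprathreshold points must have ≥ 2
spatially neighbouring channels suprathreshold with the same sign at the
same timepoint (applied as a one-pass point filter, so a spatially
isolated effect can never be reported). Clusters are connected
components under "same channel, adjacent timepoint ∨ neighbouring
channel, same timepoint"; score = sum of member t values; the null is
the maximal |score| under participant-level sign flips (2000 draws,
paired-design exchangeability; the identity permutation reproduces the
observed maximum). Channel neighbourhoods come from Delaunay
triangulation of the 2-D layout with edges pruned at 1.5 × the median
edge length; any symmetric, self-free adjacency can be supplied instead.
Response-locked data are scanned in 300 ms sub-epochs over −3000…+100 ms
(the last sub-epoch may be shorter), corrected within sub-epoch. The
peak-time ANOVA uses, per contrast, the cluster with the lowest
corrected p, extracting each participant's maximal |difference| latency
over that cluster's channels but the *entire* phase window.

## Problem sizes used in validation

The recovery suite runs the full pipeline at the default geometry over
ten seeds with the desk-scale null; calibration checks use 8
participants × 32 trials (threshold and signed-rank type-I, 400/20
replicates), 10 participants × 16 channels × 64 timepoints (cluster
permutation, 100 null runs), and 24 participants per task × 256 trials
(mixed-model recovery, with a 16 × 64 geometry for the 200-replicate
type-I run). `scripts/acceptance.py` re-runs the same computations at
one seed.

## Known limitations

* Spatially independent noise understates the benefit LDA draws from
  whitening correlated real-EEG noise, and overstates the independence
  of channels; no artifacts, no volume conduction.
* The GEE marginal formulation matches the compound-symmetry assumption
  but does not estimate participant-level random slopes; planned
  contrasts are refit per task rather than derived from one joint
  covariance.
* The group-average null threshold is deliberately permissive for
  single-trial peaks (see above); the stricter pooled-peak mode is
  available but not the default.
* Cluster-forming α and the exact neighbour template are conventions;
  cluster-level inference is only about the maximal cluster statistic,
  not about the precise extent of any cluster.
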