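# Methods

This note documents the models, numerical choices, and limitations behind
`mobidt`, in the spirit of a methods appendix: what each stage assumes, which
knobs matter, what the synthetic cohort does and does not emulate, and where
the design was genuinely open.

## The experimental design being modelled

A cohort (default 26 participants) performs blocks of 240 Go/NoGo trials —
209 Go, 31 NoGo (13%) — at a fixed 1017-ms stimulus-onset asynchrony, with
67-ms stimuli, once seated and once walking on a treadmill (7 blocks per
motor condition).  A NoGo trial is an immediate repeat of the preceding
image, so the generator never opens a block with a NoGo and never places two
NoGo trials back to back; NoGo positions are otherwise uniform over the
admissible sets.  Gait is observed through two heel markers at 360 frames/s;
a single-task (ST) walking condition without the cognitive task accompanies
the dual-task (DT) walking blocks.  EEG is recorded from the 64-channel
10–20 montage (positions taken from the standard BioSemi-64 layout, fitted
to a sphere and normalized).

## Behavioral scoring

Responses at or before 183 ms post-onset are treated as delayed responses to
the previous trial (the cutoff is exclusive: a 183.1-ms response survives).
Rates are pooled over all blocks of a motor condition, giving one hit rate
and one false-alarm rate per participant-condition, hence one
d′ = Φ⁻¹(HR) − Φ⁻¹(FAR).  At boundary rates (0 or 1) the rate is replaced
by the log-linear corrected (k + ½)/(n + 1); the correction touches only the
degenerate rate, preserving the antisymmetry d′(HR, FAR) = −d′(FAR, HR).
The epoch-eligible correct rejections and false alarms are those preceded by
a hit, guaranteeing the inhibitory component was engaged.

**Improver classification.** A participant is IMP iff their
walking-minus-sitting d′ change exceeds z₀.₉₇₅ · σ̂, where σ̂ is the n−1
sample SD of the whole cohort's changes (candidate included).  The band is
two-sided but only positive exceedance counts as improvement; significant
decline is grouped with nIMP.  A structural caveat follows directly from
the definition: if a fraction p ≈ ½ of the cohort improves by δ, the cohort
SD approaches √(p(1−p))·δ, so the threshold sits at ≈ 0.98 δ and the
criterion can never stably label half a cohort IMP.  Under the default
conditions it labels roughly half of the true improvers (with perfect
purity — the nIMP mode sits many SDs below the bound).  The pipeline applies
the criterion exactly as defined and reports what it yields; the cohort
table keeps the generating group alongside the label so users can audit the
gap.

## Gait variability

Heel strikes are local maxima of the fore-aft (Z) position with topographic
prominence above 0.1 m, computed on the raw series; a cycle spans
[strike_k, strike_{k+1}).  Cycles with a kurtosis statistic (max across the
three axes of the per-axis Pearson kurtosis) more than 5 SD from the mean of
the participant-condition pool (both feet) are rejected; removing a cycle
makes its neighbours adjacent.  Surviving cycles are linearly resampled to
100 phase points and compared stride-to-stride within foot by classical DTW
(3D Euclidean local cost, symmetric steps, no window, no path-length
normalization — equal input lengths remove the bias a normalization would
correct).  The per-participant measure is the mean over all pooled
consecutive-stride distances.  The DP kernel is numba-compiled with an
equivalent pure-Python fallback; both are checked against an exhaustive
warping-path enumeration for short trajectories.

Open choices made here: the axis over which cycle kurtosis is computed is
unspecified in standard descriptions, so the max-over-axes rule (the most
conservative detector) was adopted; outlier statistics are pooled across
feet per participant-condition.

## EEG preprocessing

* **Filtering**: Chebyshev Type II, designed from passband/stopband edges at
  1-dB ripple and 65-dB stopband attenuation, applied forward-backward
  (zero net phase, doubled attenuation).  The ERP path is a 45-Hz lowpass
  (stop edge 50 Hz) with **no highpass** — epoch baselines handle slow
  drift, avoiding high-pass distortion of ERP components.
* **Downsampling** 2048→512 Hz: the anti-aliasing lowpass puts its stopband
  at the target Nyquist (256 Hz) and passband at 0.8× that, then decimates.
* **Bad channels**: four across-channel screens — kurtosis, mean negative
  log-probability of the channel's samples under the pooled amplitude
  histogram, band-averaged log-spectrum (all at 5 SD), and mean absolute
  covariance with the other channels (±3 SD, two-sided; catches both noisy
  and flat/disconnected channels).  Zero across-channel SD disables a
  screen.  The "probability" statistic is a documented interpretation of
  the toolbox-style joint-probability screen; no exact formula is canonical.
* **Interpolation**: order-4 spherical splines (Legendre series to 50 terms,
  1e-5 Tikhonov regularization) on the unit sphere; cross-checked against an
  independent spherical-spline operator in the tests.
* **Epoching**: stimulus-locked [−200, 800] ms with [−100, 0] ms baseline
  (correct rejections); response-locked [−500, 500] ms with [−400, −300] ms
  baseline (false alarms).  Events too close to the recording edges are
  skipped and logged.
* **Epoch rejection**: any of — |V| > 150 μV; per-channel kurtosis or
  Gaussian log-probability beyond 5 SD across epochs; band power deviating
  from the across-epoch mean by ±50 dB at 0–2 Hz (eye movements) or by
  +25/−100 dB at 20–40 Hz (muscle).  Statistics are computed once on the
  incoming set, rules evaluated in a fixed order, and the log records every
  rule that fired — so rejection is deterministic and idempotent.
* **ICA hook**: independent-component decomposition plus component labelling
  requires a trained classifier and is deliberately a pluggable pass-through
  (identity by default).

## Cluster statistics

Within participant, walking-minus-sitting difference waveforms are formed
from condition-mean ERPs; one-sample t-maps (df = n−1) are computed per
electrode-timepoint, with zero-variance cells guarded to a signed finite
sentinel.  Clusters connect supra-threshold points that share an electrode
at consecutive timepoints or are montage neighbours at the same timepoint;
the neighbour graph links electrodes within 0.55 rad on the unit sphere
(≈6 mean neighbours on the 64-channel montage, the density of common
toolbox neighbourhood templates; the radius is a recorded config knob).
Cluster score is the weighted cluster mass Σ(|t| − t_thresh)^w with w = 1 by
default (the exponent is configurable since the statistic admits a family);
the cluster-forming threshold is the parametric two-tailed t quantile at the
cluster significance level (0.05).  The Monte-Carlo null flips the sign of
whole participants — the exchangeability implied by the paired design after
within-subject differencing — and records the per-sign maximum mass;
cluster p = (1 + #{null ≥ observed})/(1 + n_perm), doubled for two-sidedness
and capped at 1.  Sign flips are vectorized by exploiting that Σx² is
flip-invariant, so each permutation costs one matrix product plus a sparse
connected-components pass over the supra-threshold subgraph.

Family-wise error under an exchangeable null is calibrated (the acceptance
suite measures the rate of datasets with any cluster p ≤ 0.05 over 200
simulated cohorts × 500 permutations and requires it inside the binomial
95% CI of 0.05), and injected component-window deltas are recovered with
correct sign and ≥50% footprint overlap in ≥95% of simulations.

## Scalar statistics and FDR

Paired contrasts are routed by a Shapiro–Wilk gate (α = 0.05) to a paired t
or a Wilcoxon signed-rank test (tie- and continuity-corrected normal
approximation; below n = 5 the parametric branch is used as the
approximation is meaningless there).  Effect sizes follow the reporting
conventions d = t/√n (paired), pooled-SD d (independent), and
r = |z|/√(2n); the Wilcoxon z carries the sign of the paired difference.
The 2×2 mixed ANOVA uses the classical univariate decomposition (group
against subjects-within-groups; condition and interaction against the
subject×condition error), which conserves SS_total exactly and therefore
supports classical η² = SS_effect/SS_total; with unequal group sizes this is
the weighted-means analysis.

The combined FDR set contains, by default, the three group-level tests, the
independent t on average d′, three p-values per ANOVA (two mains, one
interaction), and the minimum cluster p of each of the six EEG comparisons
(cohort/IMP/nIMP × correct-rejection/false-alarm) — 16 p-values when all
comparisons run; comparisons with no clusters contribute nothing, and the
composition is configurable.  Control is the two-stage
Benjamini–Krieger–Yekutieli step-up procedure (stage 1 at q/(1+q) estimates
the number of true nulls; stage 2 reruns the step-up at the adjusted level)
via statsmodels, validated against an independent implementation.  One
property worth noting: the two-stage procedure is *not* guaranteed to reject
a superset of plain BH at the same q — when stage 1 rejects nothing the
procedure stops, while BH at q may still reject; the guaranteed superset is
against BH at the stage-1 level q/(1+q), and that is what the tests assert.

## The synthetic cohort

The generator encodes the study conditions the analysis is meant to
recover; its defaults are fixed, not tuned per run:

* **Behavior**: truncated-normal RTs (floor 100 ms), improvers faster
  (365/370 ms sitting/walking vs 400/412 ms, SDs 45–62 ms; cohort-weighted
  means ≈381/389 ms); hit/FA rates give d′ ≈ 2.26 when seated for both
  groups, with improvers dropping their false-alarm rate to 0.08 while
  walking (d′ ≈ 3.3) and non-improvers unchanged.
* **Gait**: each stride is a template heel path (≈1.1-m fore-aft sweep,
  double-bump vertical, small lateral sway) plus a smooth random
  displacement field with pointwise SD equal to the jitter knob, plus a
  small jitter-scaled time warp.  Empirically mean DTW ≈ 150 × jitter;
  defaults (16.5/14 mm ST/DT for improvers, 19/17.5 mm for non-improvers)
  place the four cells in the 2.0–2.8 m range with DT below ST.
* **ERP**: raised-cosine component templates with Gaussian scalp projection —
  frontocentral N2 ([200, 350] ms, −4 μV) and centroparietal P3
  ([350, 600] ms, +8 μV) stimulus-locked; frontocentral ERN ([−50, 100] ms,
  −6 μV, peak +50 ms) and central premovement positivity ([−210, −50] ms,
  +4 μV) response-locked.  Walking-minus-sitting deltas (+1.5 to +2 μV
  frontocentrally in the N2/ERN/premovement windows, −1.5 μV
  centroparietally in the P3 window) are injected for improvers only, as
  flat offsets so zero-noise runs recover them exactly.  Noise is
  1/f (exponent 1, 6 μV) plus white (4 μV), mixed across channels by a
  Gaussian spatial kernel (0.6 rad) with per-channel SD preserved — the
  spatial correlation is a knob because cluster tests are sensitive to it.

What the generator does **not** emulate: continuous raw EEG with embedded
events (epochs are produced directly; the BDF reader exists for real data),
ocular/muscle artifact morphology (rejection tests plant artifacts
explicitly), stride-time drift and marker dropout, stimulus-content effects,
and any coupling between gait phase and EEG noise.  Passing tests therefore
demonstrate correctness of the analysis chain under its stated statistical
assumptions, not robustness to every pathology of real mobile recordings.

## Problem sizes and determinism

The default configuration mirrors the study scale (26 participants, 7
blocks × 240 trials per condition, 5000 permutations, 512-Hz epochs).  The
demo/acceptance run scales where scale is statistically inert: 128-Hz
epochs, 80 correct-rejection / 48 false-alarm epochs per condition, 60-s
gait traces, 1000 permutations — chosen as the package's standard quick-run
sizes.  In that run the whole-cohort correct-rejection comparison yields a
significant cluster, the false-alarm comparison is marginal, and the
labelled-IMP subgroup (n ≈ 6, by the classification caveat above) is
underpowered for sign-flip inference — an honest consequence of the
criterion, not a failure of the cluster machinery, which recovers
ground-truth-group effects reliably in the dedicated tests.

Everything is driven by one integer seed through spawned generator streams:
identical seeds reproduce byte-identical streams, reports, and manifest
digests.  Permutation p-values use the +1 correction and so never return 0.

## Known limitations

* The improver criterion's half-cohort instability (above) is inherent to
  its definition; alternative splits (median, bimodality-based) are out of
  scope.
* The Wilcoxon z is the continuity-corrected normal approximation even for
  moderate n; exact p-values are available per call but not used for effect
  sizes.
* Bad-channel "probability" and epoch "probability" screens are reasonable
  formalizations of toolbox practice, not bit-compatible reimplementations.
* Cluster geometry depends on the neighbour radius and mass exponent; both
  are recorded in output metadata, and cluster shapes should be compared
  across settings before strong topographic claims.
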