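# Methods

This note documents the models, numerical choices and limitations of the
`infantmmr` pipeline, and what the synthetic-data generator does and does not
emulate.

## Montage and coordinate system

Eleven scalp channels (F5, Fz, F6, C5, Cz, C6, P5, Pz, P6, M1, M2) on a unit
sphere with +X right, +Y anterior, +Z superior; "leftward shift" therefore
means ΔX < 0. The coordinates are frozen constants derived from a standard
10-10 template: a sphere was fitted to the template positions, left/right
homolog pairs were symmetrized, midline X was set to exactly 0, the set was
rotated so Cz sits at the vertex (0, 0, 1), and every vector was normalized
to unit radius. Because all topographic results are *relative* displacements
of an amplitude-weighted centroid, any self-consistent standard coordinate
set gives the same displacement structure; the absolute positions carry no
claim about anatomy. Continuous data are exchanged in the package's HDF5
container (channels × samples in µV plus montage and subject metadata) with
events as TSV (`onset_sample`, `label`), keeping fixtures plain-text
friendly.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes, with
analytically known ground truth:

- **Oddball sequences.** After a deviant the next label is forced standard;
  otherwise a deviant is drawn with p′ = p/(1−p), which makes the marginal
  deviant rate equal the nominal p (0.15 by default, so a 600-trial block
  yields ≈ 510 standards and ≈ 90 deviants). Stimulus-onset asynchrony is
  stimulus duration + ISI (400 + 1200 ms).
- **ERP morphology.** Components are Gaussian bumps
  amp · topo_c · exp(−(t−lat)²/2w²). Defaults: P1 at 200 ms (width 40 ms),
  N1 at 350 ms (45 ms, negative), P2 at 620 ms (60 ms), each with a
  frontocentral topography normalized to sum 1. Component amplitudes are
  specified before the topography weights; the defaults give vertex-montage
  peaks of roughly +6/−4/+5 µV and a 1–2 µV MMR, the infant CAEP scale.
  Gaussians were chosen because their peak latency, amplitude and weighted
  centroid are known in closed form, making recovery tests exact.
- **Mismatch structure.** The deviant response is the standard response plus
  one additive MMR component per language condition (native stronger than
  nonnative by default), so deviant − standard equals the injected MMR
  template identically.
- **Maturation.** A per-session latency shift (default −30 ms/session,
  matching the observed P1 speed-up) and per-component topographic centroid
  drifts. A centroid drift is realized by re-solving the channel weights:
  minimize ‖w − w₀‖² subject to w ≥ 0, Σw = 1 and Cᵀw = target centroid
  (penalized nonnegative least squares), which makes the injected
  displacement exact rather than approximate.
- **Noise and artifacts.** 1/f-spectrum Gaussian noise via FFT shaping,
  default 15 µV per channel with ~10% lognormal heterogeneity across
  channels (real caps never have identical noise floors; perfectly equal
  variances would also make any variance-based bad-channel rule degenerate).
  With probability `artifact_rate` per stimulus epoch one artifact is
  injected: a 400–600 µV smooth excursion, an abrupt ~2 mV sustained offset,
  or a high-kurtosis spike burst — each sized to still violate at least one
  rejection rule *after* the 1–18 Hz filter.
- **Subjects.** Stable per-subject amplitude intercepts (SD 8 µV before
  topography weighting) and a stable latency offset (SD 15 ms), matching the
  random-intercept assumption of the group model. Cohort attendance is
  accelerated-longitudinal: per-session subject counts (default 59/72/46
  from a pool of 83) drawn from a common pool, so subjects overlap but few
  attend all sessions.

What the generator does **not** emulate: real infant EEG nonstationarity
(sleep-state changes, movement epochs clustered in time), acoustic stimulus
structure, volume-conduction physics (topographies are abstract weight
vectors, not dipole projections), amplifier differences, or channel-specific
drift. Passing recovery tests therefore demonstrates that the estimators are
correct and calibrated under the model's assumptions, not that those
assumptions hold in any particular infant dataset.

## Preprocessing

Fixed order: resample to 1000 Hz (event onsets rescaled) → bad-channel
detection → band-pass → epoch → reject → resample to 250 Hz → baseline →
spatial PCA → re-baseline.

- **Filter.** scipy Butterworth of order 4 (`butter(4, [1, 18])`), applied
  forward–backward (`sosfiltfilt`), i.e. zero-phase with the squared
  magnitude response; passband gain at 10 Hz is 0.997 and stopband gain at
  50 Hz ~2·10⁻⁴. Filtering happens on continuous data so epoch edges carry
  no filter transients.
- **Bad channels.** Only signal-based proxies are possible (impedance is not
  in the data stream): near-zero variance (flat) or log-variance z-score
  above threshold (default 3) *and* variance above 4× the channel median.
  The absolute floor matters: in a homogeneous montage the across-channel
  variance spread is tiny and a pure z-score would flag whichever channel
  carries the most evoked signal. Flagged channels are dropped, not
  interpolated — with 11 channels spherical interpolation is poorly
  conditioned — and CoM weights renormalize over the survivors. More than a
  third of channels flagged is fatal.
- **Rejection.** A trial is rejected if any channel violates any rule.
  The kurtosis rule is operationalized as the per-trial-channel excess
  kurtosis z-scored against that channel's across-trial distribution,
  |z| > 5 (the printed rule names only "kurtosis > 5 SD from the mean").
  Reason codes record the first violated rule in the order voltage, step,
  kurtosis. Manual inspection is replaced by an optional user-supplied
  rejection list. Raising the voltage threshold can only reduce rejections.
- **Spatial PCA.** Per subject × session × language, over all retained
  epochs jointly (standard and deviant share one subspace): z-score each
  channel over retained trials × time, eigendecompose the channel
  covariance, keep the smallest leading set reaching 95% cumulative
  variance, project and back-project, undo the z-scoring, re-apply baseline
  correction. `var_retained = 1` is the identity by construction.

## Trial matching

Preceding-standard matching walks backward from each retained deviant to the
nearest earlier retained standard not already used; a deviant with no
available earlier standard is dropped (logged). This fallback preserves the
temporal-proximity rationale when the immediately preceding standard was
rejected. Matching runs after rejection — pairing with a rejected trial
would be meaningless. The random strategy samples standards uniformly
without replacement, seeded.

## ERP estimation and per-timepoint inference

The bootstrap resamples trials with replacement (realized as multinomial
trial counts, so each iteration is a weighted trial mean); the estimate is
the mean over 10,007 iterations with elementwise 2.5/97.5 percentile CIs.
Coverage of the percentile interval at n = 50 Gaussian trials is ≈ 0.94,
the expected mild undercoverage of percentile bootstrap at moderate n.

Trial-level inference uses the vertex montage — mean(Fz, Cz) −
mean(M1, M2) — the montage used for peak measurement; the Bayes factor is
the two-sample JZS BF₁₀ with Cauchy prior scale √2⁄2 computed by adaptive
quadrature over the prior's inverse-gamma mixing variable (cross-checked
against an independent implementation to ~10⁻⁴ relative error). The t-tests
are Student (equal-variance) unpaired, as a paired structure is not assumed
at the trial level, with a paired option available; BH adjustment runs
across the full epoch series, and a timepoint with zero pooled variance
yields NaN with a warning rather than an error. The window-maximum BF is
taken over 150–450 ms, and its group analysis uses the natural log.

## Peak measurement

Candidates are strict local extrema of the required polarity whose amplitude
sign matches that polarity (an N1 pick can never be positive). Thinning
visits candidates in decreasing prominence (earliest latency on prominence
ties) and keeps each candidate at least 80 ms from every kept one. The
winner maximizes prominence × SNR, where SNR = |amplitude| / SD of the
pre-stimulus baseline of the same waveform (the SNR definition is a package
choice; the source convention is unspecified). Score ties break to the
earliest latency, making picks deterministic. The MMR search runs both
polarities and keeps the better-scoring sign, since infant MMRs can be
positive or negative. "No extremum in window" is a value (`found = False`),
not an error; such rows are excluded from group tables with a log entry.
Search windows are configuration constants, not re-derived per dataset, so
results are deterministic and comparable across cohorts.

## Topography

Component weights are the mean over subjects of |amplitude| at the
group-mean component latency, read from each subject's channel waveforms
(nasion-referenced; the vertex re-reference is used only for peak
measurement). Using one group latency keeps the weight vector comparable
across channels; per-channel latencies would conflate latency and amplitude
topography. All 11 channels enter the CoM, including the mastoids.
Obligatory-component CoMs are computed from standard-waveform amplitudes
(per condition and pooled "combined"), the MMR CoM from the difference
waveform. Displacement bins are left-closed as printed (0.05 is "moderate").
A CoM is a convex combination of unit vectors, so its norm never exceeds 1 —
asserted on every computation. With realistic noise the |amplitude| weights
carry a folded-normal bias toward the montage centroid; the bias is common
to both sessions and mostly cancels in displacements, but it makes
small-trial-count CoMs noisy — the recovery experiments therefore run at the
paradigm's ~600-trial scale.

## Mixed-effects analysis

Each measure is modeled as `value ~ Session × Language + (1 | subject)` with
sum-to-zero contrasts (T1/native reference order fixed), fit by REML. The
implementation profiles the residual variance analytically and optimizes the
single variance ratio numerically (bounded scalar search on the log scale),
using per-group Woodbury identities for the compound-symmetric covariance.
Type III marginal F-tests of each coefficient block use Satterthwaite
denominator degrees of freedom: each contrast's variance is differentiated
numerically with respect to (σ², σ_b²), and the variance-parameter
covariance comes from the inverse observed information of the REML
criterion (central finite differences). Multi-df contrasts combine
eigenvalue-wise candidate dfs as 2E/(E−q) with E = Σ νᵢ/(νᵢ−2). On
unbalanced factorial data this reproduces `lmerTest::anova(type=3,
ddf="Satterthwaite")` to four significant figures (tested against R).
A variance ratio estimated at the zero boundary triggers a warning and
degenerates smoothly to the fixed-effects ANOVA, which the tests verify
against a Type III OLS oracle. Partial η² = F·df₁/(F·df₁+df₂), reported to
3 decimals. α = 0.05 with no multiplicity correction across the 14
interaction tests, matching the reporting convention this pipeline mirrors
(a caveat worth keeping in mind when interpreting a single borderline
interaction). A constant response vector returns F = 0 for every term
rather than failing.

## Calibration experiments (scripts/acceptance.py)

All experiment sizes were chosen to keep the whole script under a few
minutes on one CPU while holding Monte-Carlo error well below each decision
band: 1,000 oddball sequences; 500 epochs for the rejection oracle; 200
bootstrap-coverage replicates of 50 trials; 500 global-null FDR replicates;
1,000 random waveforms for peak-picker equivalence; 20-subject cohorts at
400 trials/block for CoM recovery; 500 null and 100 effect cohorts (n = 40,
between-subject SD 15 ms, residual SD 15 ms) for mixed-model type-I error
and power — at 500 replicates the type-I Monte-Carlo SE (~0.01) is small
against the [0.025, 0.075] acceptance band, so the check reflects the
method's calibration rather than simulation noise. The end-to-end
determinism check runs the full pipeline twice on a 3-subject cohort and
compares result CSV bytes.

## Known limitations

- The spectral step rule is largely vestigial after 1–18 Hz filtering: a
  physical step must exceed ~1.4 mV to retain a 50 µV sample-to-sample
  difference post-filter, so most step artifacts are caught by the voltage
  rule instead. The rule is kept for fidelity to the documented procedure.
- Overlapping component tails shift composite-waveform extrema slightly away
  from injected latencies; recovery tests compare against the analytic
  extremum of the summed template, not the isolated-bump latency.
- No source localization is attempted or implied; CoM summarizes the
  surface voltage distribution on an 11-electrode montage.
- No random slopes or growth-curve structure in the group model; the random
  intercept matches the generator and the mirrored analysis plan.
- Bad-channel detection cannot see impedance; only signal-based proxies are
  implemented.
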