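# Methods

## Measurement model

The pipeline assumes single-foot treadmill running data: a vertical
ground-reaction-force trace sampled at 1000 Hz and a sagittal foot
segment-angle trace at 200 Hz (dorsiflexion positive), plus a standing
static trial that defines each runner's foot-flat reference. Stride time is
foot-strike (FS) to foot-strike of the *same* foot; contact time t_c runs
from FS to toe-off (TO), swing time t_s from TO to the next FS. The duty
factor is DF = t_c/(t_c+t_s) = t_c·SF with SF the stride frequency. The
foot-strike angle (FSA) is the rescaled foot angle at the FS instant.

### Event detection

FS is the first force sample ≥ 20 N within a step and TO the last sample
≥ 20 N of the same step. Contacts shorter than 25 ms are discarded as noise
artifacts, as are partial contacts touching a trace boundary. At the
threshold-0 limit a contact is the strictly positive support of the force
(otherwise zero-force swing samples would merge all steps).

Detection runs on the **raw** 1000 Hz force by default. This is a
deliberate choice: a zero-phase 20 Hz low-pass spreads each contact pulse
outward, which moves the 20 N crossings several milliseconds into the swing
phase and biases DF upward by roughly +0.01 — twice the discretization and
threshold-crossing bias combined. The raw-force bias is ≤ ~1 ms per edge
(one sample plus the analytic crossing shift 2·asin(20/F_peak)·t_c/π).
Whether the original motion-capture tool detected events before or after
filtering is not documented, so both alternatives are exposed
(`detect_on_filtered`, `detect_at_kinematic_rate`); the filtered force is
still what feeds the 200 Hz downsampled copy.

### Conditioning

Kinematic dropouts up to 20 frames are filled by evaluating a cubic
least-squares polynomial fitted to 3 valid frames on each side; longer or
boundary-adjacent gaps stay missing and are reported. Both signal types are
filtered with a 4th-order low-pass Butterworth at 20 Hz, applied forward
and backward by default. Zero-lag filtering preserves event timing; the
stated order is per pass, so the two-pass magnitude response corresponds to
an 8th-order filter — documented, not compensated. Decimation to the
kinematic rate keeps every 5th sample and requires an integer rate ratio.

### FSA extraction

The scalar mean of the static trial is subtracted from the running trace
(so an arbitrary mounting offset cancels — rescaling is translation
equivariant), and the rescaled trace is sampled at the nearest kinematic
sample **at or before** each force-detected FS: contact decisions should
not use future frames. Per-runner values are the arithmetic means over the
first 10 strides; for DF the mean of per-stride ratios is primary and the
ratio of means is also emitted for sensitivity checks (they differ only
under stride-to-stride variability).

## Classifications

* FSP thresholds: RFS iff FSA ≥ 8°, MFS iff −1.6° ≤ FSA < 8°, FFS iff
  FSA < −1.6° (boundaries included exactly as stated).
* Terciles, per speed: values sorted descending; the first ⌊n/3⌋ runners
  form the high group, the next ⌊n/3⌋ the mid group, and the remainder the
  low group — for n = 100 that is 33/33/34 with the extra runner in the low
  group. Ties straddling a boundary are resolved by the stable order of
  runner ids and logged; the scheme is invariant to any strictly increasing
  transform of the values. An absolute-FSA tercile variant is computed
  alongside the threshold FSP.

## Concordance statistics

The 3×3 FSP×DF table is collapsed to three 2×2 tables, one per
presumed-corresponding pair. With cells tp/fn/fp/tn: agreement = (tp+tn)/N,
sensitivity = tp/(tp+fn), specificity = tn/(tn+fp). The identity
agreement·N = sensitivity·(tp+fn) + specificity·(tn+fp) holds exactly and
is property-tested.

**Binomial CIs.** The default 95% interval is the normal approximation
(Wald), truncated to [0, 1]. Although the reference analysis describes its
intervals as "binomial exact", recomputation shows every printed bound
matches the Wald formula (e.g. 70/100 → (61, 79); 15/27 → (37, 74)) and not
Clopper–Pearson. Both methods are implemented (via
`statsmodels.stats.proportion.proportion_confint`); Clopper–Pearson is
cross-checked in the tests against brute-force binomial tail inversion to
1e-6. The discrepancy is documented rather than silently resolved.

**Published midfoot agreement.** The published MFS–DF_mid agreements
(76/81/85% at 9/11/13 km/h) cannot be derived from the published counts,
which give 57/62/66% — a constant +19-point offset — while the MFS
sensitivities and specificities *are* derivable. The package reports the
count-derived values and `compare_with_published` flags the three
mismatches explicitly. Consequently the count-derived average agreement is
66%, not the published 73% (which requires the printed MFS values); the
average sensitivity (49%) and specificity (75%) reproduce either way, as
unweighted means of the nine per-speed, per-pair values before rounding.

Report tables round percentages half-away-from-zero to integers; full
precision is kept on every result object. Chi-squared homogeneity uses the
Pearson statistic without continuity correction; Pearson CIs use the Fisher
z transform; Cohen's d uses the (n−1)-weighted pooled SD. Interpretation
bands: |r| at 0.30/0.50/0.70/0.90, and |d| bands cut midway between the
anchors 0.01/0.2/0.5/0.8 (at 0.105/0.35/0.65).

## Synthetic cohort generator

The generator's defaults *are* the study conditions: 100 runners at 9, 11
and 13 km/h, 10 analysed strides per trial.

* **FSA marginal**: per-speed 3-component Gaussian mixture, one component
  per FSP group, weights from the observed group proportions and
  means/SDs from the published group statistics (e.g. at 9 km/h:
  0.27·N(13.3°, 2.9²) + 0.34·N(4.3°, 4.2²) + 0.39·N(−6.7°, 4.7²)).
* **DF marginal**: per-speed normal, mean/SD back-solved from the published
  tercile boundaries (the tercile edges of a normal sit at μ ± 0.4307σ):
  N(0.374, 0.025²) at 9, N(0.346, 0.027²) at 11, N(0.325, 0.024²) at
  13 km/h. Draws are clipped to (0.05, 0.495); with these parameters the
  clip is ~7σ away and effectively never binds.
* **Copula**: the FSA draw is mapped through the mixture CDF to a normal
  score z, and the DF score is ρ·z + √(1−ρ²)·ε with ρ = 0.45 by default
  (the published per-speed correlations span 0.39–0.48). Because FSA is
  non-normal the realized linear correlation is attenuated by a few
  hundredths (measured ≈ 0.44 at ρ = 0.45, n = 10⁴), well inside the ±0.05
  calibration tolerance. ρ = 1 is the comonotone limit (identical ranks);
  ρ = 0 gives independence. Mixture quantiles are computed by monotone
  interpolation of the CDF on an 8193-point grid spanning ±8 SD of every
  component.
* **Stride frequency**: N(1.40, 0.07²) Hz at 11 km/h, mean scaled by ±1%
  per km/h, drawn independently of FSA — reproducing the negligible FSA–SF
  correlation. No SF or body-mass summaries are published for the
  reference cohort; 1.40 Hz, 70 ± 7 kg body mass and the shoe distributions
  (257 ± 49 g mass, 7 ± 3 mm drop, r = 0.52 between them, independent of
  gait) are conventional recreational-runner values.
* **Between-speed coupling**: each runner keeps one latent score across
  speeds, perturbed per speed by jitter of SD 0.2 (rank correlation ≈ 0.96
  between speeds). Single-speed marginals and the FSA–DF correlation are
  unaffected; a minority of runners change tercile or FSP group between
  speeds, as observed in real cohorts.
* **Force waveform**: each contact of duration t_c = DF/SF is a half-sine
  with peak (π/2)·m·g/DF (g = 9.81 m/s²), which makes the stride-averaged
  force exactly body weight — the impulse identity tested to 0.1%. Swing is
  exactly zero before noise. Gaussian noise (default SD 5 N) is added and
  the trace truncated at 0 N.
* **Angle waveform**: offset + FSA + (A/2)·(cos 2π·SF·(t−t_FS) − 1) with
  swing amplitude A = 20°, so the curve equals offset + FSA exactly at
  every FS and has zero slope there — sampling at 200 Hz then incurs only
  second-order error (< 0.05° for the default timing). Angle noise SD
  0.2°; two short missing-frame gaps (2–8 frames) are inserted per trial,
  spaced so each keeps a full fit window, to exercise gap filling. The
  static trace is the constant mounting offset (drawn N(0°, 2°)) plus
  noise over 5 s.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: impact transients and loading rate, both
feet on one belt, stride-to-stride timing variability within a trial,
3D segment kinematics and soft-tissue artifact, force-plate drift and
crosstalk, and any systematic FSA dependence of contact time beyond what
the copula induces. Conclusions here are about the *analysis chain*, not
about human runners.

## Numerical choices and degenerate inputs

* Determinism: every random stream derives from the cohort seed
  (default 20220729, recorded in each manifest) via per-runner,
  per-speed, per-purpose child seeds; identical configs give
  bit-identical cohorts and byte-identical output tables.
* Noise-free recovery, measured over DF ∈ [0.27, 0.45] × FSA ∈ [−15°, 18°]:
  |DF error| ≤ 0.004 (budget 0.005), |FSA error| ≤ 0.002° (budget 0.2°).
* Zero denominators (a 2×2 with no negatives, constant correlation input,
  zero pooled SD) yield flagged NaN/undefined results or ValueError at the
  statistic level, never silent zeros.
* Trace containers reject non-finite force, non-positive rates and
  sub-2-sample signals; AngleTrace marks missing frames as NaN.

## Problem sizes

The test suite and acceptance script use: single trials of 12 contacts for
waveform checks; a 5×5 (DF × FSA) noise-free grid for end-to-end recovery;
n = 10⁴ latent draws for copula calibration and the independence limit;
500 cohorts of n = 100 for the calibrated Monte-Carlo sensitivity (which
lands near 47–50%, consistent with the reference headline of ~50%; the
exact published 49% is a property of the real cohort and is not claimed);
and one full 100×3 signal-level pipeline run. The whole suite completes in
well under a minute on one CPU.

## Known limitations

* The kinematic chain consumes a precomputed sagittal foot angle; the 3D
  Cardan-angle decomposition of a five-marker foot segment is out of scope.
  This is the one deliberate simplification of the measurement chain.
* Linear mixed models and Holm-corrected post hoc contrasts are not
  implemented; the exported tidy tables (`runner_metrics.csv`,
  `labels.csv`) are one-line fits in any statistics package.
* Classification is per speed only; no speed-pooled variant.
* The generator draws stride timing as exactly periodic within a trial, so
  within-trial DF variance is zero up to noise; per-stride outputs exist
  but their within-trial spread is not calibrated to anything.
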