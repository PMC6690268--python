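# Methods

## Measurement model

The unit of analysis is the 60 s epoch. During a calibration session a
participant wears one count-accumulating device per wrist while a portable
indirect calorimeter records energy expenditure; all instruments share a
clock, and timestamps are truncated (never rounded) to the containing minute
before alignment, matching the epoch-start convention of count accumulators.
Only minutes present in all streams are analyzed.

Energy expenditure is expressed in METs: the measured per-minute rate divided
by the participant's predicted basal metabolic rate (BMR) per minute
(BMR/1440). BMR is predicted from sex, age band and body weight with the
Schofield weight-only coefficients (MJ/day; 1 MJ = 239.006 kcal). Epochs are
classed sedentary (SB) strictly below 1.5 METs, moderate-to-vigorous (MVPA)
strictly above 3.0 METs, and light (LPA) in the closed band between —
boundary values 1.5 and 3.0 are light, per the strict inequalities that
define SB and MVPA. If a calorimeter export already contains METs, the
derivation path is bypassed. No steady-state VO₂ filtering is applied.

## Cut-point derivation

For one target intensity, epoch labels are coded 1 (epoch is of that class)
or 0, and counts per minute (CPM) are the score. Candidate thresholds are
exactly the observed score values plus ∓∞ sentinels, so a reported cut-point
is always an achieved integer CPM rather than a midpoint. Direction matters:
SB is predicted when counts ≤ threshold, MVPA when counts ≥ threshold, and
the reported bounds are inclusive in the same directions.

The SB bound maximizes the Youden index J = Se + Sp − 100 over the full
sweep. The MVPA bound maximizes J over thresholds whose false-positive ratio
is ≤ 0.10 (the inclusive boundary is the default because it is the variant
consistent with specificities of exactly 90%; a strict `<` is configurable).
The feasible set is never empty — the strictest sentinel predicts nothing
positive and has FPR 0. Maximization uses exact integer arithmetic
(tp·n_neg − fp·n_pos), so float rounding can never reorder mathematically
tied thresholds; ties are broken toward higher sensitivity, then toward the
more conservative activity estimate (lower SB bound, higher MVPA bound). LPA
is the open interval between the two bounds, and a crossing (SB ≥ MVPA) is a
hard calibration-inconsistency error.

AUC is the tie-corrected pairwise probability (Mann–Whitney form), identical
to the trapezoid area under the empirical curve. Variances and the
correlated-curve test use DeLong placement values: per-epoch structural
components whose empirical covariance gives var(AUC) and cov(AUC_a, AUC_b)
for two score streams sharing labels; Z = (AUC_a − AUC_b)/√(var_a + var_b −
2·cov) with a two-sided normal p. Identical streams return Z = 0, p = 1; a
vanishing variance with genuinely different AUCs raises a degenerate-variance
error rather than fabricating a statistic. Confidence intervals are normal
approximations clipped to [0, 1]. Epochs are pooled across participants
within each calibration cell; no within-participant clustering adjustment is
made (the analysis this package operationalizes pooled likewise).

## Agreement between wrists

Each epoch is one agreement target and the two wrists are the raters, pooled
across participants within a stratum slice; only epochs with counts on both
wrists enter (epochs with a single wrist remain usable for single-side
calibration). Statistics per slice:

- partial Pearson r of the two streams after removing per-participant means
  (equivalent to partialling out participant indicator variables);
- consistency ICC from two-way ANOVA mean squares, ICC(3,1) =
  (BMS − EMS)/(BMS + (k−1)EMS) and ICC(3,k) = (BMS − EMS)/BMS, with the
  F-based 95% interval of the two-way mixed model;
- Bland–Altman mean difference (affected − non-affected), sample (n−1) SD,
  limits mean ± 1.96·SD (multiplier configurable), and the slope of the
  difference on the pair mean as a proportional-bias diagnostic.

Qualitative labels use configurable half-open bins; defaults are ICC < 0.5
poor, 0.5–0.75 moderate, 0.75–0.9 good, ≥ 0.9 excellent, and AUC 0.5–0.7
low, 0.7–0.9 moderate, ≥ 0.9 high. The source criteria these emulate are not
fully specified numerically, so the tables are explicit configuration, not
constants.

## Stratified pipeline

Participants are stratified on the Fugl-Meyer motor total (0–100, upper
0–66 + lower 0–34): mild when total ≥ 79, else moderate-to-severe. The
pipeline derives six cut-point sets — {all, mild, moderate_severe} ×
{affected, non_affected} — and one agreement report per stratum. Epochs
lacking a MET value are excluded from calibration without imputation. A cell
whose slice lacks one of the three intensity classes aborts the run under
the default strict policy or is recorded and skipped under the permissive
policy. Outputs embed a hash of the resolved configuration for provenance,
and results are invariant to epoch order.

## Scoring

Applying a calibrated set to a count stream is a pure threshold rule: SB at
or below the SB bound, MVPA at or above the MVPA bound, LPA between. Every
epoch is scored (no non-wear detection, no bout rules), and summarized
minutes conserve total duration exactly.

## Synthetic cohort

The generator emulates the calibration session: 43 participants (29 mild,
14 moderate-to-severe), each performing four paced walks with 2 min seated
recoveries plus sitting, cleaning, bicep curls, chair squats, lying and
standing — 5 min per activity, 58 scheduled minutes per participant. With
the default 9% epoch dropout the expected cohort size is ≈ 2,270 epochs,
the scale of the study design this emulates.

Per epoch, METs are drawn log-normally around an activity-specific median
(medians straddle the 1.5 and 3.0 boundaries: lying 1.0 … brisk walk 4.3;
these are free parameters, not estimates of any real cohort). Expected
counts follow a strictly increasing piecewise-linear link f with planted
boundaries f(1.5) = 150 and f(3.0) = 650 CPM. Observed counts are
round(f(METs)·exp(ε)) with mean-corrected multiplicative noise whose deviate
is clipped at 2.5 SD (count accumulators saturate; an unclipped log-normal
tail produces maxima several times anything a wrist device reports). The two
wrists share a fraction ρ of the noise variance; the affected side is
additionally scaled by a per-participant attenuation λ drawn from a Beta
distribution around the stratum mean (λ_mild = 0.95, λ_modsev = 0.70,
concentration 50). Defaults count_log_sd = 0.80 and ρ = 0.30 were set so the
default cohort reproduces the agreement regime reported for this population
(ICC(3,k) ≈ 0.68, partial r ≈ 0.53) together with the documented qualitative
signatures: lower affected-side means in the moderate-to-severe stratum and
between-wrist disagreement growing with activity level.

What the simulator does **not** emulate: autocorrelation within an activity
bout, tremor/dysmetria artifacts, device-specific filtering, steady-state
VO₂ dynamics, or non-wear. Passing tests therefore demonstrate correctness
of the statistical machinery and recoverability of planted structure, not
the field accuracy of any particular device.

## Numerical choices and degenerate inputs

- Rates are carried as proportions internally and converted to percent only
  at the reporting boundary; J = Se + Sp − 100 holds exactly on every
  emitted metrics object.
- PPV/NPV with an empty denominator are reported as missing, never zero.
- Single-class label vectors, zero within-group variance, zero
  between-target mean square, and negative counts/METs raise typed errors.
- Boundary-recovery tests use a noise-free configuration (λ = 1, ρ = 1,
  zero count dispersion); the derived bounds then bracket the planted
  boundaries within one observed-count gap, with the MVPA error one-sided
  (≥ 0) because of the FPR ceiling. The noise-trend check uses dispersions
  0.1/0.2/0.4 over 20 seeds: in this moderate regime the recovery error is
  variance-dominated and grows with noise, whereas far larger dispersions
  make the mean-correction bias dominate and the trend uninformative.
- Monte-Carlo checks (DeLong null calibration, qualitative signatures) use
  2,000 and 10-seed designs respectively; the null rejection rate at
  α = 0.05 is required to fall in 0.05 ± 0.02.

## Known limitations

- The F-based ICC interval assumes the two-way mixed model with epochs
  pooled across participants; within-participant correlation of epochs makes
  the interval anti-conservative, as in the pooled design it mirrors.
- DeLong inference treats epochs as independent pairs; the same caveat
  applies.
- The Schofield age bands stop being weight-calibrated below age 3 and are
  extrapolated linearly above the last knot in the simulator's link.
- Vendor-native binary exports are out of scope; inputs are per-minute CSV
  summaries.
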