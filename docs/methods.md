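# Methods

## Entropy estimation

Sample entropy is computed from template-pair counts under the Chebyshev
(infinity) norm with a **non-strict** comparison (distance ≤ r), the
Richman–Moorman convention. Templates for dimensions m and m+1 are formed
over the *same* index range i = 1…N−m·lag, which makes the two counts
directly comparable: every (m+1)-match is an m-match, so n<sup>m+1</sup> ≤
n<sup>m</sup> holds structurally, SampEn ≥ 0 whenever defined, and a
constant series yields exactly 0. Self-matches are excluded and each
unordered pair is counted once.

Defaults: embedding m = 2, tolerance r = 0.2 × sample SD (ddof = 1),
lag 1, scales τ = 1–6 — the common operating point for ~2000-point trunk
acceleration records at 100 Hz. Entropy is computed on the first 2000
samples of longer traces; shorter traces are processed with a logged
warning and never padded. Input signals are used as recorded: no
detrending or filtering (mean removal would be a no-op for SampEn because
templates are compared to each other, not to a reference level).

**Tolerance across scales.** By default the tolerance is fixed once from
the SD of the *original* series and reused at every scale
(`r_mode="sd_original"`, the Costa convention), so the scale profile
reflects genuine structure rather than the shrinking variance of
coarse-grained series. `r_mode="sd_per_scale"` recomputes r per
coarse-grained series and is provided for sensitivity analysis only.

**Coarse-graining at arbitrary offset.** The offset-k series is the
sequence of means over non-overlapping width-τ windows starting at sample
k; its length is floor((N−k+1)/τ) with trailing partial windows discarded,
which generalises the usual divisible-length definition while preserving
non-overlap. τ = 1 returns the series unchanged, so MSE, CMSE and RCMSE
all equal plain SampEn at scale 1, bit-exactly (the implementation reuses
the very same count).

**Undefined values** (zero match counts) are first-class: they are NaN in
profiles, propagate through the complexity index, are surfaced per
(subject, axis, τ) in pipeline reports, and are never replaced by 0. CMSE
at scale τ is undefined as soon as *one* of its τ offset entropies is
undefined; RCMSE pools the counts and is undefined only when *every*
offset produced zero matches — hence RCMSE is defined whenever CMSE is,
and this gap is measurable on short series (at N = 100, τ = 6 the CMSE
undefined rate is far higher; the acceptance script reports both).

The **complexity index** integrates an entropy profile by the trapezoid
rule over unit-spaced scales, by default the full computed range 1–6 (the
integration range for reported CIs is not standardised in the literature;
the full range is the neutral choice and sub-ranges are exposed as
arguments).

## Diagnostic accuracy

The AUC is the tie-aware Mann–Whitney pair statistic computed from
midranks; its 95% CI uses DeLong's placement-component variance
(implemented directly; verified to 10 decimals against pROC's
`ci.auc(method="delong")` on a frozen fixture). AUC ≥ 0.70 flags
"sufficient" discriminative ability.

Candidate cutoffs are midpoints between consecutive distinct scores plus
sentinels beyond the range, with "score ≥ cutoff" called positive (or ≤
when lower values indicate disease). The optimal cutoff maximises
sensitivity + specificity, Youden and F1; when the criteria disagree the
candidate with the greatest PTP⁺ − PTP⁻ wins, remaining ties going to
higher specificity, then to the lower cutoff. Post-test probabilities use
the Fagan relation (pretest odds × LR), reported at the sample prevalence
and at a fixed 35% external prevalence. Likelihood ratios and PTPs keep
their exact 0/∞ endpoints; the diagnostic odds ratio is the exact
cross-product ratio, with a separate Haldane–Anscombe (+0.5 per cell)
estimate reported and the record flagged whenever a confusion cell is
empty.

## Cohort statistics

Propensity scores come from a maximum-likelihood logistic regression of
group on age and gait speed; zero-variance covariates are dropped (pure
intercept fit returns the sample patient fraction), and (quasi-)separation
triggers a warned fallback to an L2-penalised fit. Matching minimises the
**total** absolute propensity-score difference over all 1:1 assignments
(solved exactly via the rectangular assignment algorithm), with each
control subject contributing at most one of its two walking-speed trials.
Because a subject can contribute only one trial, it suffices to give each
(patient, subject) pair the subject's closest trial and assign over
subjects — this is equivalent to the trial-level constrained optimum. When
patients outnumber control subjects, every control subject is matched to a
distinct patient and the remaining patients stay in the analysis set, the
behaviour of a design that retains the full patient group and selects
which control trials enter. A greedy nearest-neighbour matcher is kept
only as a baseline for demonstrating the advantage of global matching.

Two-group comparisons use the Mann–Whitney U test (exact when
n₁·n₂ ≤ 400 and tie-free, otherwise the tie-corrected normal
approximation) with Cohen's d shrunk by Hedges' 1 − 3/(4N−9) factor.
Severity strata (< 32, ≥ 32, ≥ 58 on the motor score, half-open bins) are
compared by tie-corrected Kruskal–Wallis with two-sided Dunn z tests on
the pooled midranks and Holm step-down adjustment over the three pairs
(standard monotone Holm, i.e. with the cumulative-maximum step, as in
statsmodels). Partial Spearman correlations rank-transform all variables,
residualise the x- and y-ranks on the covariate ranks by least squares and
correlate the residuals (the ppcor/pingouin convention; equal to plain
Spearman when there are no covariates), with a t-approximate p-value on
n − 2 − k degrees of freedom.

## Synthetic data

Each trial is a harmonic sum per axis: six harmonics of the stride
frequency (0.86 Hz, cadence ≈ 103 steps/min), with AP/V weighting the even
(step-frequency) harmonics and ML the odd ones, the standard lumbar
accelerometry phenomenology. Irregularity enters three ways: a per-cycle
random-walk phase drift shared across axes (timing variability,
SD 0.12 rad/cycle), per-cycle amplitude rescaling (CV 0.08), and additive
white noise (SD 0.10 in harmonic-amplitude units). Stride frequency scales
with the square root of walking speed (walk-ratio scaling). These defaults
put healthy-like SampEn values in the 0.1–1.5 band across scales 1–6,
the plausible range for trunk-acceleration gait entropy.

Cohorts: 51 patients (one trial) and 50 controls (a self-selected-speed
trial plus a slower one at 0.75–0.9× speed), ages ≈ 71 ± 5 vs 69 ± 5
years, speeds ≈ 1.08 ± 0.25 m/s, so the matching stage faces a realistic
covariate landscape. Every subject carries a lognormal irregularity factor
(σ = 0.4 on the log scale, both groups): without between-subject
heterogeneity all controls would be statistically identical and any group
effect would separate perfectly. Patients additionally multiply all three
irregularity sources by the group effect (preset "paper-like": 1.65,
calibrated once by a pilot sweep so the AP sample-entropy feature yields
AUC ≈ 0.8 at n = 50 per group; "null": 1.0 with identical covariate
distributions; "strong-effect": 1.6 × the calibrated value). A patient's
multiplier also grows mildly with their simulated motor score (slope 0.25
over ±28 points), giving the severity-strata tests a signal. Synthetic
motor scores, stage, disease duration and faller status are drawn from
plausible clipped distributions.

What the generator does **not** emulate: real trunk-acceleration
waveshapes (no double-support asymmetry, turning, or freezing episodes),
sensor artefacts, the empirical covariance between speed, age and
irregularity, or the specific entropy magnitudes of any clinical
population. Passing tests therefore demonstrate the correctness and
calibration of the estimators and pipeline under the assumed statistical
structure, not clinical performance.

## Problem sizes and determinism

Simulation-backed checks use sizes chosen to make Monte-Carlo error small
relative to the asserted effect: 50 seeds for the iid-Gaussian SampEn
limit (±0.1 band) and for noise-profile shapes; 200 short series for the
CMSE/RCMSE robustness gap; 200 null cohorts of 25 + 25 subjects with
500-sample traces for the type-I error (binomial 95% acceptance band);
20 effect cohorts of 50 + 50 with full 2000-sample traces for the AUC
calibration (±0.07). The acceptance script uses the same designs at
100 null cohorts / 10 effect cohorts and one full study-sized pipeline
run (51 + 50×2 trials, 2000 samples, scales 1–6).

All randomness flows from numpy `default_rng` seeds; fixed seeds make
every generator output and every written pipeline artifact byte-identical
across reruns (reports deliberately contain no timestamps — provenance is
the config hash plus seed).

## Known limitations

- SampEn estimates at scale 6 of a 2000-point series rest on ~330 points;
  profiles at higher scales would need longer recordings.
- The DeLong CI is asymptotic and can be degenerate (zero width) for
  perfectly separated small samples.
- The per-cycle phase jitter model affects stride-scale structure far more
  than the 10 ms native scale; group contrasts at fine scales are driven
  mainly by the noise and amplitude components.
- Exact Mann–Whitney p-values are used only for small tie-free samples;
  elsewhere the normal approximation is standard but approximate.
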