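# gaitmse

Multiscale sample entropy of trunk accelerations, and how well it separates
Parkinsonian from healthy gait.

People with Parkinson's disease walk with subtly irregular trunk motion.
A single lumbar-mounted accelerometer records that motion as three
acceleration time series (antero-posterior AP, medio-lateral ML, vertical
V), and the cycle-to-cycle irregularity of those series can be quantified
without any step detection using **sample entropy** and its multiscale
extensions. This package implements the full analysis chain for that idea:
entropy estimation, diagnostic-accuracy evaluation of each entropy feature,
the cohort statistics of a speed-matched case–control design, and a
synthetic cohort generator so the whole pipeline is testable end to end
without clinical data.

## The estimators

For a series *x₁…x_N*, embed templates
*xᵢᵐ = (xᵢ, …, xᵢ₊ₘ₋₁)* and count unordered template pairs whose Chebyshev
distance is at most *r* (tolerance *r = 0.2·SD*, embedding *m = 2*, lag 1
by default):

- **SampEn**(x, m, r) = −ln(*nᵐ⁺¹ / nᵐ*), the conditional irregularity of
  the series; 0 for perfectly regular signals, larger for noisier ones.
- **Coarse-graining**: replace the series by means of non-overlapping
  windows of width τ (offset k = 1…τ), shifting the analysis to longer
  time scales.
- **MSE**(τ) = SampEn of the first (k = 1) coarse-grained series,
  τ = 1…6.
- **CMSE**(τ) = mean of the τ per-offset SampEn values; undefined as soon
  as one offset has no matches.
- **RCMSE**(τ) = −ln(Σₖ nₖᵐ⁺¹ / Σₖ nₖᵐ): pools the counts before the
  logarithm, so short series rarely yield undefined values.
- **Complexity index** = trapezoid-rule integral of an entropy-vs-scale
  profile.

Every feature (method × axis × τ, plus CI) is then scored as a diagnostic
marker: ROC AUC (Mann–Whitney statistic, DeLong 95% CI, "sufficient" at
AUC ≥ 0.70), optimal cutoff (max sensitivity+specificity / Youden / F1,
disagreements resolved by the largest PTP⁺−PTP⁻ difference), likelihood
ratios, Fagan post-test probabilities at the sample prevalence and at a
35% external prevalence, and the diagnostic odds ratio. Cohort statistics
cover propensity-score 1:1 *optimal* matching on age and gait speed
(global assignment optimum, not greedy), Mann–Whitney tests with
Hedges-corrected effect sizes, Kruskal–Wallis/Dunn/Holm comparisons across
motor-severity strata (UPDRS III < 32 / ≥ 32 / ≥ 58), and partial Spearman
correlations that exclude age and gait speed.

## Worked example

```python
from gaitmse import EntropyConfig, multiscale_profiles
from gaitmse.simulate import GaitSimParams, gen_trunk_signal

traces = gen_trunk_signal(GaitSimParams(seed=7))          # 20 s at 100 Hz
profiles = multiscale_profiles(traces["AP"], EntropyConfig())
mse = profiles["MSE"]
for tau, value in mse.values.items():
    print(f"tau={tau}: MSE = {value:.3f}")
print(f"complexity index (scales 1-6) = {mse.ci:.3f}")
```

prints

```
tau=1: MSE = 0.676
tau=2: MSE = 0.637
tau=3: MSE = 0.595
tau=4: MSE = 0.679
tau=5: MSE = 0.710
tau=6: MSE = 0.791
complexity index (scales 1-6) = 3.354
```

i.e. a healthy-like synthetic walk has moderate irregularity (SampEn ≈ 0.68
at the native 10 ms scale) and a mildly rising profile toward stride-level
scales; the complexity index integrates that profile. Patient-like signals
(higher cycle-to-cycle jitter) shift every scale upward.

The same analysis from the shell, end to end:

```sh
gaitmse run-all --preset paper-like --seed 1 --outdir out/
gaitmse report --rundir out/
```

which simulates a 51-patient / 50-control cohort (two walking speeds per
control), matches controls to patients on the propensity score, extracts
all entropy features, and writes the group tests, ROC/cutoff tables at
both prevalences, severity-strata tests and partial correlations under
`out/report/`.

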