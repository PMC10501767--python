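# Methods

## The design and its statistical model

Monozygotic co-twins share their genome, sex, age and childhood
environment. If one twin currently smokes and the other never did, a
methylation difference between them at a CpG cannot be explained by
genotype; it is evidence that methylation is reactive to smoking (or to
something tightly coupled to it). The package's central statistic is the
within-pair difference of covariate-adjusted β-values,

ΔM = residual(less-exposed twin) − residual(more-exposed twin),

tested per CpG with a one-sample t-test against zero: t = mean(ΔM)/(s/√n)
on n−1 degrees of freedom, two-sided p, and 95% CI
mean ± t₀.₉₇₅,ₙ₋₁·s/√n. The sign convention makes a positive ΔM mean *lower*
methylation in the exposed twin, which matches how the reference estimates
for the 13 published smoking-reactive CpGs are tabulated. Family-wise error
is controlled by Bonferroni correction over the M CpGs actually tested
(α/M; with the published 411,169 autosomal probes, 0.05/411,169 ≈ 1.2×10⁻⁷).

Pairs with a missing value at a CpG are excluded from that CpG's test only,
and the per-CpG n is reported. Zero-variance difference vectors are flagged
`degenerate` and yield no p-value rather than an infinite t.

### Residualization

β-values are adjusted by per-CpG OLS on: bisulphite plate and array row
(dummy-coded, first sorted level as reference — any full-rank coding gives
identical residuals) and neutrophil, monocyte and eosinophil percentages.
Lymphocyte percentage is excluded (nearly collinear with neutrophils,
r ≈ −0.93 in blood), basophil percentage is excluded (near-zero variance),
and sex/age are unnecessary within MZ pairs. The fit is **global** — all
samples at once, not per group. This matters numerically: regressing p
covariate columns out of n samples absorbs an O(p/n) fraction of any
exposure signal by chance. At the full cohort size (1536+ samples, ~16
columns) the attenuation is ≈1%; fitting on a single 53-pair group would
cost ≈15% of the effect and distort the null. CpGs with missing entries are
fitted on complete cases with the count recorded; rank-deficient designs
raise an error naming the collinear columns.

### Calibration diagnostic

The genomic inflation factor is the classical λ: each t is mapped to its
two-sided p and the matching χ²₁ quantile; λ = median(χ²₁)/0.4549. The
report adds the mean/SD of sign-preserving probability-integral-transform
z-scores (standard normal under a calibrated null). A full Bayesian
mixture-model inflation estimate is out of scope; λ plus z-moments suffice
to verify the qualitative claim that the within-pair statistics are not
inflated.

## Reversibility, dose–response, enrichment, power

**Reversibility.** For a CpG set (the significant, or top-k by p, sites of
the current/never EWAS) the percent reduction is
100·(1 − |ΔM_comp|/|ΔM_ref|), computed on absolute mean differences —
signs are preserved in reporting but not in the ratio — with the summary
mean taken over unrounded per-CpG values and rounded last (half-up). This
reproduces the published 81% (range 61–96%) former/never attenuation from
the printed per-CpG estimates. The group-profile operation summarises, per
group, the distribution over top-k CpGs of the mean absolute within-pair
difference, and `ordering_check` evaluates
current/never > current/former > former/never > concordant-never on the
group means.

**Dose–response.** Pearson correlations (two-sided p via the t transform on
n−2 df), complete-case per CpG × phenotype, with pair deltas taken under
the same member ordering as ΔM. The time-since-quitting correlation can be
restricted to recent quitters; "less than y years" is a strict inequality.
Summaries report mean |r| and the signed range, matching the field's
reporting style.

**GWAS-proximity enrichment.** CpGs within 1 Mb (inclusive — the boundary
is tested) of SNPs with GWAS p strictly below 5×10⁻⁸ are flagged;
|t| = intercept + β·flag is fitted by OLS, where β equals the difference of
class means exactly (binary-predictor identity, asserted in tests).
Uncertainty is a nonparametric case-resampling bootstrap over CpGs
(default B = 2000): SE = SD of bootstrap slopes, 95% percentile CI,
two-sided p from a normal approximation on β/SE. Single-class resamples are
redrawn so B stays fixed, with the redraw count reported. Chromosome names
are normalized by stripping a `chr` prefix and uppercasing.

**Power.** The paired design's power is exact under normality:
P(|T′| > t₁₋α/₂,ₙ₋₁) with T′ noncentral t (df n−1, noncentrality δ√n/σ_d).
At epigenome-wide α the noncentral-t and normal approximations differ
materially, so the t form is used; where scipy's noncentral-t tail
underflows to NaN at extreme noncentrality, each tail falls back on its
asymptotic normal bound separately. `calibrate_sd` inverts the power
function (strictly decreasing in σ_d) by bracketing + Brent to recover the
within-pair SD implied by a stated operating point: 80% power for δ = 0.15
at n = 50, α = 1.2×10⁻⁷ gives σ_d ≈ 0.1484, under which power at δ = 0.10
is ≈11.9% — consistent with the cited "about 10%" — while power at
δ = 0.05 is ≈6.3×10⁻⁴. That last value is small but still three orders of
magnitude above α: under this model "approaches α" cannot be read as
"within a factor of 10 of α", and the corresponding test records that
honestly rather than relaxing the band.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes, with
ground truth recorded for recovery tests.

*Methylation.* Each CpG has a baseline on the logit scale (bimodal mixture,
as 450k β distributions are; reactive CpGs are placed mid-range so β-scale
effects have headroom). Co-twins share a pair-level baseline
(SD 0.5 logits); individual noise SD is 0.14 logits, which yields a
within-pair difference SD of ≈0.05 on the β scale at mid-range CpGs — the
noise level consistent with the cited power analysis (σ_d ≈ 0.148 for 80%
power at δ = 0.15). Plate and array-row shifts (SDs 0.05/0.03 logits) and
linear white-cell terms (per-CpG coefficients, SD 0.02 per percentage
point, on the three covariate cell types) are added so residualization is
exercised non-trivially. Values are inverse-logit transformed; the smoking
effect is then added on the **β scale**, so the configured effect *is* the
expected within-pair difference; clipping to [0,1] is applied last and
counted.

*Smoking effect.* A sample's effect magnitude is
δ·min(cpd/dose_ref, 2) for current smokers (linear dose–response, capped at
twice the 10 cigarettes/day reference) times exp(−q/τ) for former smokers
who quit q years ago; never smokers carry none. The per-CpG sign is −1
(smoking lowers methylation) with probability 0.6, echoing the published
8-of-13 hypomethylated split. All reactive CpGs carry δ = delta_max
(default 0.13, the largest published within-pair effect), which keeps the
truth-implied mean ΔM a closed-form quantity.

*Reversal time constant.* Default τ = 4.2 years, calibrated analytically to
the published attenuation: with quit times Gamma-distributed (mean 13.5 y,
SD 11.4 y, as in former/never pairs), E[exp(−q/τ)] = (1+θ/τ)^(−k) ≈ 0.19,
i.e. an expected ≈81% reduction of the within-pair difference — the printed
former/never anchor. A faster constant (τ ≈ 2.5) would imply ≈96% reduction
and contradict that anchor.

*Phenotypes.* Group sizes default to the study's own
(53/72/66/83/88/406 pairs). Cigarettes/day are lognormal (means/SDs from
the published group descriptives, e.g. 8.9 ± 6.4 in discordant current
smokers); in concordant current pairs co-twin values come from a bivariate
lognormal whose latent Gaussian correlation is solved in closed form so the
*observed* Pearson correlation equals the target (default r = 0.50, the
published twin correlation). Quit times are Gamma with group-specific
means; packyears follow the (cpd/20)·years formula; plasma cotinine is
≈25 ng/ml per cigarette/day with lognormal noise in current smokers
(≈222 ng/ml at 8.9 cpd) and near zero otherwise, supporting the ≥15 ng/ml
misclassification flag. Cell percentages use blood-count descriptives, with
current smokers shifted +1.3 toward neutrophils.

*What it does not emulate.* Probe-level intensities, spatial/chromosomal
correlation between CpGs, genome-scale CpG counts (defaults use 2000 CpGs;
the real array has 411k), cell-type interactions, longitudinal dynamics, or
sex-chromosome CpGs. Passing recovery tests therefore demonstrates
correctness of the statistical machinery under the design's assumptions,
not performance on real array data.

## Numerical and design choices

- All randomness flows from `numpy.random.default_rng` seeds; identical
  seeds give bit-identical cohorts, bootstraps and simulations.
- Filtering order: per-measurement rules (detection p, beads, zero
  intensity) first, then probe success rate, then sample success rate.
  Measurements failing per-measurement rules become missing (not removed)
  before success rates are computed. The operation is idempotent.
- Ties in p when ranking CpGs break by |t| descending, then CpG id.
- `calibrate_sd` brackets upward from δ·10⁻³ and solves with Brent to
  relative tolerance 10⁻¹⁰.
- Percent summaries round half-up, at report time only.
- Tables are TSV with `.` for missing values and 1-based positions; BED
  annotation input is converted 0-based → 1-based on read. Output files
  carry a header comment with tool version, seed and input checksums.
- Test problem sizes: the null-calibration check uses 20 cohorts × 2000
  CpGs at full group sizes; recovery/ordering use 100 cohorts × 300 CpGs;
  the bootstrap-vs-analytic comparison uses 10⁵ CpGs with 500 replicates —
  sizes chosen to keep Monte-Carlo error well inside the asserted bands.

## Known limitations

- The Bayesian mixture inflation model is replaced by classical λ (see
  above); λ is coarser for detecting subtle bias mixtures.
- The bootstrap treats CpGs as exchangeable units; real neighbouring CpGs
  are correlated, so real-data SEs would be mildly optimistic.
- β-scale effects plus clipping introduce a small downward bias in realized
  effects at extreme baselines (the clip count is reported in the truth
  object).
- The enrichment regression follows the field's specification on |t|;
  heteroskedasticity between flagged/unflagged classes is handled by the
  bootstrap, not by the OLS standard errors.
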