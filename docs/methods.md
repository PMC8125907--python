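# Methods

This note documents the statistical procedures implemented in `nersig`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generators do and do not emulate.

## Differential expression and the consensus filter

Each knockdown line is compared with the shared control on log2 expression.
The default per-gene test is a **moderated t-test**: the pooled two-sample
variance s_g² (df = n₁+n₂−2) is shrunk toward an empirical-Bayes prior
fitted across all genes. The prior is a scaled inverse-chi-square (s₀², d₀)
estimated by matching the moments of log s² (solving
trigamma(d₀/2) = var(e) − trigamma(df/2) by Newton iteration, where e is the
bias-corrected log variance); the statistic uses the posterior variance
(d₀s₀² + df·s²)/(d₀+df) with df + d₀ degrees of freedom. The motivation is
power: with three replicates per group a per-gene variance estimate has four
degrees of freedom, and raw two-sample tests (Welch's included) cannot reach
per-line q < 0.05 for moderate fold changes at realistic noise, which makes
an all-lines intersection filter close to empty. Variance shrinkage is the
standard remedy for small-replicate expression designs. Welch's t-test is
retained (`welch_de`, `method="welch"`) for heteroscedastic data.

Multiple testing uses **Storey q-values**: π₀ is estimated on the λ grid
0.05–0.95 (step 0.05) via the usual #{p>λ}/(m(1−λ)) estimates, smoothed by a
natural cubic smoothing spline (GCV penalty) and read off at λ = 0.95,
clipped to (0, 1]; q_i = π₀ · min over p_j ≥ p_i of m·p_j/rank(p_j). With
π₀ = 1 this reduces exactly to Benjamini–Hochberg. When every grid estimate
is ≥ 1 (e.g., all p = 1), π₀ is set to 1 without smoothing.

Fold-change convention: `fold_change` is signed linear (−2 = halving),
thresholds are strict (|FC| > 1.5 ⇔ |log2FC| > log2 1.5 ≈ 0.585; q < 0.05).
Zero-variance genes in both groups get p = 1 when means are equal, p = 0
otherwise (the limit of the t statistic), and a warning.

Consensus selection intersects the per-line pass sets and additionally
requires a consistent sign of log2FC across lines — a single averaged
coefficient is meaningless for direction-discordant genes; on correlated
panels the requirement is nearly vacuous.

## Coefficients and the score

Coefficients are the arithmetic mean of the per-line **log2** fold changes
(a signed-linear mode exists). Log scale was chosen because it makes up- and
down-regulation symmetric and averaging well behaved. The score of sample s
is Σ c_i z_i(s) / Σ|c_i|, with z computed per gene across the cohort being
scored (sample sd, ddof = 1). Per-cohort z-normalization is deliberate: the
signature is applied to cohorts it was never trained on, so no frozen
reference distribution exists; a frozen-reference mode
(`score_samples(..., reference=(means, sds))`) supports single-sample
scoring. Genes missing from the cohort or with zero variance are dropped and
the denominator renormalized; dropping more than 20% of the signature
(configurable) is an error rather than a silent degradation. Consequences of
the construction, all property-tested: scores are invariant to positive
affine maps of any gene row, negate when all coefficients negate, have
cohort mean 0 when nothing is dropped, and are bounded by the largest |z|.

Hierarchical clustering of samples uses Ward linkage on Euclidean distances
over z-normalized signature-gene rows, so every gene contributes on a common
scale.

## Cohort evaluation

AUROC is computed by the Mann–Whitney rank formulation with average ranks
for ties. Candidate thresholds are midpoints between consecutive distinct
scores plus ±∞; prediction is score **>** threshold (strict). Youden's J is
maximized with ties broken toward higher sensitivity, then the lowest
threshold — matching a screening use of the signature where sensitivity is
the priority. The threshold CI is a class-stratified percentile bootstrap
(default 2000 resamples, seed required).

The log-rank test delegates to lifelines. The Cox hazard ratio for a binary
group is fitted directly: Breslow tie handling, 1-D Newton iteration on the
partial likelihood, Wald CI and p. Breslow was chosen as the simplest
documented convention; on untied data it coincides with Efron (this
agreement with lifelines is a cross-check in the test suite).

Mutational-signature concordance compares three disjoint groups — (1)
deficient with an NER mutation, (2) predicted deficient without one, (3)
predicted proficient — by Cohen's d (pooled sd) of each signature's activity
in group 1 vs 3 and 2 vs 3, then the Pearson r between the two d profiles.
Standardized differences keep r scale-free across signatures with very
different activity magnitudes; a raw-mean-difference mode is provided. Note
that both profiles share group 3, so their sampling errors are positively
correlated (≈ (1/n₃)/(1/n₁ + 1/n₃) under the null); with a reference group
several times larger than the others — the realistic regime — the induced
null correlation is small.

## Drug screen

Lines at or above the type-7 (linear-interpolation) 75th percentile of the
score are labeled deficient; the quantile convention is documented because
membership at the boundary depends on it. Per drug, Welch's t-test on the
response values with effect = mean(deficient) − mean(others) and BH FDR
across tested drugs; drugs with fewer than `min_n` = 3 measured lines in
either group are flagged untested, not dropped. The Welch + BH combination
is a reconstruction of a previously published screening approach whose exact
statistic is not restated here; it is deliberately simple and clearly
labeled as the default rather than a canonical choice.

## Median effect and combination index

Single-agent curves are fitted by OLS on the median-effect linearization
log10(fa/(1−fa)) vs log10 D; m is the slope, Dm = 10^(−intercept/m).
Observed fa outside [0.005, 0.995] is an error by default (the
linearization diverges at the boundaries) with an explicit clip option.
CI uses the mutually exclusive two-term form d1/Dx1 + d2/Dx2 (the common
reported variant); the non-exclusive three-term form is an option. The
default call uses an additivity band (synergism < 0.9, additive 0.9–1.1,
antagonism > 1.1) because exact CI = 1 is measure-zero on real data; the
strict <1/=1/>1 rule is available (`additive_band=None`). The fundamental
consistency check — a drug combined with itself at any dose split gives
CI = 1 — holds to 1e-9 and is enforced in tests.

## Synthetic-data generators

All generators require an explicit seed and are bit-reproducible.

* **Panel**: baseline log2 expression per gene ~ N(8, 2); core genes carry
  one signed shift (magnitude ~ N(1.2, 0.1) by default) applied identically
  in every knockdown line; each line has private DE genes shifted only
  there; replicate noise is additive N(0, 0.3) on log2. Defaults mirror the
  source design: 5 knockdown lines, 3 replicates, 105 core genes among 1000.
  The small default spread of core magnitudes reflects planting effects "at"
  a configured size; widen `core_log2fc_sd` for heterogeneous effects.
* **Cohort**: 300 tumors, 25% deficient. Deficient tumors are shifted by
  `score_shift` (default 3) standard deviations along sign(c_i) per
  signature gene; about half (configurable) carry an NER-mutation flag;
  mutational-signature activities are gamma(2, 0.5) with `mutsig_shift`
  (default 1.0) added to half the signatures in deficient tumors; survival
  is exponential with baseline hazard 1/24 per month and hazard ratio
  `survival_hr` (default 0.46) for deficient tumors — the exponential
  proportional-hazards form makes the planted HR exactly the Cox estimand.
  Censoring is an independent exponential calibrated to the requested rate.
* **Screen**: AUC = 0.7 baseline + N(0, 0.05), minus `auc_effect` (0.3) for
  lethal drugs in upper-quartile lines, clipped to [0, 1].
* **Dose–response**: exact median-effect fa with Gaussian noise on the
  logit, keeping fa strictly inside (0, 1).

What the generators do **not** emulate: count-level sampling (negative
binomial dispersion), gene–gene correlation, batch effects, non-proportional
hazards, and dose–response model misspecification. Green tests therefore
demonstrate correctness of the statistical machinery under the stated
models, not robustness to real-data pathologies; the moderated test's
advantage, in particular, is largest under the generator's homoscedastic
noise and shrinks when per-gene variances genuinely differ.

## Problem sizes and numerical choices

The test suite and the reproduction script run panels of 1000 genes × 18
samples, cohorts of 300 (2000 for hazard-ratio recovery, where the estimate
needs to be tight), 200-seed null calibrations, and 1000–2000 bootstrap
resamples — sizes at which every planted quantity is comfortably estimable
on a laptop in minutes. Newton iterations (Cox, trigamma inversion) stop at
relative steps of 1e-12/1e-10; the Youden tie-break and strict threshold
rules above pin down otherwise arbitrary boundary behavior.

Under the panel generator's default study conditions the five-line consensus
intersection recovers ~93% of planted core genes. This is a ceiling imposed
by the design, not the test: the fold-change estimate carries
SE = noise·√(2/3) ≈ 0.245 (case and control means from three replicates
each), and the per-line q < 0.05 filter acts as an effective |log2FC| cut
near 0.65, so even a known-variance oracle test leaves a few percent of
≈1.2-log2FC genes below threshold in at least one of five lines. Larger
effects, more replicates, or fewer lines push recovery to 1.

## Known limitations

* The per-gene DE test upstream of the original signature is not public;
  the 105-gene list itself is therefore not re-derivable here, and workflows
  against the deposited expression data (GEO) or TCGA cohorts are left to
  the user — the pipeline consumes already-tabulated TSV inputs.
* The screen statistic is a reconstruction (see above).
* Storey's π₀ smoother uses a GCV-penalized spline rather than the fixed
  3-df smoother of the reference implementation; q-values agree with BH
  exactly at π₀ = 1 and differ from the reference only through π₀.
* Single-sample scoring requires a user-supplied reference distribution;
  no default reference ships with the package.
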