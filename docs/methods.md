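# Methods

`metascreen` asks, for a single gene of interest in a tumor/normal setting:
is it over-expressed across many independent expression cohorts, does it
discriminate tumor from normal tissue, does it carry prognostic information,
and which genes does it plausibly regulate? Each question is answered by a
standard evidence-synthesis procedure, and the four answers are combined
into a target screen. This note records the models, their assumptions, the
defaults, and the design choices made where the design was genuinely open.

## Effect-size meta-analysis

Per cohort the group contrast is the standardized mean difference
d = (m_t − m_n)/s_pooled with the usual pooled-variance denominator, carried
as Hedges' g = J·d, J = 1 − 3/(4·df − 1), which removes the small-sample
upward bias of d. Its sampling variance is the large-sample form
var(g) = (n_t+n_n)/(n_t·n_n) + g²/(2(n_t+n_n)). Fixed-effect pooling is
inverse-variance; the random-effects model uses the DerSimonian–Laird
moment estimator τ² = max(0, (Q − (k−1))/C) with fixed-effect weights in Q
and C = Σw − Σw²/Σw, then re-weights by 1/(varᵢ + τ²). Heterogeneity is
summarised as I² = max(0, (Q − (k−1))/Q)·100, truncated to [0, 100]. The
model selector (`pool_auto`) uses the random-effects fit when I² > 50%,
else the fixed-effect fit.

Choices the literature leaves open, fixed here:

- Normal (z) critical values for all CIs, not t — the common default of
  classic meta-analysis packages. Two-sided p-values throughout.
- Hedges' correction is always applied; fixtures must use the same formula.
- Egger's test regresses g/SE on 1/SE and t-tests the intercept (df = k−2).
  Begg's test correlates variance-stabilized deviates
  (gᵢ − pooled)/√(varᵢ − 1/Σw) with varᵢ via Kendall's tau — exact
  permutation p below k = 10 when there are no ties, tie-corrected normal
  approximation otherwise. Both require k ≥ 3.
- Known caveat: for large SMDs, var(g) depends on g itself, so funnel
  asymmetry tests can fire without any publication bias. The synthetic
  conditions (SMD 1.7) sit exactly in that regime; a significant Egger
  intercept on simulated data is this artifact, not a generator defect.

## Diagnostic-accuracy meta-analysis

Per cohort the rank AUC (normalized Mann–Whitney U, ties counted half) is
computed, and a 2×2 confusion table is formed at the cutoff maximizing
Youden's J = Se + Sp − 1 over midpoints between adjacent sorted unique
values, classifying positive at values ≥ cutoff. The source studies never
publish a per-study cutoff rule, so Youden's J was chosen; J ties resolve
toward the higher-sensitivity (smaller) cutoff. A per-cohort AUC ≥ 0.7
flags the gene as a candidate diagnostic marker in that cohort.

Pooling is on the logit scale: logit(Se) with variance 1/tp + 1/fn (and
likewise Sp), through the same DerSimonian–Laird machinery, back-transformed.
Tables containing a zero cell get 0.5 added to every cell. Likelihood
ratios derive from the pooled pair: LR+ = Se/(1−Sp), LR− = (1−Se)/Sp.
The summary ROC is the Moses–Littenberg construction: per study
D = logit(TPR) − logit(FPR), S = logit(TPR) + logit(FPR), unweighted OLS
D = a + bS, back-solved to logit(TPR) = a/(1−b) + ((1+b)/(1−b))·logit(FPR)
and integrated by trapezoid on a 2001-point FPR grid over the full (0, 1)
range. This is a deliberate simplification relative to bivariate/HSROC
models: it is dependency-free, exactly testable against a numeric oracle,
and matches the era of tooling the procedure descends from. It requires
k ≥ 3 studies, spread in S, and |1 − b| bounded away from zero.

## Survival

Patients are dichotomized at the expression cutpoint maximizing the
standardized two-sample log-rank statistic (maximally selected rank
statistics, Lausen–Schumacher form): with log-rank scores
aᵢ = δᵢ − Λ̂(tᵢ) (Nelson–Aalen), each candidate cutpoint c gives the linear
rank statistic S_c = Σ_{xᵢ>c} aᵢ standardized by its permutation mean and
variance. Candidates are unique expression values whose split leaves at
least `minprop` = 0.10 of patients on each side (the cited cutpoint
routine's default). Ties go to the smaller cutpoint. No selection-bias
correction is applied to downstream p-values — an acknowledged optimism
source, consistent with how the procedure is used in practice. Because the
statistic depends on expression only through its ranks, the cutpoint maps
through monotone transformations.

Group curves are Kaplan–Meier estimates and the group comparison the
hypergeometric-variance log-rank test (both via lifelines). Proportional
hazards are fitted by Newton iteration on the Breslow partial likelihood
(gradient tolerance 1e−8, step-halving, 100-iteration cap). Breslow rather
than Efron tie handling was chosen because it is exactly reproducible by a
grid-search oracle; on tie-free data the fit agrees with lifelines' Efron
fit. Categorical covariates expand against their first sorted level;
constant covariates are excluded with a warning. Monotone likelihood
(separation) is detected as a runaway coefficient and the affected term is
reported as non-estimable instead of a spurious huge HR — degenerate fits
like HR ≈ 0 with an infinite CI are surfaced, not reproduced.

Published hazard ratios are pooled fixed-effect on the log scale, with
study SEs recovered from the reported 95% CIs as (ln hi − ln lo)/(2·1.96).
The pipeline's own contribution to that pool is the high-vs-low (cutpoint
group) HR, which is the scale literature HRs are reported on; the per-unit
HR is reported separately.

## Target screen

Three candidate sets intersect exactly:

- **ChIP candidates** — genes whose maximum regulatory-potential score
  across ChIP datasets is ≥ 1. The maximum (not per-dataset or mean) was
  chosen as the monotone "candidate in any dataset" reading; scores are
  consumed as opaque nonnegative numbers.
- **Co-expressed genes (CEG)** — per platform, Pearson r of each gene
  against the gene of interest with p from t = r·√((n−2)/(1−r²)); a gene
  passes a platform iff r ≥ 0.30 and p < 0.05, and enters the consensus
  when it passes ≥ 20 platforms. p-values are unadjusted within platforms:
  the ≥ 20-platform consensus requirement is the error control. By default
  all samples are used (tumor-only is available via `tumor_only`). Genes
  absent from a platform simply cannot pass it.
- **Highly expressed genes (HEG)** — per-gene Hedges' g per cohort, pooled
  by DerSimonian–Laird; HEG iff pooled SMD > 0 and pooled p < 0.05. Genes
  usable in fewer than two cohorts are not assessed.

The gene of interest is excluded from all three sets (it trivially
correlates r = 1 with itself); it is added back to the enrichment query
only, mirroring how such screens report "targets plus the regulator".
Verification re-examines survivors: per-platform r/p rows in bulk, and
within a designated single-cell cluster, the fraction of cells expressing
both genes plus the Spearman correlation, against all other clusters pooled.

## Enrichment

One-sided hypergeometric over-representation: p = P(X ≥ k) with
X ~ Hypergeom(N, K, n); the universe defaults to all genes present in at
least one input cohort (configurable), each annotation set is intersected
with the universe first, and adjustment is Benjamini–Hochberg (the usual
default of enrichment tooling when the method is unnamed). No ranked
(GSEA-type) statistic, ontology propagation, or redundancy pruning.

## Synthetic test bed

`SimSpec` defaults are the study conditions, chosen once:

| parameter | default | rationale |
| --- | --- | --- |
| n_platforms | 39 | the multi-platform design at full width |
| samples/arm | 30–80 | desk-scale cohorts (vs ~100/arm in the motivating data) |
| true_smd / tau | 1.7 / 0.3 | pooled SMD and strong-heterogeneity regime |
| n_genes / true targets | 200 / 9 | nine-target program plus decoy background |
| target_correlation | 0.5 | within-group latent-factor correlation to the gene of interest |
| survival | x ~ N(2.7, 1.4²), HR 1.30/unit, n = 364, 35% censoring | clinical-table conditions |
| literature HRs | 14 studies around 2.0 | the HR-pooling stratum |
| ChIP | 41 datasets; targets 1+Exp(1) in ~90% of datasets, decoys sparse Exp(0.3) | score-≥-1 rule separable but not trivial |
| single cell | 2000 cells, 4 clusters, NB(size 2), 60% dropout | zero-inflated counts with one co-expressing malignant cluster |

Expression is normal on the log2 scale with unit within-group SD, so the
per-platform shift δᵢ ~ N(true_smd, τ²) *is* the per-platform Cohen's d —
heterogeneity is injected on the effect scale, matching the random-effects
generative model the pooling assumes. Event times are exponential with
hazard exp(β₀ + β·x); censoring is an independent uniform time whose upper
bound is calibrated numerically so the expected censored fraction hits the
target. All generators are pure functions of (spec, seed), with independent
seed streams per stage.

What the generator does **not** emulate: platform-specific probe effects,
batch structure, non-normal expression marginals, correlated decoys,
informative censoring, realistic single-cell library-size variation, or
ambient RNA. Passing tests therefore show that the estimators recover the
structure they assume, not that real multi-platform data satisfy those
assumptions; batch correction in particular is out of scope (an optional
per-cohort standardization exists instead, and SMD is scale-invariant).

## Numerical notes and degenerate inputs

- τ² is truncated at 0, I² to [0, 100]; Q is computed with fixed-effect
  weights in both pooling models.
- Zero pooled SD, single-sample arms, constant expression, empty groups,
  all-tied variances (Begg), k below each method's minimum, and CIs with
  lo ≥ hi are hard errors with specific messages, not silent NaNs.
- Duplicate gene rows collapse by mean on read (deterministic and
  order-independent); symbols are uppercased and matched exactly.
- Pipeline outputs are byte-deterministic for fixed inputs and seed:
  fixed float formatting, sorted JSON keys, no timestamps in tables.

## Problem sizes used by the test suite

The simulation-based checks run 100 replicates of the 39-platform design
(12 genes where only the gene of interest matters, 200 where the screen
needs the decoy background), 100 survival replicates at n = 400 and
n = 300, and 200 null replicates for the log-rank calibration check; the
full suite completes in about a minute on one core.
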