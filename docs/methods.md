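# Methods

This note documents the statistical procedures implemented in `invasig`,
the defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical choices that matter for reproducing
results.

## Preprocessing

Two-channel intensities are normalized per array by global LOWESS: with
R and G the channel intensities, M = log2(R/G) and A = ½·log2(R·G) are
formed and a locally weighted linear smoother of M on A (span 0.3, degree 1,
3 robustness iterations; `statsmodels` LOWESS) is subtracted from M. The
span default is a standard choice for global (print-tip-free) MA
normalization; a strongly curved intensity bias whose wavelength approaches
the span window retains a small curvature residual (~0.05 log2 units), and a
smaller span removes it. Rows with non-positive intensities are filtered and
logged rather than raised, since their log ratios are undefined.

Probes collapse to genes by retaining, per gene, the probe with the greatest
across-sample variation — sample variance by default, median absolute
deviation by option — with variance ties broken to the lexicographically
smallest probe id so collapsing is deterministic and idempotent. Probes
missing in more than 20% of samples are filtered; remaining gaps are imputed
with the probe median. These filtering defaults are package decisions; the
variation-maximizing collapse rule is the substantive one.

## SAM differential expression

For an unpaired two-class comparison, each gene gets

    d_i = (mean_1i − mean_2i) / (s_i + s0),

with s_i = sqrt[(1/n1 + 1/n2) · (SS_1i + SS_2i) / (n1 + n2 − 2)] the pooled
standard error and s0 ≥ 0 the exchangeability constant. By default s0 is
chosen on a 21-point percentile grid of s to minimize the coefficient of
variation of the windowed MAD of d across s-quantile windows; a simpler
"median of s" mode and fixed numeric values are available. Fold change is
2^(mean difference) on log2 input.

Significance: class labels are permuted (300 permutations by default; all
distinct arrangements are enumerated when there are at most that many, e.g.
70 at 4+4), the sorted d of each permutation gives expected order statistics
d̄_(i), and at each threshold Δ the cut points are the first sorted positions
where |d_(i) − d̄_(i)| > Δ; all genes beyond the cuts are called. The FDR
estimate at Δ is the median permutation count of statistics beyond the cuts
divided by the observed call count, capped at 1 (a 90th-percentile variant
is available). Raw FDR estimates are not guaranteed monotone in Δ, so the
table stores the conservative monotone envelope fdr(Δ_i) = max_{j≥i}
raw_fdr(Δ_j). The calling rule picks the smallest tabulated Δ with FDR at or
below the target (default 0.10); an unreachable target yields an empty call
set with a warning, not an error.

A behavior worth knowing: with very few arrays (4+4, 70 enumerable
permutations) the median false-call count at the largest thresholds is
frequently zero, so roughly 40% of fully null matrices call one to three
genes at an estimated FDR of 0. This is a property of median-false-count SAM
at such sample sizes, essentially independent of the s0 rule, and the tests
guard against grossly worse behavior rather than against this floor.

The prognostic subset takes the top k called genes (default 80) by |log2
fold|, ties at the boundary included; direction is the sign of the fold.

## Survival primitives

Kaplan–Meier uses the product-limit estimator over distinct event times;
censored-only times affect risk sets only. The k-sample weighted log-rank
test accumulates observed minus hypergeometric-expected events per group at
each distinct event time with weight 1 (log-rank) or the total number at
risk (Gehan–Breslow–Wilcoxon, early-separation sensitive) and forms the
quadratic form of the first k−1 sums against their estimated covariance.

Cox proportional-hazards models maximize the partial likelihood by
Newton–Raphson with step-halving; ties use the Efron approximation by
default (Breslow by flag); convergence is a relative log-likelihood change
below 1e-9 or 50 iterations; Wald standard errors come from the observed
information; 95% CI = exp(β ± 1.96·SE). Monotone likelihood (separation)
caps |β| at 10 and clears the convergence flag. A constant covariate is an
error univariately and is dropped with a warning multivariately. A
vectorized batch mode fits one univariate model per gene simultaneously
(shared risk-set suffix sums across genes, per-gene Newton steps clipped at
2 to damp early oscillation, 30 iterations, step tolerance 1e-8); it agrees
with the scalar fitter to ~1e-4 and with `lifelines` to the same order, and
it is what makes leave-one-out cross-validation and thousand-signature
screens run in seconds.

## Cross-validated risk index

For each held-out patient j, every signature gene is fit univariately on the
other n−1 patients; RI_j = Σ_g β̂_g x_gj uses those coefficients, and the
cutoff is the empirical 80th percentile (linear interpolation) of the n−1
training risk indices under resubstitution. "Top 20th percentile" is read as
strictly above the 80th-percentile cutoff. Per-gene expression enters as-is
(no per-fold standardization; a z-scoring flag exists for sensitivity
analysis), and a fold's non-convergent or separated univariate fits
contribute zero coefficients there, keeping the score defined. The procedure
is deterministic.

Evaluation fits KM per group, the log-rank (and optionally
Gehan–Breslow–Wilcoxon) test, and a Cox model on the high/low indicator for
the hazard ratio with Wald CI; multivariate adjustment adds grade
(ordinal-linear), node (binary), size (continuous, cm), ER (binary), and/or
an external per-patient score (continuous).

**Known limitation — anti-conservatism.** Although each patient's index is
computed without their own outcome, the final log-rank test reuses all n
outcomes that informed every fold's coefficients (the folds share n−2
patients pairwise). This is the naive test on a pre-validated predictor,
known to be anti-conservative; with a 50-gene noise signature, 100 patients
and ~55 events, the measured null rejection rate at nominal 0.05 is ≈0.11
(600 replicates). The implementation reproduces the published procedure
faithfully — an exactly equivalent brute-force fold-by-fold loop with
independent Cox fits gives identical assignments — so p-values from this
construction should be read as optimistic, and the random-signature null
(below) is the more honest specificity reference. The same inflation
appears, attenuated, in the random-signature null itself when run with full
LOOCV on null cohorts (≈0.06–0.2 of random signatures reach p < 0.05
depending on the cohort draw).

## Random-signature null

M signatures (default 1,000) of the matched size are drawn uniformly without
replacement from the cohort's measured gene universe (optionally excluding
the observed signature's genes) and pushed through the same stratification;
their log-rank p-values form the null. Directions are set to +1 because the
risk-index pipeline estimates signs via Cox. The observed signature's
empirical tail uses (r+1)/(M+1); the best-5% cutoff is the 5th percentile of
the null p-values. A documented fast mode replaces LOOCV with a single
full-data fit per signature for large screens; it inherits resubstitution
optimism, so it is used for *relative* comparisons (observed vs null under
the same mode), never for absolute calibration.

## R-values by subtype

Expression over the signature genes is centered per gene on the centroid
mean — the mean of the two comparison-group means (default grouping: the
high/low risk groups; any two-grouping can be supplied) — and each patient's
R is the Pearson correlation of the ±1 direction pattern with their centered
values, with the t-transform p at n_genes − 2 df and the corresponding |r|
significance cutoff reported. A one-sided signature (all +1) has a constant
pattern and an undefined R; such patients are flagged rather than dropped.
Centering uses signature genes only.

## Synthetic generators

Two-class matrices plant a mean shift of `effect_size` log2 units (random
sign per gene, split ±e/2 around a zero baseline) in `n_de` genes, with iid
Gaussian noise. Defaults mirror the derivation setting exercised throughout:
1000 genes, 4 arrays per class, 50 DE genes at 2.0 log2 units, noise 0.5.

Cohorts draw per-gene standard-normal expression and exponential event times
with rate h0·exp(Σ_g β_g x_gj) (constant baseline h0 = 0.01/month, a ~70
month median under the null), independent exponential censoring (0.005/
month) and administrative cutoff at 120 months, giving ~55% events —
plausible for a 10-year breast-cancer follow-up. Subtypes are multinomial
over {basal 0.15, luminal A 0.35, luminal B 0.20, HER2 0.15, normal-like
0.15}; clinical covariates have documented marginals (grade uniform {1,2,3},
node Bernoulli(0.4), size log-normal with 2 cm median, ER Bernoulli(0.7))
and can be tied to the risk score through a mixing weight to create
confounding on demand. The "planted 20-gene signature" used in examples and
checks sets each gene's log HR to 1/√20 so the combined linear predictor has
unit variance and unit log-HR per standard deviation.

What the generators do *not* emulate: dye bias and batch effects, platform
differences between cohorts, correlated gene expression (co-expression
modules), non-proportional hazards, competing risks, and informative
censoring. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to those
real-data features.

All randomness flows through numpy's PCG64 generator; every public
stochastic entry point takes a seed or Generator, fixed seeds give
bit-identical outputs, and pipeline artifacts embed the seed and a config
hash. Pipeline outputs contain no timestamps, so re-runs at a fixed
configuration are byte-identical; files are written via temp-and-rename so
interrupted runs never leave truncated artifacts.

## Problem sizes used in checks

The automated checks run at desk scale, chosen to finish in minutes on one
CPU while keeping Monte-Carlo error well inside the asserted tolerances:
200 replicate cohorts (n = 100) for the null rejection rate, 50 replicates
(n = 500) for Cox parameter recovery, 1000 × (4+4) matrices for SAM
recovery, M = 200 random signatures for the null, and 20 replicates for the
specificity comparison (fast mode on both sides).
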