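# invasig

Derivation and survival validation of prognostic *invasion* gene-expression
signatures, built around the analysis style used for two-population tumor
microarray studies: a migratory (invasive) tumor-cell population is compared
against the average primary-tumor population to yield a differential-expression
signature, and that signature is then tested for prognostic value in
independent breast-cancer survival cohorts.

The package is a library first (`import invasig`), with narrative scripts in
`examples/` and a thin `invasig` command-line wrapper
(`simulate / preprocess / derive / validate / null / rvalue`).

## What it computes

**Derivation.** Two-channel arrays are normalized per array by global LOWESS
of M = log2(R/G) on A = ½·log2(R·G); probes collapse to genes by greatest
across-sample variance. Differential expression uses SAM (Significance
Analysis of Microarrays): a moderated statistic per gene

d_i = (x̄_i1 − x̄_i2) / (s_i + s0),

with s_i the pooled two-class standard error and s0 an exchangeability
constant, judged against permutation expected order statistics; the FDR at
each threshold Δ is the median permutation false-call count over the observed
call count. Genes called at the FDR target (default 10%) are ranked by
|log2 fold|, and the top k (default 80) form the signature.

**Validation.** For each patient j a risk index

RI_j = Σ_g β̂_g · x_gj

is built by leave-one-out cross-validation: each signature gene's univariate
Cox proportional-hazards coefficient β̂_g is fit on the n−1 other patients,
and patient j is called *high risk* when RI_j exceeds the 80th percentile of
the training risk indices. The high/low split is evaluated by Kaplan–Meier
curves, the (weighted) log-rank test (Gehan–Breslow–Wilcoxon weighting
available for early separation), a Cox hazard ratio on the group indicator
with Wald 95% CI, and multivariate Cox adjustment for grade, nodal status,
tumor size, ER status, or an external signature score. Specificity is judged
against M random signatures of matched size (default 1,000) run through the
same machinery, and per-patient signature resemblance by the R-value — the
Pearson correlation between the signature's ±1 direction pattern and
centroid-centered expression — grouped by intrinsic subtype.

All survival primitives (product-limit estimator, weighted log-rank,
Newton–Raphson partial-likelihood Cox with Efron ties, and a vectorized batch
univariate Cox that makes LOOCV × thousands of signatures tractable) are
implemented in `invasig.survival` and cross-checked against `lifelines` in
the test suite.

**Synthetic data.** `invasig.synthetic` generates the study substrates with
known ground truth: two-class matrices with planted log2 shifts, and
proportional-hazards cohorts (exponential baseline, planted per-gene log
hazard ratios, independent exponential censoring plus administrative cutoff,
intrinsic-subtype and clinical covariates).

## Worked example

```sh
python examples/02_validate_signature.py
```

```
high risk: 58, low risk: 242
hazard ratio 3.53 (95% CI 2.51-4.95)
log-rank p = 9.06e-15; Gehan-Breslow-Wilcoxon p = 1.05e-13
adjusted high-risk HR: 3.62
```

A 20-gene score with unit log-hazard variance was planted in a simulated
300-patient cohort; the LOOCV risk index flags 58 patients as high risk, who
have ~3.5-fold the hazard of the rest, and adjustment for clinical covariates
generated independently of the score leaves the hazard ratio essentially
unchanged — the signature carries independent prognostic information.
`examples/01_derive_signature.py` shows the SAM derivation (recall of planted
DE genes near 1 at a 10% FDR target), `03_random_signature_null.py` the
random-signature specificity control (a planted signature ranks 1st of 200
random gene lists), and `04_rvalue_by_subtype.py` the subtype R-value
analysis.

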