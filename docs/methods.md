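# Methods

This note documents the statistical model behind each stage of `bigsea`,
the defaults and why they are what they are, what the synthetic-data
generator does and does not emulate, and the numerical choices that matter
for reproducibility.

## Study design and data model

All operations assume a two-group design: a log2-scale expression matrix
(genes × samples), a two-level group factor with at least 2 samples per
group (≥ 3 for permutation tests), optional gene sets (GMT), and an
optional samples × markers table of clinical measurements. Input is taken
to be already background-corrected and normalized; raw-array processing is
out of scope. Missing values are rejected at read time rather than imputed,
because no imputation model is part of the method.

The low-expression filter removes a gene iff it falls below the intensity
floor (default 3, on whatever scale the input is on — for GCRMA-style log2
intensities this is the conventional "essentially off" level) on **strictly
more than** the given fraction of arrays (default 50%). The boundary case —
low on exactly half the arrays — retains the gene, reading "more than 50%"
literally. The filter is idempotent and order-preserving.

HOMA-IR, provided for assembling marker tables, is
`glucose [mg/dl] × insulin [µU/ml] / 22.5`.

## Per-gene differential expression

The baseline statistic is the ordinary least-squares fit of expression on
the group factor, equivalent to the pooled-variance two-sample t on
`n₁+n₂−2` df. Welch's correction is deliberately not offered: the pathway
statistics below are built from plain linear-model t values and the
permutation null makes their calibration exact regardless.

Empirical-Bayes moderation (used for the single-gene report, **not** for
the enrichment pipeline) places a scaled-inverse-χ²(d₀, s₀²) prior on the
residual variances, estimated by moment matching on log variances: with
`e_g = log s²_g − ψ(d/2) + log(d/2)`, the excess of `Var(e)` over
`ψ'(d/2)` identifies d₀ through the inverse trigamma (Newton iteration,
relative tolerance 1e-10), and the mean of `e` identifies s₀². Posterior
variances `(d₀s₀² + d·s²_g)/(d₀+d)` replace the per-gene values and t is
recomputed on `d₀+d` df. When the observed spread of log variances does not
exceed pure χ² sampling noise, d₀ is treated as infinite and every gene
receives s₀² (logged). Parameter recovery is verified in the tests to
within 15% relative error at 5000 genes.

BH adjustment is statsmodels' step-up `fdr_bh` throughout, validated
against a direct implementation to 1e-15.

## Permutation gene-set enrichment

For a set of k genes the statistic is the sum of per-gene t values divided
by k (signed mode) or the sum of |t| divided by k (absolute mode). Division
by k is the plain reading of "normalized for set size"; a √k option exists
but only rescales within a set — the permutation reference distribution
makes the test invariant to the choice.

The null permutes the **sample labels** (group sizes preserved) and refits
every gene's t; one relabelling produces one row of null statistics for all
sets simultaneously, preserving inter-gene and inter-set correlation (a
self-contained test). When the number of distinct assignments C(n, n₁) does
not exceed B, the scheme switches to exhaustive enumeration of all distinct
assignments, each exactly once; null rows are computed with the same
matrix-vector product as the observed statistics so that the identity
assignment ties the observed value bit-for-bit.

p-values are plug-in tail proportions with ties counted toward the
p-value: `p_up = #{T_b ≥ T_obs}/B`, `p_down = #{T_b ≤ T_obs}/B`, and
`p_bidir = #{A_b ≥ A_obs}/B` where the absolute-statistic null is built
from permuted |t| — never from |signed null|, which is a different (and
wrong) distribution. The plug-in estimator (no +1 smoothing) reproduces the
canonical worked example: observed above exactly 950 of 1000 permutation
values → p = 0.05. A `(count+1)/(B+1)` variant is not the default because
it cannot reproduce that example; users needing strictly positive p-values
can smooth downstream. B defaults to 1000. BH is applied across sets within
each of the three families separately, since the three statistics answer
different questions.

`pct_up`/`pct_down` report the percentage of set members with raw
(unmoderated) per-gene p < α moving in each direction; the raw p is used
because the enrichment pipeline is built entirely on unmoderated t values.

A practical caveat, visible in the tests: for a genuinely balanced
bi-directional set with large effects, the *signed* permutation test is not
calibrated (the set violates exchangeability even though its signed
statistic is centred at zero) and fires at above the nominal rate (~13% at
δ = 1.5σ). Directional and bi-directional p-values should therefore be read
jointly; the direction-class summary labels a set "bidirectional-only" when
q_bidir < α while neither directional q is.

## Regularized CCA and the relevance network

Expression and markers are z-scored (mean 0, variance 1, n−1 denominator)
**within each group** before CCA, which removes the treatment contrast and
leaves the covariation between genes and markers that holds irrespective of
treatment. Variables constant within a group are rejected, not dropped
silently. Global z-scoring is available for sensitivity analysis.

With sample covariance blocks S_xx, S_yy, S_xy and ridge terms λ₁, λ₂,
weights and canonical correlations come from the SVD of
`(S_xx+λ₁I)^{-1/2} S_xy (S_yy+λ₂I)^{-1/2}`; variates have unit variance
under the regularized metric, and the sign of each dimension is fixed by
making the largest-magnitude x-weight positive (deterministic across
refits, required for cross-validation). At λ = 0 this reduces exactly to
classical CCA (checked against a whitening oracle to 1e-8); the
implementation is numerically identical to mixOmics' `rcc(method="ridge")`,
verified in the test suite by running R. Eigenvalues below 1e-10 of the
largest trigger an error advising λ > 0 rather than whitening by noise.

λ's are selected on a user-supplied grid by leave-one-out cross-validation:
for each held-out sample, fit on the rest (re-centering within the fold),
project the held-out row on the first canonical weight pair, and score the
Pearson correlation of the n held-out (u, v) pairs; ties prefer smaller λ₁
then λ₂. The criterion is pinned here because the selection routine this
mirrors does not document one; the full score surface is exported so the
choice can be audited.

The gene–marker similarity over the first d dimensions uses the bisector
variates `Z_l = (U_l+V_l)/2`:
`s_jk = Σ_l corr(x_j, Z_l)·corr(y_k, Z_l)` — the association measure behind
mixOmics' `network` (matched to 1e-15 in the cross-check). Edges keep pairs
with `|s_jk| ≥ τ`; τ defaults to 0.65 and d to 6, the documented analysis
settings, with a scree table of canonical correlations emitted to guide
overriding d. Thresholding is on |s| because negative associations are
meaningful edges (drawn dashed in the conventional visualization).
Marker-associated genes are the conjunction: ≥ 1 retained edge AND
significant single-gene effect, gating on the BH-adjusted p by default (raw
p switchable).

## Overrepresentation

Each pathway is tested on the 2×2 table over a declared universe — the
set-annotated genes that entered the CCA, not the whole array. The
one-sided p is the hypergeometric upper tail P[X ≥ actual] (≡ one-sided
Fisher), validated against exact-rational enumeration for every feasible
table with N ≤ 60. The odds ratio is the conditional MLE (with the sample
odds ratio also reported), expected count is `size·K/N`, and no multiplicity
correction is applied by default since this table is conventionally read
with raw Fisher p-values; a BH column is optional.

## Synthetic-data generator

The generator emulates the target study design: two groups of 7 samples
(14 total), i.i.d. Normal(8, σ²) log2-like baselines, and additive mean
shifts of ±δσ in the treated group for genes of planted sets (regimes: up,
down, bidirectional — half up, half down, the extra gene up for odd sizes —
and null). Markers are built as
`ρ·(standardized mean of linked genes' within-group-centered values) +
√(1−ρ²)·noise`, so links are orthogonal to the treatment contrast by
construction and survive within-group z-scoring — encoding "correlated with
markers irrespective of treatment" as a testable property. Everything is
deterministic given the seed (markers use an independent child seed so
expression is unchanged by adding marker specs).

What it does **not** emulate: probe-level effects, intensity-dependent
variance, saturation, heavy tails, count noise, or correlated background
genes. Passing tests therefore demonstrate correctness of the statistical
machinery under the homoscedastic additive model, not robustness to
microarray artefacts.

### Reference recovery fixture

Network-recovery tests use a documented fixture at the study's scale:
n = 14 samples, 60 genes, 8 markers, link strength ρ = 0.8. Four
treatment-responsive genes (δ = 3σ; two up, two down) each track a *pair*
of markers, reflecting that clinical panels are internally correlated
(e.g. glucose/insulin, TAG/NEFA); the analysis uses d = 4 — the latent
dimensionality, the same scree-style decision the method prescribes — with
τ = 0.65 and a λ grid of {0.25, 1, 4}. Link strength 0.8 with one gene per
marker keeps the per-pair population correlation at 0.8; spreading a link
across a g-gene mean would dilute each gene's marker correlation by 1/√g
and place it below the 0.65 threshold by construction, which would test the
fixture rather than the method.

## Problem sizes and numerical choices

Simulation-based checks use: type-I calibration over 250 null studies × 8
sets at B = 500; bi-directional power over 200 replicates (set size 20,
δ = 1.5σ); exhaustive enumeration on 3-vs-3 designs (20 assignments). These
sizes give the binomial CIs quoted in the tests while keeping the default
suite fast. Tie handling in permutation counts is exact (see above);
enumeration oracles in tests compare with a 1e-9 tie tolerance because they
recompute t values along an independent code path.

## Known limitations

- Only two-group designs; no covariates, batch terms, or contrasts.
- The signed permutation test's anticonservativity for strongly
  bi-directional sets (above) is inherent to self-contained label
  permutation, not an implementation artefact.
- The LOO-CV criterion for λ and the exact similarity-measure definition
  are pinned choices among reasonable alternatives; results are
  reproducible only conditional on them (both are exported/auditable).
- Exact reproduction of published tables from the motivating study design
  is not claimed: those depend on the original raw-array processing and on
  margins that are not part of this package's inputs.
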