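# Methods

This note documents the statistical procedures implemented in
`protegoqtl`, the design decisions behind them, the synthetic-data
generator's model, and the limits of what the validation suite
demonstrates.

## 1. Input normalization and filtering

**Protein** (TMT log-ratio matrices): rows (protein markers) with more
than 20 % missing values are removed first; each sample column is then
divided by its raw median absolute deviation — median of absolute
deviations from the column median over non-missing entries, with *no*
1.4826 consistency constant and *no* centering — so every sample has
MAD = 1. The operation is idempotent. A zero-MAD column is treated as a
degenerate input and raises rather than silently producing infinities.
Filtering rows before scaling columns is a choice; the opposite order
changes results only marginally (the row filter does not depend on scale).

**mRNA** (FPKM matrices): values become log2(FPKM+1); genes with
FPKM == 0 (exact) in at least 90 % of samples are removed. Negative FPKM
is rejected.

**Mutations**: `Missense_Mutation` → missense; `Silent` → synonymous;
frameshift/in-frame indels, nonsense, nonstop, splice-site and
translation-start-site events → truncating; everything else → *other*,
which is never tested but still disqualifies its samples from control
groups. Classification is a pure function of the MAF
`Variant_Classification` vocabulary.

**Carrier sets**: one test unit per (gene, functional class) with ≥ 3
*distinct* carrier samples among tumors. Controls are tumors with no
mutation of *any* class in that gene, so e.g. truncation carriers never
contaminate the baseline of the same gene's missense test. The ≥ 3 rule is
re-checked per level after removing samples with a missing value in the
tested row; a unit can be testable at the mRNA level but not the protein
level. Missing protein values are never imputed. A control-side minimum of
3 is also enforced (a two-sample comparison with < 3 controls is too
unstable to report).

## 2. The QTL scans

Per unit, the tested expression row is the mutated gene's own (cis only).
Ordinary least squares of the expression vector on
`intercept + carrier indicator + covariates`, where covariates are age
(numeric) and gender / ethnicity / TMT batch (one-hot, reference level
dropped). Covariates that are constant — or categorical with a single
observed level — among the used samples are pruned; a design that is still
rank-deficient after pruning (e.g. carrier status perfectly confounded
with batch) is skipped with a recorded reason rather than fitted.

Residual variances s²_g with d_g degrees of freedom are shrunk across all
fits of a scan by empirical-Bayes moderation: the prior is scaled
inverse-chi-square with hyperparameters (d0, s0²) fitted by matching the
first two moments of log s²_g to the scaled-F marginal (digamma/trigamma
inversion; the trigamma inverse is solved by Newton iteration). The
posterior variance is (d0·s0² + d_g·s²_g)/(d0 + d_g) and the moderated t
refers to d0 + d_g degrees of freedom. Degenerate cases are explicit: if
the observed dispersion of log-variances does not exceed its sampling
component, d0 = ∞ and the posterior collapses to the df-weighted pooled
variance (which is also exact when all variances are identical); d0 = 0
recovers unmoderated OLS t-tests, available via `moderation=False` for
oracle comparisons. With no covariates and moderation off, the scan
p-value is identically the classical equal-variance two-sample t-test.

FDR: Benjamini–Hochberg step-up, one family per cohort × level across all
(gene, class) units jointly. A per-class family would also be defensible;
the joint family matches how per-cancer discovery counts are usually
reported and is the default.

## 3. spsQTL calling

Two candidate lists are intersected:

* **Method 1 — nested-model LRT.** Full model
  `p = μ + β0·g + β1·r (+ covariates)` versus reduced
  `p = μ + β2·r (+ covariates)`, fitted by least squares on complete-case
  samples (both levels observed). The test is the exact finite-sample
  nested-model F — F = ((RSS_red − RSS_full)/1)/(RSS_full/df_full),
  p from F(1, df_full) — rather than the asymptotic χ²; the two agree at
  large n and the F form is exact for Gaussian linear models at the small
  cohort sizes involved. BH across all units entering the LRT per cohort.
  An exactly-fitting full model (RSS ≈ 0 at machine precision) is flagged
  degenerate with p = 0.
* **Method 2 — overlap filter.** spQTL FDR < α and seQTL FDR > α. A unit
  with no seQTL record (untestable at mRNA level) does not pass: a
  protein-specific claim requires having actually looked at the mRNA.

A unit is an spsQTL iff both pass. Covariates are included in both nested
models by default (`include_covariates=False` reproduces the bare
two-variable form); since they appear in both models, their inclusion
changes df but not the logic of the comparison.

Concordance labels per testable unit: *concordant* (FDR < α at both
levels), *discordant_protein_specific* (spsQTL), *seqtl_only*, *neither*,
*untestable*. Effect-size concordance is summarized by the Pearson r of
(mRNA logFC, protein logFC) across units significant at both levels, and
by the same-sign fraction among significant seQTLs.

## 4. Paired tumor-normal differential expression

Patients with exactly one tumor and one normal sample are paired; per
(gene, class) unit, restricted to carrier patients, the per-patient
difference d = tumor − normal is regressed on an intercept plus pruned
covariates of the tumor sample, and the intercept is tested with the same
variance moderation and BH machinery. The difference-score formulation is
equivalent to a patient-blocked two-condition model for complete pairs and
is simpler. With ≥ 2 pairs a unit is testable; if covariates exhaust the
residual df the model falls back to intercept-only. With no covariates and
moderation off the test is identically the classical paired t-test.

## 5. mRNA–protein correlation groups

Per gene, Pearson r between the mRNA and protein rows over complete-case
tumor samples (n ≥ 3, both levels non-constant). Genes are grouped at gene
level by any-class membership: *discordant* if any unit of the gene is an
spsQTL, else *concordant* if any unit is labeled concordant, else *other*.
Group r distributions are compared with the two-sided two-sample Wilcoxon
rank-sum test: exhaustive enumeration of all C(n1+n2, n1) assignments of
the pooled values when both groups have ≤ 10 observations (correct under
ties; the two-sided p is the null probability of a U at least as far from
n1·n2/2 as observed), otherwise the midrank normal approximation with tie
and continuity corrections.

## 6. Mutation-level expression percentiles and functional scores

For a chosen gene, each distinct protein change is summarized by the mean
expression of its carriers (non-missing), placed on the cohort-wide sample
distribution as a percentile — the fraction of samples strictly below the
carrier mean, × 100. Strictly-below is the fixed tie convention. Mutations
observed across several cohorts keep their maximum percentile when pooled.
Three groups are formed with a top-fraction threshold (default 20 %,
i.e. percentile ≥ 80): (1) observed mutations in the top fraction,
(2) other observed mutations, (3) assayed-but-unobserved mutations; the
partition is disjoint and exhaustive by construction. External functional
scores are compared group1-vs-group2 and group1-vs-group3 with the same
rank-sum engine. The percentile reference is the cohort *sample*
distribution (not the distribution of mutation means); with a single
carrier the percentile is invariant under strictly monotone transforms of
the expression row, with several carriers the pre-averaging breaks exact
invariance — an accepted property of averaging on the measurement scale.

## 7. The synthetic cohort generator

Per gene g and tumor sample s, on log2 scales:

```
m_gs = b_g + σ·ε                   b_g ~ N(5, 1), σ = noise_sd
p_gs = c_g + ρ_g(m_gs − b_g) + sqrt(1 − ρ_g²)·σ·ε′ + batch(s)
```

so cor(m, p) = ρ_g (ρ_g ~ Uniform(rho_range)) and both residual scales are
σ. The written mRNA matrix is FPKM = 2^m − 1 (clipped at zero), so the
pipeline's log2(FPKM+1) recovers the latent values exactly and the real
normalization path is exercised; protein is written on its native
log-ratio scale with c_g ~ N(0, 1.4) chosen so raw sample columns already
sit near MAD 1 and the MAD scaling step is close to a no-op. TMT batch
offsets are N(0, batch_sd) per batch, added to protein only.

Mutations: each (gene, tumor) is a carrier with probability
`carrier_rate`; each carrier draws one functional class from `class_mix`
and one MAF-vocabulary record with a synthetic HGVS-p string. Effects are
assigned per gene from `effect_classes` with a random sign s·`effect_size`
and applied to **all** carriers of the gene (the truth table records one
row per (gene, class) with the gene's effect class, deltas, ρ and carrier
count):

* *concordant* — delta on mRNA before protein is computed (so ρ·delta
  propagates), topped up by (1 − ρ)·delta on protein: realized logFC is
  the full delta at both levels;
* *mrna_only* — ρ forced to 0 (the simplest mechanism by which an mRNA
  effect fails to propagate) and delta applied to mRNA alone;
* *protein_only* — delta on protein alone.

Protein entries are masked missing independently (MCAR) at
`missing_rate`. Paired normals redraw the patient's gene baselines with no
effects and no mutation records, so carrier-patient tumor−normal
differences center on the injected delta.

**Defaults as study conditions.** n_tumor = 100 and
n_paired_normal = 20 sit inside the 84–115 tumors / 10–100 normals range
typical of CPTAC cohorts; carrier_rate = 0.05 gives the sparse handful of
carriers per gene that motivates the ≥ 3 rule; class_mix
(0.5/0.3/0.2 missense/truncating/synonymous) reflects the predominance of
missense calls in exomes; rho_range (0.2, 0.8) spans typical per-gene
mRNA–protein correlations in tumor proteogenomics; noise_sd = 0.5 log2
units and batch_sd = 0.3 give signal-to-noise in line with TMT data;
missing_rate = 0.1 is at the low end of TMT missingness (the >20 % row
filter then bites only occasionally); effect_size = 2 log2 units
represents a strong, detectable-by-design effect. These are free
parameters of the generator, chosen once and exposed in `CohortConfig`.

**What the generator does not emulate:** MNAR missingness (real TMT
missingness is abundance-dependent), copy-number and trans effects,
per-mutation (rather than per-gene-class) effect heterogeneity, tumor
purity, isoform structure, and correlated genes. Passing recovery tests
therefore demonstrate that the statistics do what they claim under the
assumed model — not that the model captures every failure mode of real
proteogenomic data.

## 8. Validation experiments and problem sizes

The validation suite (and `scripts/acceptance.py`) uses: null calibration
on 20 cohorts of 150 tumors × 300 single-class gene units (pooled raw
p < 0.05 fraction within 0.05 ± 0.015 per level; BH discovery fraction
≤ 5 %); effect recovery on 20 cohorts of 150 tumors × 120 genes with
effect_size 2, noise 0.5, carrier rate 0.1 (units with ≥ 10 carriers:
concordant sensitivity at both levels and protein-only spsQTL sensitivity
≥ 0.8, concordant/mRNA-only false spsQTL rates ≤ 0.1); directional
concordance on 10 concordant-effect cohorts (same-sign fraction among
significant seQTLs ≥ 0.889); and variance-prior recovery from 5,000
scaled-F draws with d0 = 4, s0² = 1 (both estimates within 10 %). Exact
oracle equivalences (OLS vs normal equations, nested F vs two-RSS brute
force and vs squared t, BH vs threshold scan, rank-sum vs enumeration for
all group sizes with m+n ≤ 12, unmoderated scan vs classical t) are
asserted at 1e-9–1e-12. These sizes keep the full suite within a few
minutes on one CPU while leaving Monte-Carlo error well inside the asserted
margins.

## 9. Numerical choices and degenerate inputs

* OLS via explicit normal equations / `lstsq`; rank checked before
  inversion; rank-deficient designs raise (scans catch and log).
* Exact-fit responses (zero residual variance) yield p = 0 with a
  degeneracy flag instead of NaN.
* BH is NaN-aware: untested units pass through without counting toward
  the family size.
* The trigamma inverse uses the standard monotone Newton scheme with
  asymptotic guards at both ends.
* p-values are capped at 1; two-sided throughout; FDR threshold default
  0.05.
* Seeds: the generator is fully deterministic given `CohortConfig.seed`;
  the analysis itself contains no randomness.

## 10. Known limitations

* Gene-level carrier aggregation cannot resolve single-mutation effects,
  and cis-only testing misses trans regulation.
* The overlap filter's "seQTL FDR > α" accepts absence of evidence at the
  mRNA level as evidence of absence; truly borderline mRNA effects can
  leak into spsQTL calls.
* Linear covariate adjustment only; no interaction or nonlinear terms.
* The LRT assumes Gaussian residuals; heavy-tailed protein distributions
  inflate its small-sample type-I error somewhat.
* Group assignment for the correlation stage is gene-level and
  any-class; a gene with one concordant and one discordant unit counts as
  discordant.
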