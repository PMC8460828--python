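# Methods

This note documents the statistical procedures the package implements, the
choices made where the design was open, the synthetic-data model and its
limits, and the numerical conventions.

## 9p21 genotyping

Thresholded gene-level copy calls map to states −2→HD, −1→LOH, 0→WT,
+1/+2→GAIN. Cohort groups are defined on the (*CDKN2A*, *MTAP*) state pair:
HD at either locus → **LOSS**; LOH at both → **LOH**; WT at both → **WT**.
The remaining cells of the 4×4 grid (single-locus LOH, any gain) do not
match a named group; they are labelled **OTHER** and excluded from
WT-vs-LOSS contrasts explicitly rather than silently, so the four groups
always partition the cohort. Tumors carrying inactivating *CDKN2A*
mutations can be removed via an explicit exclusion list; the package does
not call mutations.

The expression surrogate uses strict inequalities against the within-cohort
medians: above both medians → hi_hi, below both → lo_lo, anything else
(including an exact tie with a median) → mixed. Strictness is the
conservative reading of an "above/below the median" rule and makes the
boundary behavior explicit; because the split is rank-based, surrogate
labels are invariant under any strictly monotone transform of the
expression values. Quartile labels use mean ascending ranks with cuts at
the 25/50/75 rank percentiles; ties share the quartile of their mean rank,
so an all-equal vector lands deterministically in Q3 and tie-free vectors
give quartile sizes differing by at most one.

## Immune profiling

Marker abundance is the arithmetic mean of a population's marker genes on
the log2 scale (an MCP-counter-style absolute score). The ten bundled
marker panels (B lineage, T cells, CD8 T cells, cytotoxic lymphocytes, NK
cells, monocytic lineage, myeloid dendritic cells, neutrophils, endothelial
cells, fibroblasts) ship as editable GMT files; the score definition, not
the specific gene lists, is what the package fixes.

ssGSEA ranks a sample's genes by decreasing expression (ties get mean-rank
weights) and accumulates the difference between the in-set ECDF weighted by
rank^α (α = 0.25) and the unweighted out-of-set ECDF; the score is the sum
of that difference over all positions. With `normalize=True` all scores are
divided by the global max − min of the score matrix (the usual projection
normalization). Both α and the normalization are exposed. Scores are
invariant to strictly monotone within-sample transforms; a gene set with an
empty complement has no out-of-set ECDF and is rejected.

TCR diversity is clonotype richness and Shannon entropy in nats
(H = −Σ pᵢ ln pᵢ); a `base="bits"` option rescales by ln 2. The entropy
base is a reporting convention only.

Differential abundance uses the two-sided Wilcoxon rank-sum test: the exact
null distribution when both groups have n ≤ 25 and the pooled values are
tie-free, otherwise the normal approximation with tie and continuity
corrections. Both modes are available because the choice is rarely reported
in cohort studies. Score fold changes are differences of group means
(scores are already log2-scale).

## Expression screens

Gene-level fold changes are computed on de-logged values: μ = mean(2^x − 1)
per group with pseudocount 1e−9, ratio r = μ_A/μ_B, reported as r when
r ≥ 1 and −1/r otherwise, so |signed_fc| ≥ 1 always and swapping groups
negates-reciprocates the value. A log-space difference mode is available;
linear ratio is the default because "fold change" thresholds like 1.2 read
most naturally on the linear scale. The Benjamini–Hochberg family is the
tested gene list only (a curated screen, not the transcriptome);
zero-variance genes get p = NA and leave the family. BH uses the standard
step-up with enforced monotonicity; q ≥ p elementwise and q is
non-decreasing in p-rank.

Spearman screening computes ρ with mean-rank ties and the t-approximation
p-value per anchor gene, BH within anchor, and tiers anti-correlation at
ρ < −0.2 (moderate) and ρ < −0.4 (strong).

## Outcome statistics

Fisher's two-sided 2×2 exact test uses the sum-of-small-probabilities rule:
p is the total probability of margin-preserving tables whose point
probability is at most the observed one times (1 + 1e−7). The r×c
generalization (Freeman–Halton) enumerates all margin-preserving tables
depth-first; when a loose bound on the table count exceeds `max_tables`, a
seeded Monte-Carlo mode estimates the same tail by sampling tables from the
fixed-margins null (row-by-row multivariate hypergeometric construction)
with an add-one estimate so p never returns exactly 0. Zero-margin tables
return p = 1 with a warning. The likelihood-ratio test is
G² = 2 Σ O ln(O/E) with 0·ln 0 ≡ 0 against χ² with (r−1)(c−1) df.

Durable clinical benefit is CR/PR, or SD with progression-free survival
strictly greater than 6 months; SD with unknown PFS is indeterminate (NA).

The response score is additive and deterministic: 2 points for TMB strictly
above the cohort median (ties at the median score low — the split is
"greater than the median"), 1 point for hi_hi, 1 point for immune-cell
PD-L1 IC2+ (≥5% staining); tiers are low {0}, intermediate {1, 2}, high
{3, 4}. The 2:1:1 weighting mirrors the relative magnitude of the logistic
regression coefficients of the three factors;
`derive_score_weights` reproduces the integer weights from any fitted
coefficient vector as round(|β_i|/min|β_j|) floored at 1. Samples missing
any component (TMB, PD-L1, surrogate) are excluded with a reported count
rather than imputed. TMB is treated as unitless throughout — cohorts mix
mutation counts and mutations/Mb, and only the within-cohort median split
is ever used.

Logistic factor models are maximum-likelihood fits with Wald p-values;
perfect separation triggers an L2-penalized refit flagged on the result.

## Survival

Kaplan–Meier, log-rank, and Cox fits are delegated to lifelines. The median
is the earliest time with S ≤ 0.5 (NA when never reached); at tied times
events precede censorings. Cox uses Efron tie handling — the more accurate
of the two common conventions, chosen as the default since the convention
is rarely stated in cohort reports. Endpoints (OS/PFS/DSS) are selected per
cohort by configuration. For a single binary covariate the log-rank
statistic coincides with the Cox partial-likelihood score test, which the
test suite verifies against a hand-computed score statistic. Both omnibus
(k-sample) and pairwise log-rank comparisons are exposed, since multi-group
reports can mean either.

## Synthetic cohort model

Per sample: genotype LOSS/LOH/WT with frequencies 0.13/0.25/0.62 (the
approximate pan-cancer frequency of homozygous 9p21 loss, and the observed
hemizygous-loss range). *CDKN2A*/*MTAP* log2 expression is baseline (5.0)
minus 3.0 under HD (strong reduction) or 0.3 under LOH (subtle), plus
Normal(0, 0.5) noise. A single latent infiltration factor
z ~ Normal(−1.0·[LOSS], 1) drives every immune marker gene (coupling 1.0)
— one factor, not per-population factors, is the minimal structure that
reproduces correlated depletion of T/B/NK scores; it is a modeling choice,
not a biological claim. Immunomodulatory genes additionally shift in LOSS
samples (+0.8 suppressive set, −0.8 trafficking/activation sets); candidate
target genes are coupled negatively (0.5) to the anchors' expression. TMB
is log-normal(2, 1); the PD-L1 IC category follows a cumulative logit on z;
the responder flag is Bernoulli(logit⁻¹(β₀ + β_tmb·[TMB high] +
β_surr·[hi_hi] + β_pdl1·[IC2+])) with the hi_hi label derived from the
generated expression exactly as the pipeline derives it; overall and
progression-free survival are exponential with the hazard multiplied by
`hr_loss` (default 2.0) in LOSS samples and administrative censoring
Uniform(12, 36) months. Clonotype counts are Dirichlet-multinomial over a
shared pool with richness and concentration increasing in z, so LOSS
samples have lower expected richness and entropy.

Preset calibration: the `imvigor-like` preset (β₀ = −3.2, β = 1.4/1.45/0.7)
was tuned once, by a coarse sweep over the intercept and surrogate
coefficient, so the expected marginal hi_hi/lo_lo response rates sit at
~32%/12%; `melanoma-like` (β₀ = −2.35, β_surr = 1.85) targets ~60%/22%;
`null` zeroes every genotype-linked effect (expression deltas, infiltration
shift, immunomodulatory shifts, target coupling, all response coefficients
except the intercept, hazard ratio 1). All randomness flows from one seed
through per-table sub-streams, so editing one block leaves the others
byte-identical.

What the generator does **not** emulate: tumor purity, segment-level CNV
geometry, count-based expression noise (values are Gaussian on the log
scale), per-cell-type infiltration structure, covariance between TMB and
genotype, non-proportional hazards, or cohort batch effects. Passing
recovery tests therefore show that the pipeline's estimators are correct
and calibrated under the assumed structure — not that real cohorts satisfy
that structure.

## Problem sizes and numerical conventions

Recovery experiments use cohorts of n = 2000 across 20 seeded replicates in
the test suite (10 in the acceptance script); exact-test oracle sweeps
cover every 2×2 table with N ≤ 40. Comparisons against brute-force oracles
use absolute tolerances of 1e−9…1e−12; the Fisher small-probability
tolerance is relative 1e−7. Degenerate inputs are handled explicitly:
zero-margin tables (p = 1 with warning), zero-variance genes (NA, out of
the BH family), all-zero clonotype samples (NA with warning), all-censored
survival (median NA), constant covariates and single-class outcomes
(errors).

## Known limitations

Fold-change scale for published thresholds is ambiguous (linear vs log);
both are implemented, linear is default. The exact-vs-asymptotic Wilcoxon
choice can change q-values near the threshold for small cohorts. The r×c
enumeration grows quickly with margins; the Monte-Carlo fallback is
estimator-exact only in expectation (add-one estimate, seeded). Survival
fits assume proportional hazards and right-censoring only; no competing
risks, time-varying covariates, or restricted-mean summaries.
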