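# ninep21

Immunogenomic analysis of homozygous 9p21.3 deletion ("9p21 loss") and its
consequences for the tumor-immune microenvironment and immune checkpoint
therapy (ICT) response.

The chromosomal region 9p21.3 carries *CDKN2A* and *MTAP* and, a little
upstream, the type I interferon gene cluster; homozygous deletion of the
locus is among the most frequent somatic copy-number events in cancer
(~13% pan-cancer). Tumors with 9p21 loss tend to be immunologically "cold"
— depleted T/B/NK compartments, reduced TCR repertoire diversity, attenuated
immune signaling, lower PD-L1 positivity — and respond poorly to anti-PD-1 /
anti-PD-L1 monotherapy. This package implements the full analysis chain that
supports those claims, for analysts working with cohort-level expression,
copy-number, and clinical tables.

## What it computes

* **9p21 genotyping** (`ninep21.genotyping`) — thresholded copy calls
  (GISTIC-style, −2…+2) mapped to HD/LOH/WT/GAIN per locus; cohort groups
  **LOSS** (HD of *CDKN2A* or *MTAP*), **LOH** (hemizygous at both), **WT**
  (diploid at both), **OTHER** (anything else, excluded explicitly). When
  only expression is available, the surrogate labels **hi_hi** / **lo_lo**
  (both genes above / below their cohort medians) and per-gene quartiles.
* **Immune profiling** (`ninep21.profiling`) — marker-gene abundance scores
  (mean log2 expression per population), ssGSEA pathway scores (per-sample
  rank-weighted running sum, weight exponent α = 0.25), TCR clonotype
  richness and Shannon entropy H = −Σ pᵢ ln pᵢ, and Wilcoxon rank-sum
  differential abundance with Benjamini–Hochberg q-values.
* **Expression screens** (`ninep21.screen`) — curated-list differential
  expression (signed linear-scale fold change with |FC| ≥ 1.2, q < 0.05
  cutoffs) and Spearman anti-correlation screening against *CDKN2A*/*MTAP*
  (tiers at ρ < −0.2 and ρ < −0.4).
* **Outcome statistics** (`ninep21.outcomes`) — durable clinical benefit
  (CR/PR or SD lasting > 6 months), contingency construction, two-sided
  Fisher exact tests (2×2 and Freeman–Halton r×c with seeded Monte-Carlo
  fallback), likelihood-ratio χ², response-rate comparisons, logistic factor
  models, and the composite **response score**: 2 points for TMB above the
  cohort median, 1 for hi_hi, 1 for immune-cell PD-L1 IC2+ (≥5%), tiered
  low (0) / intermediate (1–2) / high (3–4).
* **Survival** (`ninep21.survival`) — Kaplan–Meier curves and medians,
  k-sample and pairwise log-rank tests, Cox proportional-hazards fits
  (Efron ties) for OS/PFS/DSS endpoints.
* **Synthetic cohorts** (`ninep21.simulate`) — a generator with the same
  statistical structure (copy-state-coupled anchor expression, a latent
  infiltration factor, TMB/PD-L1, a logistic response model, proportional
  hazards) plus a ground-truth ledger, with calibrated presets
  (`imvigor-like`, `melanoma-like`, `null`).

## Worked example

```python
import pandas as pd
from ninep21.outcomes import response_rates_compare

# combined melanoma cohort: 27/45 responders (hi_hi) vs 9/41 (lo_lo)
ids = [f"P{i}" for i in range(86)]
outcome = pd.Series([True]*27 + [False]*18 + [True]*9 + [False]*32,
                    index=ids, dtype=object)
strata = pd.Series(["hi_hi"]*45 + ["lo_lo"]*41, index=ids)
print(response_rates_compare(outcome, strata, ("hi_hi", "lo_lo")))
```

prints

```
stratum  responders  total   rate  rate_ratio      p
  hi_hi          27     45 0.6000      2.7333 0.0004
  lo_lo           9     41 0.2195      2.7333 0.0004
```

— a 60% response rate in tumors with intact 9p21 expression versus 22% in
the deletion-like lo_lo group, a 2.7-fold difference with a two-sided Fisher
exact p of 4×10⁻⁴. The `examples/` directory holds one short script per
capability (genotyping, immune profiling, response stratification, survival,
target screening); each prints its numbers with a note on what they mean.

A thin CLI mirrors the stages:

```sh
ninep21 simulate --preset imvigor-like --n 400 --seed 1 --out cohort/
ninep21 run --expr cohort/expression.tsv --clinical cohort/clinical.tsv \
        --basis surrogate --seed 1 --out bundle/
```

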