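"""Differential expression of curated gene lists and Spearman target screening.

Two screens over a curated gene list (druggable targets, immunomodulatory
genes):

* :func:`deg_screen` — per-gene Wilcoxon rank-sum contrast between two sample
  groups with a signed fold change computed on de-logged expression (ratio of
  linear-scale group means; ratios below 1 are reported as the negative
  reciprocal so |signed_fc| >= 1 always).  A gene "passes" when
  |signed_fc| >= fc_threshold and BH q < q_threshold.
* :func:`spearman_target_screen` — Spearman correlation of each listed gene
  with the two anchor genes (*CDKN2A*, *MTAP*); strong anti-correlation
  (rho < -0.4) flags candidate targets upregulated when the anchors are lost.

Benjamini-Hochberg correction is applied across the tested list only, not the
transcriptome, since the screens operate on curated lists.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError
from .io import ExpressionMatrix, GeneSetCollection


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    NA entries are excluded from the family size m and returned as NA.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
        raise AnalysisError("p-value outside [0, 1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when both groups have n <= ``exact_max_n`` and the
    pooled values contain no ties; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = (
        "exact"
        if (len(a) <= exact_max_n and len(b) <= exact_max_n and not has_ties)
        else "asymptotic"
    )
    return float(
        mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True).pvalue
    )


def signed_fold_change(
    xa: np.ndarray, xb: np.ndarray, scale: str = "linear", eps: float = 1e-9
) -> float:
    """Signed fold change of group A over group B for a log2-scale gene.

    ``scale="linear"`` (default): de-log with 2**x - 1, take the ratio of
    group means (pseudocount eps), and report ratios < 1 as -1/ratio.
    ``scale="log"``: the difference of log2 means, exponentiated to a ratio
    and signed the same way.
    """
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    if scale == "linear":
        mu_a = np.mean(2.0**xa - 1.0)
        mu_b = np.mean(2.0**xb - 1.0)
        r = (mu_a + eps) / (mu_b + eps)
    elif scale == "log":
        r = 2.0 ** (xa.mean() - xb.mean())
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return float(r) if r >= 1.0 else float(-1.0 / r)


def deg_screen(
    expr: ExpressionMatrix,
    groups: pd.Series,
    gene_list: GeneSetCollection | list[str],
    contrast: tuple[str, str],
    fc_threshold: float = 1.2,
    q_threshold: float = 0.05,
    fc_scale: str = "linear",
) -> pd.DataFrame:
    """Differential expression screen of a curated gene list between two groups.

    Returns a DataFrame with columns gene, signed_fc, p, q, passes; q is BH
    over the tested genes only.  Zero-variance genes get p = NA and are
    excluded from the BH family.  Both groups need >= 3 samples.
    """
    genes = (
        sorted({g for name in gene_list.names for g in gene_list[name]})
        if isinstance(gene_list, GeneSetCollection)
        else list(gene_list)
    )
    genes = [g for g in genes if g in expr.values.index]
    if not genes:
        raise AnalysisError("no listed gene is present in the expression matrix")
    label_a, label_b = contrast
    common = expr.values.columns.intersection(groups.index)
    g = groups.loc[common]
    a_ids = g.index[g == label_a]
    b_ids = g.index[g == label_b]
    if len(a_ids) < 3 or len(b_ids) < 3:
        raise AnalysisError(
            f"need >=3 samples per group, got {len(a_ids)} vs {len(b_ids)}"
        )
    rows = []
    for gene in genes:
        xa = expr.values.loc[gene, a_ids].dropna().to_numpy()
        xb = expr.values.loc[gene, b_ids].dropna().to_numpy()
        if len(xa) < 3 or len(xb) < 3:
            continue
        fc = signed_fold_change(xa, xb, scale=fc_scale)
        if np.ptp(np.concatenate([xa, xb])) == 0:
            p = np.nan  # zero variance: no test
        else:
            p = wilcoxon_rank_sum(xa, xb)
        rows.append({"gene": gene, "signed_fc": fc, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["passes"] = (np.abs(out["signed_fc"]) >= fc_threshold) & (out["q"] < q_threshold)
    out["passes"] = out["passes"].fillna(False)
    return out[["gene", "signed_fc", "p", "q", "passes"]]


def spearman_target_screen(
    expr: ExpressionMatrix,
    anchor_genes: tuple[str, str],
    gene_list: GeneSetCollection | list[str],
) -> pd.DataFrame:
    """Spearman correlation of each listed gene with each anchor gene.

    Ties get mean ranks; p comes from the t-approximation; q is BH per anchor
    across the tested list.  The tier flags anti-correlated candidates:
    strong (rho < -0.4), moderate (rho < -0.2), else none.  Constant genes or
    anchors yield rho = NA.
    """
    genes = (
        sorted({g for name in gene_list.names for g in gene_list[name]})
        if isinstance(gene_list, GeneSetCollection)
        else list(gene_list)
    )
    genes = [g for g in genes if g in expr.values.index]
    if not genes:
        raise AnalysisError("no listed gene is present in the expression matrix")
    if expr.values.shape[1] < 10:
        raise AnalysisError("Spearman screen needs >=10 samples")
    rows = []
    for anchor in anchor_genes:
        if anchor not in expr.values.index:
            raise AnalysisError(f"anchor gene {anchor!r} absent from expression matrix")
        x = expr.values.loc[anchor]
        for gene in genes:
            y = expr.values.loc[gene]
            ok = x.notna() & y.notna()
            xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
            if len(xv) < 3 or np.ptp(xv) == 0 or np.ptp(yv) == 0:
                rho, p = np.nan, np.nan
            else:
                rho, p = spearmanr(xv, yv)
            rows.append({"anchor": anchor, "gene": gene, "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for anchor in anchor_genes:
        mask = out["anchor"] == anchor
        out.loc[mask, "q"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    out["tier"] = "none"
    out.loc[out["rho"] < -0.2, "tier"] = "moderate"
    out.loc[out["rho"] < -0.4, "tier"] = "strong"
    out.loc[out["rho"].isna(), "tier"] = pd.NA
    return out[["anchor", "gene", "rho", "p", "q", "tier"]]
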