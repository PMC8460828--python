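"""Per-sample immune abundance, pathway enrichment, TCR diversity, and
group-wise differential abundance.

Abundance is scored two ways, both producing a feature x sample ScoreMatrix:

* **marker-mean** — the arithmetic mean of a cell population's marker genes on
  the log2 expression scale (MCP-counter-style absolute abundance score).
* **ssGSEA** — single-sample gene-set enrichment: per sample, genes are ranked
  by expression and the score is the running-sum difference between the
  rank-weighted in-set ECDF (weights ``|rank|^alpha``) and the unweighted
  out-of-set ECDF.  Scores are rank-based, hence invariant to strictly
  monotone within-sample transforms.

Group contrasts use the two-sided Wilcoxon rank-sum test (exact when both
groups have n <= 25 and no ties, otherwise the normal approximation with tie
and continuity corrections) with Benjamini-Hochberg correction across
features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import AnalysisError
from .io import ExpressionMatrix, GeneSetCollection
from .screen import bh_adjust, wilcoxon_rank_sum


@dataclass
class ScoreMatrix:
    """Feature x sample score table with the method that produced it."""

    scores: pd.DataFrame
    method: str  # "marker-mean" | "ssgsea"


def marker_abundance_scores(
    expr: ExpressionMatrix, markers: GeneSetCollection
) -> ScoreMatrix:
    """Mean log2 expression of each population's marker genes, per sample.

    Marker genes absent from the matrix are ignored; a population with no
    marker present is dropped with a warning.  NA expression values are
    excluded from the mean (a sample with all-NA markers scores NA).
    """
    rows = {}
    dropped = []
    for name in markers.names:
        present = [g for g in markers[name] if g in expr.values.index]
        if not present:
            dropped.append(name)
            continue
        rows[name] = expr.values.loc[present].mean(axis=0, skipna=True)
    if not rows:
        raise AnalysisError("no marker set has any gene in the expression matrix")
    if dropped:
        warnings.warn(f"marker set(s) with zero present genes dropped: {dropped}")
    return ScoreMatrix(pd.DataFrame(rows).T, method="marker-mean")


def _ssgsea_sample(
    values: np.ndarray, set_mask: np.ndarray, alpha: float
) -> float:
    """Enrichment score of one gene set in one sample.

    Genes are ordered by decreasing expression (ties keep their mean rank
    weight).  Walking down the ordering, the in-set running sum accumulates
    ``rank^alpha`` (rank = mean ascending rank, so the top gene carries the
    largest weight) normalized by the in-set total, the out-of-set running sum
    accumulates 1/(N - |S|); the score is the sum over positions of their
    difference.
    """
    n = values.size
    asc_ranks = rankdata(values, method="average")  # highest expression -> rank n
    order = np.argsort(-values, kind="stable")
    in_set = set_mask[order]
    w = np.abs(asc_ranks[order]) ** alpha
    w[~in_set] = 0.0
    denom_in = w.sum()
    n_out = n - int(set_mask.sum())
    p_in = np.cumsum(w) / denom_in
    p_out = np.cumsum((~in_set).astype(float)) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    expr: ExpressionMatrix,
    pathways: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> ScoreMatrix:
    """ssGSEA pathway scores for every sample.

    With ``normalize=True`` all scores are divided by the global (max - min)
    across the whole score matrix, the usual projection normalization.
    Pathways with fewer than 2 genes present are dropped with a warning;
    a pathway covering every gene in the matrix (empty complement) is an
    error.  Samples with any NA expression are scored on their non-NA genes.
    """
    genes = np.asarray(expr.values.index)
    n_genes = len(genes)
    masks = {}
    dropped = []
    for name in pathways.names:
        mask = np.isin(genes, pathways[name])
        k = int(mask.sum())
        if k >= n_genes:
            raise AnalysisError(f"pathway {name!r} covers every gene (empty complement)")
        if k < 2:
            dropped.append(name)
            continue
        masks[name] = mask
    if not masks:
        raise AnalysisError("no pathway has >=2 genes in the expression matrix")
    if dropped:
        warnings.warn(f"pathway(s) with <2 present genes dropped: {dropped}")

    out = pd.DataFrame(
        np.nan, index=list(masks), columns=expr.values.columns, dtype=float
    )
    mat = expr.values.to_numpy(dtype=float)
    for j, sample in enumerate(expr.values.columns):
        col = mat[:, j]
        ok = ~np.isnan(col)
        for name, mask in masks.items():
            m = mask[ok]
            if m.sum() < 2 or m.sum() >= ok.sum():
                continue
            out.at[name, sample] = _ssgsea_sample(col[ok], m, alpha)
    if normalize:
        lo, hi = np.nanmin(out.to_numpy()), np.nanmax(out.to_numpy())
        if hi > lo:
            out = out / (hi - lo)
    return ScoreMatrix(out, method="ssgsea")


def tcr_diversity(clonotypes: pd.DataFrame, base: str = "nats") -> pd.DataFrame:
    """Richness and Shannon entropy of each sample's clonotype repertoire.

    ``clonotypes`` is clonotype x sample counts.  Richness counts clonotypes
    with positive count; entropy is H = -sum p_i ln p_i in nats by default
    (``base="bits"`` rescales to log2).  All-zero samples get NA with a
    warning.
    """
    if (clonotypes.to_numpy() < 0).any():
        raise AnalysisError("negative clonotype count")
    rows = []
    empty = []
    for sample in clonotypes.columns:
        counts = clonotypes[sample].to_numpy(dtype=float)
        counts = counts[counts > 0]
        if counts.size == 0:
            empty.append(sample)
            rows.append((sample, np.nan, np.nan))
            continue
        p = counts / counts.sum()
        h = float(-(p * np.log(p)).sum())
        if base == "bits":
            h /= np.log(2.0)
        rows.append((sample, int(counts.size), h))
    if empty:
        warnings.warn(f"sample(s) with no positive clonotype count: {empty}")
    out = pd.DataFrame(rows, columns=["sample_id", "richness", "shannon"])
    return out.set_index("sample_id")


def differential_abundance(
    scores: ScoreMatrix,
    groups: pd.Series,
    contrast: tuple[str, str],
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Per-feature Wilcoxon comparison of scores between two groups.

    ``log2_fc`` is the difference of group means (scores are log2-scale), with
    the first contrast label as numerator group.  Features where either group
    has fewer than ``min_group_size`` non-NA scores are skipped.  Returns a
    DataFrame with columns feature, log2_fc, p, q, n_a, n_b; q is
    Benjamini-Hochberg across the tested features.
    """
    label_a, label_b = contrast
    for lab in contrast:
        if not (groups == lab).any():
            raise AnalysisError(f"group {lab!r} absent from labels")
    common = scores.scores.columns.intersection(groups.index)
    g = groups.loc[common]
    a_ids = g.index[g == label_a]
    b_ids = g.index[g == label_b]
    rows = []
    for feature in scores.scores.index:
        xa = scores.scores.loc[feature, a_ids].dropna().to_numpy()
        xb = scores.scores.loc[feature, b_ids].dropna().to_numpy()
        if len(xa) < min_group_size or len(xb) < min_group_size:
            continue
        if np.ptp(np.concatenate([xa, xb])) == 0:
            p = 1.0
        else:
            p = wilcoxon_rank_sum(xa, xb)
        rows.append(
            {
                "feature": feature,
                "log2_fc": float(xa.mean() - xb.mean()),
                "p": p,
                "n_a": len(xa),
                "n_b": len(xb),
            }
        )
    if not rows:
        raise AnalysisError("no feature has enough samples in both groups")
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out[["feature", "log2_fc", "p", "q", "n_a", "n_b"]]
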