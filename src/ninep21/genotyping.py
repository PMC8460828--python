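"""9p21.3 copy-state classification and per-sample stratification labels.

The locus 9p21.3 carries *CDKN2A* and *MTAP* (~100 kb apart, commonly
co-deleted) and, ~320 kb upstream of *MTAP*, the type I interferon gene
cluster.  Samples are stratified three ways, depending on which data are
available:

* **genomic** — from thresholded copy calls: homozygous deletion (HD, call -2)
  of either *CDKN2A* or *MTAP* defines the LOSS group; LOH (-1) at both loci
  defines LOH; diploid wildtype (0) at both defines WT.  Any other combination
  (single-locus LOH, copy gain) is labelled OTHER and excluded from WT-vs-LOSS
  contrasts explicitly rather than silently.
* **surrogate** — from expression: samples with both *CDKN2A* and *MTAP*
  strictly above their within-cohort medians are ``hi_hi``, strictly below
  both are ``lo_lo``, anything else (including exact ties at a median) is
  ``mixed``.  Median splits are rank-based, so the labels are invariant under
  any strictly monotone transform of the expression values.
* **quartiles** — per-gene expression quartiles (Q1 = lowest), used for
  dose-response-style stratification of response rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import AnalysisError
from .io import CopyCallTable, ExpressionMatrix

CDKN2A = "CDKN2A"
MTAP = "MTAP"


class GeneCopyState(str, Enum):
    HD = "HD"        # homozygous deletion (call -2)
    LOH = "LOH"      # hemizygous deletion / loss of heterozygosity (call -1)
    WT = "WT"        # diploid (call 0)
    GAIN = "GAIN"    # copy gain or amplification (call +1 / +2)


class NineP21Group(str, Enum):
    WT = "WT"
    LOH = "LOH"
    LOSS = "LOSS"
    OTHER = "OTHER"


@dataclass
class NineP21Call:
    sample_id: str
    group: NineP21Group
    basis: str  # "genomic" | "surrogate" | "ihc"


def classify_gene_call(call: int) -> GeneCopyState:
    """Map a thresholded integer copy call to its copy state.

    -2 -> HD, -1 -> LOH, 0 -> WT, +1/+2 -> GAIN.
    """
    call = int(call)
    if call == -2:
        return GeneCopyState.HD
    if call == -1:
        return GeneCopyState.LOH
    if call == 0:
        return GeneCopyState.WT
    if call in (1, 2):
        return GeneCopyState.GAIN
    raise AnalysisError(f"copy call {call} outside -2..+2")


def assign_9p21_group(
    cdkn2a: GeneCopyState, mtap: GeneCopyState, sample_id: str = "", basis: str = "genomic"
) -> NineP21Call:
    """Assign the 9p21 stratification group from the two locus states.

    HD of either gene -> LOSS; LOH at both -> LOH; WT at both -> WT; every
    remaining cell of the 4x4 state grid -> OTHER.
    """
    if GeneCopyState.HD in (cdkn2a, mtap):
        group = NineP21Group.LOSS
    elif cdkn2a == GeneCopyState.LOH and mtap == GeneCopyState.LOH:
        group = NineP21Group.LOH
    elif cdkn2a == GeneCopyState.WT and mtap == GeneCopyState.WT:
        group = NineP21Group.WT
    else:
        group = NineP21Group.OTHER
    return NineP21Call(sample_id=sample_id, group=group, basis=basis)


def genotype_cohort(
    calls: CopyCallTable,
    cdkn2a: str = CDKN2A,
    mtap: str = MTAP,
    exclude: list[str] | None = None,
) -> pd.DataFrame:
    """Genotype every sample in a copy-call table.

    Returns a DataFrame indexed by sample_id with columns ``group`` and
    ``basis``.  Samples with a missing call at either locus are excluded with
    a warning; ``exclude`` drops listed samples up front (e.g. tumors with
    truncating *CDKN2A* mutations, supplied as an external list).
    """
    for g in (cdkn2a, mtap):
        if g not in calls.calls.index:
            raise AnalysisError(f"gene {g!r} absent from copy-call table")
    excluded = set(exclude or [])
    rows = {}
    skipped = []
    for sid in calls.sample_ids:
        if sid in excluded:
            continue
        c, m = calls.get(sid, cdkn2a), calls.get(sid, mtap)
        if pd.isna(c) or pd.isna(m):
            skipped.append(sid)
            continue
        call = assign_9p21_group(classify_gene_call(c), classify_gene_call(m), sid)
        rows[sid] = call.group.value
    if skipped:
        warnings.warn(f"{len(skipped)} sample(s) without calls at both loci excluded")
    out = pd.DataFrame({"group": pd.Series(rows, dtype=object)})
    out["basis"] = "genomic"
    out.index.name = "sample_id"
    return out


def surrogate_from_expression(
    expr: ExpressionMatrix, genes: tuple[str, str] = (CDKN2A, MTAP)
) -> pd.Series:
    """Label each sample hi_hi / lo_lo / mixed from the two genes' medians.

    Strictly above both within-cohort medians -> hi_hi; strictly below both ->
    lo_lo; otherwise (including equality with a median) -> mixed.  Medians are
    taken over all non-NA samples in the input cohort.
    """
    g1, g2 = genes
    for g in genes:
        if g not in expr.values.index:
            raise AnalysisError(f"gene {g!r} absent from expression matrix")
    if expr.values.shape[1] < 4:
        raise AnalysisError("surrogate labelling needs >=4 samples")
    x1 = expr.values.loc[g1]
    x2 = expr.values.loc[g2]
    m1 = x1.median(skipna=True)
    m2 = x2.median(skipna=True)
    labels = pd.Series("mixed", index=expr.values.columns, dtype=object, name="surrogate")
    labels[(x1 > m1) & (x2 > m2)] = "hi_hi"
    labels[(x1 < m1) & (x2 < m2)] = "lo_lo"
    labels[x1.isna() | x2.isna()] = pd.NA
    return labels


def quartile_stratify(expr: ExpressionMatrix, gene: str) -> pd.Series:
    """Quartile label per sample for one gene (Q1 = lowest expression).

    Ranking is ascending with mean ranks for ties; cut points sit at the
    25/50/75 rank percentiles, so quartile sizes differ by at most one when no
    tie straddles a boundary, and all-equal input lands deterministically in
    the quartile of the shared mean rank.
    """
    if gene not in expr.values.index:
        raise AnalysisError(f"gene {gene!r} absent from expression matrix")
    x = expr.values.loc[gene].dropna()
    n = len(x)
    if n < 4:
        raise AnalysisError(f"quartile stratification needs >=4 non-NA samples, got {n}")
    ranks = rankdata(x.to_numpy(), method="average")
    # mean rank r in (0, n]; quartile = smallest q with r <= q*n/4
    qidx = np.minimum(np.ceil(4.0 * ranks / n).astype(int), 4)
    labels = pd.Series(pd.NA, index=expr.values.columns, dtype=object, name=f"{gene}_quartile")
    labels[x.index] = [f"Q{q}" for q in qidx]
    return labels


def ifn_codeletion_status(
    calls: CopyCallTable,
    ifn_genes: list[str],
    groups: pd.Series,
) -> pd.Series:
    """Joint stratum of 9p21 group x type-I-interferon-cluster deletion state.

    A sample is "IFN-del" if any listed IFN-cluster gene has a homozygous
    deletion call (-2), else "IFN-intact"; the output is e.g. "LOSS+IFN-del".
    Samples missing from either input are NA.
    """
    if not ifn_genes:
        raise AnalysisError("empty IFN gene list")
    present = [g for g in ifn_genes if g in calls.calls.index]
    if not present:
        raise AnalysisError("none of the IFN genes are in the copy-call table")
    sub = calls.calls.loc[present]
    out = pd.Series(pd.NA, index=groups.index, dtype=object, name="ifn_stratum")
    for sid in groups.index:
        if pd.isna(groups[sid]) or sid not in sub.columns:
            continue
        col = sub[sid].dropna()
        if col.empty:
            continue
        tag = "IFN-del" if (col == -2).any() else "IFN-intact"
        out[sid] = f"{groups[sid]}+{tag}"
    return out
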