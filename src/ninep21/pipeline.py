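"""End-to-end orchestration: genotype -> profile -> screen -> stratify ->
survival -> score, with exclusion accounting and deterministic outputs.

Each stage mirrors one step of the cohort analysis: 9p21 stratification
labels (genomic calls or the hi_hi/lo_lo expression surrogate), immune
abundance scoring plus group-wise differential abundance, curated-list
expression screens, exact response-rate statistics, survival comparison, and
the composite response score.  Results are written as TSVs with a JSON
manifest; the run log reports, at every stage, how many samples entered,
how many were used, and why any were excluded.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genotyping, outcomes, profiling, screen, survival
from .errors import AnalysisError, Ninep21Error
from .io import (
    ClinicalTable,
    CopyCallTable,
    ExpressionMatrix,
    GeneSetCollection,
    write_results,
)


@dataclass
class PipelineConfig:
    """Inputs, stratification basis, endpoint, thresholds, and output location."""

    out_dir: str | Path
    expr_path: str | Path | None = None
    cnv_path: str | Path | None = None
    clinical_path: str | Path | None = None
    marker_gmt: str | Path | None = None
    target_genes: list[str] | None = None
    basis: str = "surrogate"  # "genomic" | "surrogate"
    endpoint: str = "OS"  # "OS" | "PFS" | "DSS"
    contrast: tuple[str, str] | None = None
    fc_threshold: float = 1.2
    q_threshold: float = 0.05
    seed: int = 0
    linear_expression: bool = False

    def __post_init__(self) -> None:
        if self.basis not in ("genomic", "surrogate"):
            raise AnalysisError(f"unknown basis {self.basis!r}")
        if self.endpoint not in ("OS", "PFS", "DSS"):
            raise AnalysisError(f"unknown endpoint {self.endpoint!r}")
        if not (0 < self.q_threshold < 1) or self.fc_threshold < 1:
            raise AnalysisError("thresholds out of range")


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    log: list[dict] = field(default_factory=list)


def _endpoint_cols(endpoint: str) -> tuple[str, str]:
    return {"OS": ("os_time", "os_event"), "PFS": ("pfs_time", "pfs_event"),
            "DSS": ("dss_time", "dss_event")}[endpoint]


def run_pipeline(
    config: PipelineConfig,
    expression: ExpressionMatrix | None = None,
    copy_calls: CopyCallTable | None = None,
    clinical: ClinicalTable | None = None,
    markers: GeneSetCollection | None = None,
) -> PipelineResult:
    """Run every stage and write the result bundle under ``config.out_dir``.

    Tables may be passed in memory (a simulated cohort) or read from the
    configured paths.  Any stage error aborts with the stage name and cause,
    removing partial outputs.
    """
    cfg = config
    out_dir = Path(cfg.out_dir)
    if expression is None and cfg.expr_path is not None:
        expression = ExpressionMatrix.from_tsv(cfg.expr_path, linear=cfg.linear_expression)
    if copy_calls is None and cfg.cnv_path is not None:
        copy_calls = CopyCallTable.from_tsv(cfg.cnv_path)
    if clinical is None and cfg.clinical_path is not None:
        clinical = ClinicalTable.from_tsv(cfg.clinical_path)
    if markers is None:
        if cfg.marker_gmt is not None:
            markers = GeneSetCollection.from_gmt(cfg.marker_gmt)
        else:
            from .simulate import bundled_gene_sets

            markers = bundled_gene_sets("markers")
    if cfg.basis == "genomic" and copy_calls is None:
        raise AnalysisError("basis=genomic requires a copy-call table")
    if expression is None or clinical is None:
        raise AnalysisError("pipeline requires expression and clinical tables")

    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log: list[dict] = []
    meta = {"seed": cfg.seed, "basis": cfg.basis, "endpoint": cfg.endpoint,
            "fc_threshold": cfg.fc_threshold, "q_threshold": cfg.q_threshold}

    def _log(stage: str, n_in: int, n_used: int, reason: str = "") -> None:
        log.append({"stage": stage, "n_in": n_in, "n_used": n_used,
                    "n_excluded": n_in - n_used, "reason": reason})

    def _write(name: str, df: pd.DataFrame) -> None:
        path = write_results(df, out_dir / name, metadata=meta)
        written.append(path)
        written.append(path.with_suffix(path.suffix + ".json"))

    try:
        stage = "genotype"
        n_all = len(expression.sample_ids)
        if cfg.basis == "genomic":
            geno = genotyping.genotype_cohort(copy_calls)
            groups = geno["group"].reindex(expression.sample_ids)
            contrast = cfg.contrast or ("WT", "LOSS")
        else:
            groups = genotyping.surrogate_from_expression(expression)
            contrast = cfg.contrast or ("hi_hi", "lo_lo")
        labels = groups.rename("group").to_frame()
        labels["basis"] = cfg.basis
        _write("genotype_labels.tsv", labels.reset_index(names="sample_id"))
        _log(stage, n_all, int(groups.notna().sum()), "missing calls/expression")

        stage = "profile"
        scores = profiling.marker_abundance_scores(expression, markers)
        in_contrast = int(groups.isin(contrast).sum())
        _log(stage, n_all, in_contrast, f"outside contrast {contrast}")
        diff = profiling.differential_abundance(scores, groups, contrast)
        _write("differential_abundance.tsv", diff)

        stage = "screen"
        target_genes = cfg.target_genes or [
            g for g in expression.gene_ids
            if g not in (genotyping.CDKN2A, genotyping.MTAP)
        ]
        deg = screen.deg_screen(
            expression, groups, target_genes, contrast,
            fc_threshold=cfg.fc_threshold, q_threshold=cfg.q_threshold,
        )
        _write("deg_screen.tsv", deg)
        corr = screen.spearman_target_screen(
            expression, (genotyping.CDKN2A, genotyping.MTAP), target_genes
        )
        _write("spearman_screen.tsv", corr)
        _log(stage, n_all, in_contrast, f"outside contrast {contrast}")

        stage = "stratify"
        responder = clinical.data["response"].isin(["CR", "PR"]).where(
            clinical.data["response"].notna() & (clinical.data["response"] != "NE")
        )
        rates = outcomes.response_rates_compare(responder, groups, contrast)
        _write("response_rates.tsv", rates)
        _log(stage, n_all, int(rates["total"].sum()), "NA outcome or outside contrast")

        stage = "survival"
        tcol, ecol = _endpoint_cols(cfg.endpoint)
        time = clinical.data[tcol]
        event = clinical.data[ecol]
        in_strata = groups[groups.isin(contrast)]
        lr = survival.logrank_test(time, event, in_strata)
        km_rows = []
        for lab in contrast:
            ids = in_strata.index[in_strata == lab]
            curve = survival.km_estimate(time.loc[ids], event.loc[ids])
            t = curve.table.assign(stratum=lab)
            km_rows.append(t)
        km = pd.concat(km_rows, ignore_index=True)
        km["logrank_p"] = lr.p
        _write("survival_km.tsv", km)
        cov = (in_strata == contrast[1]).astype(float).rename("risk_group").to_frame()
        cox = survival.cox_fit(time, event, cov)
        _write("survival_cox.tsv", cox.reset_index())
        n_surv = int(time.loc[in_strata.index].notna().sum())
        _log(stage, n_all, n_surv, "missing survival or outside contrast")

        stage = "score"
        if "tmb" in clinical.data and "pdl1_ic" in clinical.data:
            surrogate = (
                groups if cfg.basis == "surrogate"
                else genotyping.surrogate_from_expression(expression)
            )
            score = outcomes.score_cohort(clinical.data, surrogate)
            score = score.join(responder.rename("responder"))
            _write("response_score.tsv", score.reset_index())
            tiers = score["tier"]
            tier_table = outcomes.build_contingency(
                tiers, responder.map({True: "responder", False: "non-responder"},
                                     na_action="ignore"),
            )
            tier_rows = tier_table.reset_index().rename(columns={"tier": "tier"})
            _write("response_score_tiers.tsv", tier_rows)
            _log(stage, n_all, int(score.shape[0]), "missing TMB/PD-L1/surrogate")
        else:
            _log(stage, n_all, 0, "no TMB/PD-L1 columns")
    except Ninep21Error as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise AnalysisError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in vars(cfg).items() if not k.startswith("_")},
        "outputs": [p.name for p in written if not p.name.endswith(".json")],
        "log": log,
    }
    manifest["config"]["out_dir"] = str(cfg.out_dir)
    manifest["config"]["contrast"] = list(contrast)
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(out_dir=out_dir, manifest=manifest, log=log)
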