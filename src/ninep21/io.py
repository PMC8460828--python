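"""Data model, readers/writers, and validation for cohort tables.

Four tabular kinds flow through the pipeline:

* :class:`ExpressionMatrix` — log2-scale normalized expression, genes x samples.
* :class:`CopyCallTable` — GISTIC-style thresholded copy-number calls in {-2..+2}.
* :class:`ClinicalTable` — RECIST response, survival endpoints, TMB, PD-L1 categories.
* :class:`GeneSetCollection` — named gene sets (GMT), tagged by category.

All files are UTF-8 TSV with '.' decimal; gene sets use the standard GMT dialect.
Validation is total: malformed inputs raise typed errors and are never coerced.
Missing values propagate as NA; each downstream operation states its own NA policy.
Sample joins are exact-string.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

RESPONSE_VOCAB = frozenset({"CR", "PR", "SD", "PD", "NE"})
PDL1_IC_VOCAB = frozenset({"IC0", "IC1", "IC2+"})

#: clinical columns with an enforced vocabulary or type; anything else is
#: preserved as an opaque column.
_TIME_COLS = ("os_time", "pfs_time", "dss_time")
_EVENT_COLS = ("os_event", "pfs_event", "dss_event")


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in ids:
        if x in seen:
            dups.add(x)
        seen.add(x)
    if dups:
        raise ValidationError(f"duplicate {what} id(s): {sorted(dups)}")


@dataclass
class ExpressionMatrix:
    """Log2-scale normalized expression values, genes as rows, samples as columns."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        if df.shape[0] < 1 or df.shape[1] < 2:
            raise ValidationError(
                f"expression matrix needs >=1 gene and >=2 samples, got {df.shape}"
            )
        arr = df.to_numpy(dtype=float)
        bad = np.isinf(arr)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite expression value at gene {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            )
        self.values = df.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path: str | Path, linear: bool = False) -> "ExpressionMatrix":
        """Read a genes-x-samples TSV (header = sample ids, first column = gene ids).

        With ``linear=True`` the values are log2(x+1)-transformed on load.
        """
        path = Path(path)
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ParseError(f"{path}: {exc}") from exc
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ParseError(f"{path}: duplicate gene id(s): {dups}")
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise ParseError(
                    f"{path}: non-numeric cell at gene {row!r}, sample {col!r}"
                )
            df[col] = coerced
        if linear:
            if (df < 0).any().any():
                raise ValidationError("linear input has negative values; cannot log2(x+1)")
            df = np.log2(df + 1.0)
        df.index = df.index.astype(str).rename(None)
        df.columns = df.columns.astype(str).rename(None)
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        df = self.values.copy()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


@dataclass
class CopyCallTable:
    """Integer thresholded copy calls (-2..+2) per sample x gene (genes as rows)."""

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.calls
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        vals = pd.unique(df.stack().dropna())
        bad = [v for v in vals if v not in (-2, -1, 0, 1, 2)]
        if bad:
            raise ValidationError(f"copy call(s) outside -2..+2: {sorted(bad)}")
        self.calls = df.astype("Int64")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)

    def get(self, sample_id: str, gene_id: str):
        """Return the call for one sample x gene, or NA if absent."""
        if gene_id not in self.calls.index or sample_id not in self.calls.columns:
            return pd.NA
        return self.calls.at[gene_id, sample_id]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CopyCallTable":
        """Read either the long (sample, gene, call) or wide (genes x samples) dialect.

        The dialect is auto-detected from the header: a header whose first three
        columns are sample/gene/call (any case) is long form.
        """
        path = Path(path)
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
        lowered = [h.strip().lower() for h in header[:3]]
        if lowered[:3] in (["sample", "gene", "call"], ["sample_id", "gene_id", "call"]):
            long = pd.read_csv(path, sep="\t", dtype={header[0]: str, header[1]: str})
            long.columns = ["sample", "gene", "call"] + list(long.columns[3:])
            if long.duplicated(["sample", "gene"]).any():
                dup = long[long.duplicated(["sample", "gene"])].iloc[0]
                raise ParseError(
                    f"{path}: duplicate call for sample {dup['sample']!r}, gene {dup['gene']!r}"
                )
            try:
                wide = long.pivot(index="gene", columns="sample", values="call")
            except Exception as exc:
                raise ParseError(f"{path}: cannot pivot long-form calls: {exc}") from exc
            wide.index.name = None
            wide.columns.name = None
            return cls(wide)
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ParseError(f"{path}: duplicate gene id(s): {dups}")
        df.index = df.index.astype(str).rename(None)
        df.columns = df.columns.astype(str).rename(None)
        return cls(df)

    def to_tsv(self, path: str | Path, dialect: str = "wide") -> None:
        if dialect == "wide":
            df = self.calls.copy()
            df.index.name = "gene_id"
            df.to_csv(path, sep="\t")
        elif dialect == "long":
            long = (
                self.calls.stack()
                .rename("call")
                .rename_axis(["gene", "sample"])
                .reset_index()[["sample", "gene", "call"]]
            )
            long.to_csv(path, sep="\t", index=False)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations: response, survival, TMB, PD-L1, therapy.

    TMB is treated as unitless (cohorts mix mutation counts and mutations/Mb);
    it is only ever used through a within-cohort median split.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "sample")
        if "response" in df:
            bad = set(df["response"].dropna()) - RESPONSE_VOCAB
            if bad:
                raise ValidationError(
                    f"response value(s) outside {sorted(RESPONSE_VOCAB)}: {sorted(bad)}"
                )
        if "pdl1_ic" in df:
            bad = set(df["pdl1_ic"].dropna()) - PDL1_IC_VOCAB
            if bad:
                raise ValidationError(
                    f"pdl1_ic value(s) outside {sorted(PDL1_IC_VOCAB)}: {sorted(bad)}"
                )
        for col in _TIME_COLS:
            if col in df:
                t = pd.to_numeric(df[col], errors="coerce")
                if ((t < 0).fillna(False)).any():
                    sid = df.index[(t < 0).fillna(False)][0]
                    raise ValidationError(f"negative {col} for sample {sid!r}")
                self.data[col] = t
        for tcol, ecol in zip(_TIME_COLS, _EVENT_COLS):
            if ecol in df:
                has_event = df[ecol].notna()
                if tcol not in df:
                    raise ValidationError(f"{ecol} present without {tcol}")
                orphan = has_event & df[tcol].isna()
                if orphan.any():
                    sid = df.index[orphan][0]
                    raise ValidationError(f"{ecol} set but {tcol} missing for {sid!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClinicalTable":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ParseError(f"{path}: duplicate sample id(s): {dups}")
        for col in _EVENT_COLS + ("dcb",):
            if col in df:
                df[col] = df[col].map(
                    {True: True, False: False, 1: True, 0: False, "1": True, "0": False,
                     "True": True, "False": False, "true": True, "false": False},
                    na_action="ignore",
                )
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        df = self.data.copy()
        df.index.name = "sample_id"
        # booleans as 0/1 so the round trip is unambiguous
        for col in _EVENT_COLS + ("dcb",):
            if col in df:
                df[col] = df[col].map({True: 1, False: 0}, na_action="ignore")
        df.to_csv(path, sep="\t")


@dataclass
class GeneSetCollection:
    """Named gene sets; ``category`` tags a set as markers / pathway / target list."""

    sets: dict[str, list[str]]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.sets.keys(), "gene-set")
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                warnings.warn(f"gene set {name!r}: duplicate members deduplicated")
                seen: set[str] = set()
                self.sets[name] = [g for g in members if not (g in seen or seen.add(g))]

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        """Read a standard GMT file (name TAB description TAB member...)."""
        path = Path(path)
        sets: dict[str, list[str]] = {}
        categories: dict[str, str] = {}
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ParseError(
                        f"{path}:{lineno}: GMT line needs name, description, >=1 member"
                    )
                name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
                if not members:
                    raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
                if name in sets:
                    raise ParseError(f"{path}:{lineno}: duplicate gene set {name!r}")
                sets[name] = members
                if desc:
                    categories[name] = desc
        return cls(sets, categories)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name, members in self.sets.items():
                desc = self.categories.get(name, "")
                fh.write("\t".join([name, desc, *members]) + "\n")


def read_expression(path: str | Path, linear: bool = False) -> ExpressionMatrix:
    return ExpressionMatrix.from_tsv(path, linear=linear)


def read_copy_calls(path: str | Path) -> CopyCallTable:
    return CopyCallTable.from_tsv(path)


def read_clinical(path: str | Path) -> ClinicalTable:
    return ClinicalTable.from_tsv(path)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    return GeneSetCollection.from_gmt(path)


def write_results(
    results: pd.DataFrame,
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> Path:
    """Write a result table as TSV plus a JSON sidecar with run metadata.

    The sidecar (``<path>.json``) records the passed metadata (seed, config, ...),
    a SHA-256 of the TSV payload, and package/library versions.
    """
    path = Path(path)
    df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(results)
    df.to_csv(path, sep="\t", index=False)
    payload = path.read_bytes()
    from . import __version__

    sidecar = {
        "metadata": dict(metadata or {}),
        "sha256": hashlib.sha256(payload).hexdigest(),
        "n_rows": int(df.shape[0]),
        "versions": {
            "ninep21": __version__,
            "pandas": pd.__version__,
            "numpy": np.__version__,
        },
    }
    with open(path.with_suffix(path.suffix + ".json"), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    return path
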