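"""Tabular I/O and the core in-memory containers.

All stages exchange three kinds of tables:

* :class:`ExpressionMatrix` -- genes x samples log10 ratios (sample vs a
  pooled reference), with a per-sample metadata sheet (subtype, cohort,
  tissue, patient).
* :class:`CtTable` -- long-format qPCR cycle-threshold observations, one row
  per (assay, patient, tissue, replicate).  The instrument token
  ``Undetermined`` is mapped to missing, never to a sentinel Ct.
* :class:`TargetTable` -- miRNA -> gene predicted-target edges with the set
  of prediction programs supporting each edge, optionally annotated with the
  subtype in which the miRNA is over-expressed.

Dialect: TSV with a header row, UTF-8.  Gene/miRNA identifiers are opaque,
case-sensitive strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError

__all__ = [
    "ExpressionMatrix",
    "CtTable",
    "TargetTable",
    "VALID_PROGRAMS",
    "UNDETERMINED_TOKEN",
    "read_expression",
    "write_expression",
    "read_ct",
    "write_ct",
    "read_targets",
    "write_targets",
    "load_published_targets",
]

VALID_PROGRAMS = frozenset({"miRanda", "TargetScan", "miRWalk"})
UNDETERMINED_TOKEN = "Undetermined"

METADATA_COLUMNS = ["subtype", "cohort", "tissue", "patient_id"]
CT_COLUMNS = ["assay", "patient_id", "tissue", "replicate", "ct"]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log10 ratios plus sample metadata.

    ``values`` is indexed by gene with one column per sample id;
    ``metadata`` is indexed by sample id with columns
    subtype/cohort/tissue/patient_id and must cover every sample.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ParseError(f"duplicate gene identifiers: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ParseError(f"duplicate sample identifiers: {dups[:5]}")
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        if missing:
            raise ParseError(f"samples without metadata: {missing[:5]}")
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise ParseError(f"sample sheet lacks required column {col!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subtypes(self) -> pd.Series:
        """Subtype label per sample, aligned to the matrix column order."""
        return self.metadata.loc[self.values.columns, "subtype"]


@dataclass
class CtTable:
    """Long-format qPCR observations: (assay, patient, tissue, replicate, ct).

    ``ct`` is a float; missing (undetermined) observations are NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = [c for c in CT_COLUMNS if c not in self.data.columns]
        if missing_cols:
            raise ParseError(f"Ct table lacks columns {missing_cols}")
        key = ["assay", "patient_id", "tissue", "replicate"]
        if self.data.duplicated(subset=key).any():
            first = self.data[self.data.duplicated(subset=key)].iloc[0]
            raise ParseError(
                "duplicate Ct record for "
                f"({first['assay']}, {first['patient_id']}, "
                f"{first['tissue']}, {first['replicate']})"
            )
        ct = self.data["ct"]
        bad = ct.notna() & ((ct <= 0) | (ct >= 50))
        if bad.any():
            row = self.data[bad].iloc[0]
            raise ParseError(
                f"Ct value {row['ct']} out of range (0, 50) for assay "
                f"{row['assay']!r}, patient {row['patient_id']!r}"
            )

    @property
    def assays(self) -> list[str]:
        return sorted(self.data["assay"].unique())


@dataclass
class TargetTable:
    """Predicted miRNA->gene edges with supporting prediction programs.

    One row per (mirna, gene); ``programs`` holds a frozenset drawn from
    miRanda / TargetScan / miRWalk.  ``direction`` (optional, may be NaN)
    records the subtype in which the miRNA is over-expressed.
    """

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["mirna", "gene", "programs", "direction"]))

    def __post_init__(self) -> None:
        for col in ("mirna", "gene", "programs"):
            if col not in self.data.columns:
                raise ParseError(f"target table lacks column {col!r}")
        if "direction" not in self.data.columns:
            self.data = self.data.assign(direction=pd.NA)
        if self.data.duplicated(subset=["mirna", "gene"]).any():
            raise ParseError("duplicate (mirna, gene) rows after merging")
        for progs in self.data["programs"]:
            unknown = set(progs) - VALID_PROGRAMS
            if unknown:
                raise ParseError(
                    f"unknown prediction program(s) {sorted(unknown)}; "
                    f"valid names: {sorted(VALID_PROGRAMS)}"
                )
            if not progs:
                raise ParseError("empty program set for a target edge")

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.data["mirna"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    @property
    def n_edges(self) -> int:
        return len(self.data)

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.data["mirna"], self.data["gene"]))

    def mirna_directions(self) -> dict[str, str]:
        """Map miRNA -> subtype of over-expression, for annotated tables."""
        out: dict[str, str] = {}
        for _, row in self.data.iterrows():
            if pd.isna(row["direction"]):
                continue
            prev = out.setdefault(row["mirna"], row["direction"])
            if prev != row["direction"]:
                raise ParseError(
                    f"conflicting direction annotations for {row['mirna']!r}"
                )
        return out


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(path, sample_sheet_path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus its sample sheet.

    The first column of the matrix file must be named ``gene``; every other
    header entry is a sample id which must appear in the sample sheet.
    """
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    if raw.columns[0] != "gene":
        raise ParseError(
            f"first column of {path} must be 'gene', got {raw.columns[0]!r}"
        )
    values = raw.set_index("gene")
    for col in values.columns:
        coerced = pd.to_numeric(values[col], errors="coerce")
        bad = coerced.isna() & values[col].notna()
        if bad.any():
            gene = values.index[bad][0]
            raise ParseError(
                f"non-numeric expression cell at gene {gene!r}, sample {col!r}"
            )
        values[col] = coerced
    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
    if "sample_id" not in sheet.columns:
        raise ParseError("sample sheet lacks column 'sample_id'")
    if sheet["sample_id"].duplicated().any():
        raise ParseError("duplicate sample_id in sample sheet")
    metadata = sheet.set_index("sample_id")
    return ExpressionMatrix(values=values, metadata=metadata)


def write_expression(x: ExpressionMatrix, path, sample_sheet_path) -> None:
    out = x.values.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep="\t", index=False)
    sheet = x.metadata.copy()
    sheet.insert(0, "sample_id", sheet.index)
    sheet.to_csv(sample_sheet_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Ct tables


def read_ct(path) -> CtTable:
    """Read a long-format Ct TSV; ``Undetermined`` becomes missing (NaN)."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in CT_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ParseError(f"Ct file {path} lacks columns {missing_cols}")
    ct = raw["ct"].where(raw["ct"] != UNDETERMINED_TOKEN)
    try:
        ct = ct.astype(float)
    except ValueError as exc:
        raise ParseError(f"unparseable Ct value in {path}: {exc}") from exc
    data = raw.assign(ct=ct, replicate=raw["replicate"].astype(int))
    return CtTable(data=data[CT_COLUMNS])


def write_ct(table: CtTable, path) -> None:
    out = table.data.copy()
    out["ct"] = out["ct"].map(
        lambda v: UNDETERMINED_TOKEN if pd.isna(v) else format(v, "g")
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# target tables


def _split_programs(cell: str) -> frozenset[str]:
    parts = [p.strip() for p in str(cell).replace(";", ",").split(",")]
    return frozenset(p for p in parts if p)


def read_targets(path) -> TargetTable:
    """Read a miRNA->gene prediction TSV, merging duplicate pairs.

    Columns: mirna, gene, programs (semicolon- or comma-separated),
    direction (optional).  Program annotations of duplicated (mirna, gene)
    rows are unioned.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("mirna", "gene", "programs"):
        if col not in raw.columns:
            raise ParseError(f"target file {path} lacks column {col!r}")
    if "direction" not in raw.columns:
        raw["direction"] = pd.NA
    rows: dict[tuple[str, str], dict] = {}
    for _, r in raw.iterrows():
        key = (r["mirna"], r["gene"])
        progs = _split_programs(r["programs"])
        if key in rows:
            rows[key]["programs"] = rows[key]["programs"] | progs
            if pd.notna(r["direction"]):
                prev = rows[key]["direction"]
                if pd.notna(prev) and prev != r["direction"]:
                    raise ParseError(f"conflicting directions for pair {key}")
                rows[key]["direction"] = r["direction"]
        else:
            rows[key] = {
                "mirna": r["mirna"],
                "gene": r["gene"],
                "programs": progs,
                "direction": r["direction"],
            }
    data = pd.DataFrame(list(rows.values()),
                        columns=["mirna", "gene", "programs", "direction"])
    return TargetTable(data=data)


def write_targets(table: TargetTable, path) -> None:
    out = table.data.copy()
    out["programs"] = out["programs"].map(lambda s: ";".join(sorted(s)))
    out.to_csv(path, sep="\t", index=False)


def load_published_targets() -> TargetTable:
    """Load the packaged prediction table for the nine NSCLC
    subtype-discriminating miRNAs (miRanda/TargetScan/miRWalk predictions,
    annotated with each miRNA's over-expressing subtype)."""
    ref = resources.files("nsclcmir.data").joinpath("mirna_targets_nsclc.tsv")
    with resources.as_file(ref) as p:
        return read_targets(p)
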