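"""Readers, writers and canonical in-memory tables for the pipeline.

Expression matrices are tab-separated text with genes in rows (first column
gene identifiers, header row sample identifiers).  Gene sets use the GMT
format; animal growth records, sample metadata and qPCR Ct values are CSV
with fixed column names.  Result tables are written as TSV or JSON with a
deterministic column order and fixed floating-point precision.

Gene identifiers are matched case-sensitively as plain strings; no alias
resolution is attempted.  Missing values are rejected, never imputed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionKind",
    "ExpressionMatrix",
    "GeneSet",
    "GeneSignature",
    "SampleMetadata",
    "GrowthTable",
    "CtTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_growth_table",
    "read_sample_metadata",
    "read_ct_table",
    "write_results",
]


class ExpressionKind(str, Enum):
    raw = "raw"
    normalized = "normalized"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix.

    ``kind`` records whether values are raw read counts (non-negative
    integers) or normalized reads (non-negative reals).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    kind: ExpressionKind = ExpressionKind.raw

    def __post_init__(self) -> None:
        self.kind = ExpressionKind(self.kind)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if self.kind is ExpressionKind.raw and np.any(self.values != np.round(self.values)):
            bad = np.argwhere(self.values != np.round(self.values))[0]
            raise ValueError(
                f"raw counts must be integral; fractional value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def column(self, sample_id: str) -> pd.Series:
        j = self.sample_ids.index(sample_id)
        return pd.Series(self.values[:, j], index=self.gene_ids, name=sample_id)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in genes if g in set(self.gene_ids)]
        idx = [self.gene_ids.index(g) for g in keep]
        return ExpressionMatrix(keep, list(self.sample_ids), self.values[idx, :], self.kind)


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        _check_unique(self.genes, "gene (in set %r)" % self.name)


@dataclass
class GeneSignature:
    """Up-regulated / down-regulated gene lists used by the activation caller."""

    name: str
    up_genes: list[str]
    down_genes: list[str]

    def __post_init__(self) -> None:
        if not self.up_genes or not self.down_genes:
            raise ValueError("signature must have non-empty up and down gene lists")
        _check_unique(self.up_genes, "up gene")
        _check_unique(self.down_genes, "down gene")
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValueError(f"up and down gene lists overlap: {sorted(overlap)}")


@dataclass
class SampleMetadata:
    """Per-sample annotations: group label, treatment arm, optional dose."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    GROUPS = ("activated", "wild_type", "unknown")
    TREATMENTS = ("vehicle", "drug")

    def __post_init__(self) -> None:
        t = self.table
        if len(t) == 0:
            return
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id in metadata: {dup!r}")
        bad_g = set(t["group"]) - set(self.GROUPS)
        if bad_g:
            raise ValueError(f"unknown group labels: {sorted(bad_g)}")
        if "treatment" in t.columns:
            bad_t = set(t["treatment"].dropna()) - set(self.TREATMENTS)
            if bad_t:
                raise ValueError(f"unknown treatment labels: {sorted(bad_t)}")

    def group_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if len(row) == 0:
            raise KeyError(sample_id)
        return str(row["group"].iloc[0])


@dataclass
class GrowthTable:
    """Longitudinal caliper records: one row per (animal, day).

    Width and length are in mm; volume (mm^3) is optional and computed
    downstream from the caliper formula when absent.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"animal_id", "group", "day", "width", "length"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"growth table missing columns: {sorted(missing)}")
        if t.duplicated(subset=["animal_id", "day"]).any():
            dup = t.loc[t.duplicated(subset=["animal_id", "day"]), ["animal_id", "day"]].iloc[0]
            raise ValueError(
                f"duplicate (animal, day) record: {dup['animal_id']!r} day {dup['day']}"
            )
        groups_per_animal = t.groupby("animal_id")["group"].nunique()
        multi = groups_per_animal[groups_per_animal > 1]
        if len(multi):
            raise ValueError(f"animal {multi.index[0]!r} appears in more than one group")
        if (t["day"] < 0).any() or (t["day"] != t["day"].astype(int)).any():
            raise ValueError("day must be a non-negative integer")
        for col in ("width", "length"):
            if (t[col] <= 0).any():
                bad = t.loc[t[col] <= 0].iloc[0]
                raise ValueError(
                    f"non-positive {col} for animal {bad['animal_id']!r} day {bad['day']}"
                )
        days_per_animal = t.groupby("animal_id")["day"].nunique()
        few = days_per_animal[days_per_animal < 2]
        if len(few):
            raise ValueError(
                f"animal {few.index[0]!r} has fewer than 2 distinct measurement days"
            )

    @property
    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique())


@dataclass
class CtTable:
    """qPCR Ct values: (sample, condition, gene, ct, is_reference) rows."""

    table: pd.DataFrame

    CONDITIONS = ("control", "treated")

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample_id", "condition", "gene", "ct", "is_reference"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        bad_c = set(t["condition"]) - set(self.CONDITIONS)
        if bad_c:
            raise ValueError(f"unknown conditions: {sorted(bad_c)}")
        if not np.all(np.isfinite(t["ct"].to_numpy(dtype=float))):
            raise ValueError("non-finite Ct value")
        n_ref = t[t["is_reference"]].groupby(["sample_id", "condition"]).size()
        all_pairs = t.groupby(["sample_id", "condition"]).size()
        for pair in all_pairs.index:
            k = n_ref.get(pair, 0)
            if k != 1:
                raise ValueError(
                    f"sample {pair[0]!r} condition {pair[1]!r} has {k} reference-gene "
                    f"Ct rows (exactly one required)"
                )


# ---------------------------------------------------------------------------
# Readers / writers


def read_expression_matrix(
    path: str | Path, kind: str | ExpressionKind = ExpressionKind.raw, transpose: bool = False
) -> ExpressionMatrix:
    """Read a tab-separated genes x samples matrix.

    First column holds gene identifiers, the header row sample identifiers.
    ``transpose=True`` accepts samples-in-rows files.  Duplicate gene
    identifiers and non-numeric or missing cells are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transpose:
        df = df.T
    gene_ids = [str(g) for g in df.index]
    dups = pd.Index(gene_ids).duplicated()
    if dups.any():
        raise ValueError(f"duplicate gene id in {path}: {gene_ids[int(np.argmax(dups))]!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell in {path} at gene {gene_ids[i]!r}, "
                    f"sample {col!r}: {raw!r}"
                ) from None
    return ExpressionMatrix(gene_ids, [str(s) for s in df.columns], values, kind)


def write_expression_matrix(path: str | Path, matrix: ExpressionMatrix) -> None:
    df = matrix.to_frame()
    if matrix.kind is ExpressionKind.raw:
        df = df.astype(int)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: ``name TAB description TAB gene TAB gene ...``.

    Duplicate genes within a line are deduplicated with a logged warning;
    lines with fewer than three fields are hard errors.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning(
                    "%s:%d: gene set %r contains %d duplicate gene entries (deduplicated)",
                    path, lineno, name, len(genes) - len(deduped),
                )
            sets.append(GeneSet(name=name, description=desc, genes=deduped))
    return sets


def write_gmt(path: str | Path, sets: Iterable[GeneSet]) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def read_growth_table(path: str | Path) -> GrowthTable:
    """Read a caliper CSV with columns animal, group, day, width, length[, volume]."""
    df = pd.read_csv(path)
    rename = {"animal": "animal_id"}
    df = df.rename(columns=rename)
    df["animal_id"] = df["animal_id"].astype(str)
    df["group"] = df["group"].astype(str)
    return GrowthTable(df)


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path)
    df["sample_id"] = df["sample_id"].astype(str)
    return SampleMetadata(df)


def read_ct_table(path: str | Path) -> CtTable:
    df = pd.read_csv(path)
    df["is_reference"] = df["is_reference"].astype(bool)
    return CtTable(df)


_FLOAT_FMT = "%.6g"


def write_results(path: str | Path, table: pd.DataFrame, format: str = "tsv") -> None:
    """Write a result table as TSV or JSON with deterministic column order.

    Floating values are serialized with 6 significant digits so that
    write/read round trips are stable.
    """
    path = Path(path)
    if format == "tsv":
        table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    elif format == "json":
        records = []
        for _, row in table.iterrows():
            rec = {}
            for col, val in row.items():
                if isinstance(val, (float, np.floating)):
                    if math.isfinite(val):
                        rec[col] = float(f"{val:.6g}")
                    else:
                        rec[col] = None
                elif isinstance(val, (np.integer,)):
                    rec[col] = int(val)
                elif isinstance(val, (np.bool_,)):
                    rec[col] = bool(val)
                else:
                    rec[col] = val
            records.append(rec)
        path.write_text(json.dumps(records, indent=1) + "\n")
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'json')")
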