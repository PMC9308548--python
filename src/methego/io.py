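"""Readers and writers for the pipeline's external formats.

All tabular formats are TSV with a header row, ``.`` for missing values and
six decimals for β-values.  Gene sets use the standard GMT layout.  Edge
lists follow the STRING convention (gene_a, gene_b, confidence in 0–1000).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "ProbeAnnotation",
    "ValidationError",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_sample_groups",
    "write_sample_groups",
    "read_network_edges",
    "write_network_edges",
    "read_gene_sets",
    "write_gene_sets",
]

logger = logging.getLogger("methego")

BETA_DECIMALS = 6
MISSING = "."

ANNOT_COLUMNS = [
    "probe_id",
    "chrom",
    "pos",
    "snp_distance",
    "maf",
    "cross_hyb",
    "design_type",
    "gene",
]

SEX_CHROMS = frozenset({"X", "Y"})
_CANONICAL_CHROMS = frozenset({str(i) for i in range(1, 23)} | SEX_CHROMS | {"MT"})


class ValidationError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class BetaMatrix:
    """CpG-probe × sample matrix of methylation fractions.

    ``data`` is indexed by probe ID with sample IDs as columns; values lie
    in [0, 1] (NaN marks missing).  ``groups`` optionally maps each sample
    to its group label (e.g. tumor / normal).
    """

    data: pd.DataFrame
    groups: pd.Series | None = None

    @property
    def probes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_groups(self, groups: pd.Series) -> "BetaMatrix":
        missing = [s for s in self.samples if s not in groups.index]
        if missing:
            raise ValidationError(f"samples without group label: {missing[:5]}")
        return BetaMatrix(self.data, groups.loc[self.samples])


@dataclass
class ProbeAnnotation:
    """Per-probe metadata driving QC filtering and CpG→gene mapping."""

    table: pd.DataFrame  # indexed by probe_id

    @property
    def probes(self) -> pd.Index:
        return self.table.index

    def gene_of(self) -> pd.Series:
        return self.table["gene"]


def _normalize_chrom(value: str) -> str:
    token = str(value).strip()
    if token.lower().startswith("chr"):
        token = token[3:]
    token = token.upper()
    if token == "M":
        token = "MT"
    if token not in _CANONICAL_CHROMS:
        raise ValidationError(f"unrecognized chromosome token {value!r}")
    return token


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read a probe × sample β-value TSV.

    First column holds probe IDs, the header row sample IDs; the body is
    numeric in [0, 1] with ``.`` marking missing values.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING])
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate probe ID {dup!r} in {path}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric β value in {path}: {exc}") from exc
    bad = (df < 0) | (df > 1)
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        row = bad[col].idxmax()
        raise ValidationError(
            f"β value {df.loc[row, col]!r} outside [0, 1] at probe {row!r}, "
            f"sample {col!r}"
        )
    logger.info("read_beta_matrix: %d probes x %d samples from %s", *df.shape, path)
    return BetaMatrix(df)


def write_beta_matrix(beta: BetaMatrix, path: str | Path) -> None:
    out = beta.data.round(BETA_DECIMALS)
    out.to_csv(path, sep="\t", na_rep=MISSING, float_format=f"%.{BETA_DECIMALS}f",
               index_label="probe_id")


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """Read the probe-annotation TSV (QC fields + gene symbol per probe)."""
    df = pd.read_csv(path, sep="\t", na_values=[MISSING], dtype={"chrom": str})
    missing_cols = [c for c in ANNOT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"annotation {path} lacks columns {missing_cols}")
    if df["probe_id"].duplicated().any():
        raise ValidationError(f"duplicate probe_id in annotation {path}")
    df = df.set_index("probe_id")
    df["chrom"] = df["chrom"].map(_normalize_chrom)
    bad_maf = df["maf"].dropna()
    if ((bad_maf < 0) | (bad_maf > 0.5)).any():
        val = bad_maf[(bad_maf < 0) | (bad_maf > 0.5)].iloc[0]
        raise ValidationError(f"MAF {val!r} outside [0, 0.5] in {path}")
    bad_design = ~df["design_type"].isin(["I", "II"])
    if bad_design.any():
        raise ValidationError(
            f"design_type must be I or II; got {df['design_type'][bad_design].iloc[0]!r}"
        )
    return ProbeAnnotation(df)


def write_probe_annotation(annot: ProbeAnnotation, path: str | Path) -> None:
    annot.table.to_csv(path, sep="\t", na_rep=MISSING, index_label="probe_id")


def read_sample_groups(path: str | Path) -> pd.Series:
    """Read the sample → group TSV (columns: sample, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "group"):
        if col not in df.columns:
            raise ValidationError(f"groups file {path} lacks column {col!r}")
    if df["sample"].duplicated().any():
        raise ValidationError(f"duplicate sample ID in {path}")
    return df.set_index("sample")["group"]


def write_sample_groups(groups: pd.Series, path: str | Path) -> None:
    groups.rename("group").to_csv(path, sep="\t", index_label="sample")


def read_network_edges(path: str | Path) -> pd.DataFrame:
    """Read a STRING-style edge TSV (gene_a, gene_b, confidence 0–1000).

    The result is undirected and deduplicated — (a, b) and (b, a) collapse
    to one row — and self-loops are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    for col in ("gene_a", "gene_b", "confidence"):
        if col not in df.columns:
            raise ValidationError(f"edge list {path} lacks column {col!r}")
    conf = pd.to_numeric(df["confidence"], errors="coerce")
    if conf.isna().any():
        bad = df["confidence"][conf.isna()].iloc[0]
        raise ValidationError(f"non-numeric confidence {bad!r} in {path}")
    df["confidence"] = conf
    loops = df["gene_a"] == df["gene_b"]
    if loops.any():
        logger.warning("read_network_edges: dropped %d self-loop(s)", int(loops.sum()))
        df = df[~loops]
    lo = df[["gene_a", "gene_b"]].min(axis=1)
    hi = df[["gene_a", "gene_b"]].max(axis=1)
    df = df.assign(gene_a=lo, gene_b=hi)
    df = df.drop_duplicates(subset=["gene_a", "gene_b"], keep="first")
    return df.reset_index(drop=True)[["gene_a", "gene_b", "confidence"]]


def write_network_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered mapping of set name → members.

    Duplicate members within a line are stored once (first occurrence);
    duplicate set names and empty sets are rejected.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"GMT line {lineno} in {path} has {len(fields)} field(s); "
                    "expected name, description and at least one member"
                )
            name = fields[0]
            if name in sets:
                raise ValidationError(f"duplicate gene-set name {name!r} at line {lineno}")
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            if not members:
                raise ValidationError(f"empty gene set {name!r} at line {lineno}")
            sets[name] = members
    return sets


def write_gene_sets(sets: dict[str, list[str]], path: str | Path,
                    descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")
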