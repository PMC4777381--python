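"""Readers and writers for the external formats the pipeline touches.

All downstream stages consume only the in-memory containers defined here:
:class:`FeatureMatrix` (expression or methylation beta values, features x
samples), :class:`Phenotype` (sample ages in years), :class:`GeneSetCollection`
(GMT-style annotation sets) and :class:`IntervalTable` (BED-style genomic
intervals, 0-based half-open).

Conventions
-----------
* Matrices are TSV with a header row of sample ids and feature ids in the
  first column.  Non-numeric cells become missing values; features missing in
  more than ``max_missing_frac`` of samples are dropped (logged).
* All genomic coordinates are 0-based half-open (BED native).  Any 1-based
  source must be converted at this boundary.
* Floats are written with 6 significant digits for reproducible files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"
NA_TOKENS = ("", "NA", "NaN", "nan", "null")

MATRIX_KINDS = ("expression", "methylation")


@dataclass
class FeatureMatrix:
    """A features x samples numeric matrix with identifier lists.

    ``kind`` is either ``"expression"`` (unbounded values) or
    ``"methylation"`` (beta values; every finite entry must lie in [0, 1]).
    """

    data: pd.DataFrame
    kind: str = "expression"

    def __post_init__(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise ValidationError(f"unknown matrix kind {self.kind!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        vals = self.data.to_numpy(dtype=float)
        if self.kind == "methylation":
            bad = np.nonzero((vals < 0) | (vals > 1))
            if bad[0].size:
                i, j = bad[0][0], bad[1][0]
                raise ValidationError(
                    "methylation beta value outside [0, 1] at "
                    f"feature {idx[i]!r}, sample {cols[j]!r}: {vals[i, j]!r}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class Phenotype:
    """Sample ages in years, keyed by sample id."""

    sample_ids: list[str]
    age: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.age = np.asarray(self.age, dtype=float)
        if len(self.sample_ids) != self.age.size:
            raise ValidationError("sample_ids and age have different lengths")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in phenotype")
        if not np.all(np.isfinite(self.age)) or np.any(self.age < 0):
            raise ValidationError("ages must be finite and non-negative")

    def age_of(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = dict(zip(self.sample_ids, self.age))
        return np.array([lookup[s] for s in sample_ids], dtype=float)


@dataclass
class GeneSet:
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set id -> (description, members)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)
    universe_hint: int | None = None

    def __post_init__(self) -> None:
        for sid, gs in self.sets.items():
            if not gs.members:
                raise ValidationError(f"gene set {sid!r} has no members")
            # dedup preserving first occurrence
            self.sets[sid] = GeneSet(gs.description, tuple(dict.fromkeys(gs.members)))

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def __iter__(self):
        return iter(self.sets)

    def members(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id].members

    def items(self):
        return self.sets.items()

    def all_members(self) -> set[str]:
        out: set[str] = set()
        for gs in self.sets.values():
            out.update(gs.members)
        return out


@dataclass
class IntervalTable:
    """BED-style records, 0-based half-open.  Columns: chrom, start, end,
    name, strand ('+'/'-'/'.')."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        required = ["chrom", "start", "end"]
        for col in required:
            if col not in df.columns:
                raise ValidationError(f"interval table missing column {col!r}")
        if "name" not in df.columns:
            df = df.assign(name=[f"iv{i}" for i in range(len(df))])
        if "strand" not in df.columns:
            df = df.assign(strand=".")
        df = df[["chrom", "start", "end", "name", "strand"]].copy()
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["chrom"].astype(str) == "").any():
            raise ValidationError("empty chrom field")
        bad = df["start"] >= df["end"]
        if bad.any():
            row = df[bad].iloc[0]
            raise ValidationError(
                f"interval with start >= end: {row['chrom']}:{row['start']}-{row['end']}"
            )
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def by_name(self) -> dict[str, tuple[str, int, int, str]]:
        return {
            r.name: (r.chrom, int(r.start), int(r.end), r.strand)
            for r in self.records.itertuples(index=False)
        }

    def midpoints(self) -> np.ndarray:
        r = self.records
        return ((r["start"].to_numpy() + r["end"].to_numpy()) // 2).astype(int)


# ---------------------------------------------------------------------------
# matrix TSV


def read_matrix(
    path: str | Path,
    kind: str = "expression",
    max_missing_frac: float = 0.2,
) -> FeatureMatrix:
    """Read a features x samples TSV (header = sample ids, first column =
    feature ids) into a :class:`FeatureMatrix`.

    Non-numeric cells become NaN.  Features with more than
    ``max_missing_frac`` missing samples are dropped with a logged count.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    fields = header.split("\t")
    if len(fields) < 2:
        raise FormatError(f"{path}: malformed header (need >= 2 tab-separated fields)")
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, na_values=list(NA_TOKENS), keep_default_na=False
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse TSV matrix: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature ids: {dups[:5]}")
    df = df.apply(pd.to_numeric, errors="coerce")
    if kind == "methylation":
        vals = df.to_numpy(dtype=float)
        bad = np.nonzero((vals < 0) | (vals > 1))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"{path}: methylation beta outside [0, 1] at feature "
                f"{df.index[i]!r}, sample {df.columns[j]!r}: {vals[i, j]}"
            )
    miss = df.isna().mean(axis=1)
    drop = miss > max_missing_frac
    if drop.any():
        logger.warning(
            "%s: dropped %d/%d features with > %.0f%% missing values",
            path,
            int(drop.sum()),
            len(df),
            100 * max_missing_frac,
        )
        df = df[~drop]
    return FeatureMatrix(df, kind=kind)


def write_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    fm.data.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="feature_id")


# ---------------------------------------------------------------------------
# phenotype TSV


def read_phenotype(path: str | Path) -> Phenotype:
    """Read a two-column phenotype TSV (sample_id, age)."""
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    if "age" not in cols:
        raise FormatError(f"{path}: phenotype table needs an 'age' column")
    df.columns = cols
    sid_col = "sample_id" if "sample_id" in cols else df.columns[0]
    return Phenotype(df[sid_col].astype(str).tolist(), df["age"].to_numpy(dtype=float))


def write_phenotype(pheno: Phenotype, path: str | Path) -> None:
    pd.DataFrame({"sample_id": pheno.sample_ids, "age": pheno.age}).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: tab-separated set_id, description, member genes."""
    sets: dict[str, GeneSet] = {}
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        logger.warning("%s: empty GMT file", path)
        return GeneSetCollection({})
    for i, ln in enumerate(lines, start=1):
        parts = ln.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: line {i}: GMT line needs >= 3 fields")
        sid, desc, *members = parts
        members = [m for m in members if m]
        if not members:
            raise FormatError(f"{path}: line {i}: gene set {sid!r} has no members")
        if sid in sets:
            raise FormatError(f"{path}: line {i}: duplicate set id {sid!r}")
        sets[sid] = GeneSet(desc, tuple(dict.fromkeys(members)))
    return GeneSetCollection(sets)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, gs in coll.items():
            fh.write("\t".join([sid, gs.description, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> IntervalTable:
    """Read BED3/BED4/BED6; ``track``/``browser``/``#`` lines are skipped."""
    rows = []
    path = Path(path)
    with open(path) as fh:
        for i, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            if ln.startswith(("track", "browser", "#")):
                continue
            parts = ln.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {i}: BED line needs >= 3 fields")
            chrom, start, end = parts[0], parts[1], parts[2]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}: line {i}: non-integer coordinates") from exc
            name = parts[3] if len(parts) > 3 and parts[3] else f"iv{i}"
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
            rows.append((chrom, start_i, end_i, name, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    return IntervalTable(df)


def write_bed(table: IntervalTable, path: str | Path) -> None:
    df = table.records.copy()
    df["score"] = 0
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# plain gene lists


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments skipped."""
    out = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if ln and not ln.startswith("#"):
                out.append(ln)
    return list(dict.fromkeys(out))


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
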