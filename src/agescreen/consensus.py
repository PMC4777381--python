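"""Cross-region consensus of screened features and site-to-gene mapping.

A feature is a consensus aging feature when it passes the correlation cutoff
with the *same sign* in at least ``min_regions`` regions (direction-specific
counting: a feature positive in two regions and negative in two supports
neither direction at min_regions=3).  Methylation sites are mapped to genes
through strand-aware promoter windows around annotated TSSs, and the gene
namespaces from the expression and methylation arms are combined by union.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import IntervalTable
from .screen import FLAG_OK, CorrelationTable

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = (-2000, 2000)


@dataclass
class ConsensusSet:
    """Sign-consistent consensus features across regions.

    ``table`` index: feature_id; columns: direction ('pos'/'neg'),
    n_support, plus one ``r_<region>`` column per input region.
    """

    table: pd.DataFrame
    min_regions: int
    cutoff_c: float

    @property
    def features(self) -> set[str]:
        return set(self.table.index)

    @property
    def positive(self) -> set[str]:
        return set(self.table.index[self.table["direction"] == "pos"])

    @property
    def negative(self) -> set[str]:
        return set(self.table.index[self.table["direction"] == "neg"])

    def counts(self) -> tuple[int, int, int]:
        """(n_positive, n_negative, total); the two directions partition the
        consensus, so the first two always sum to the third."""
        n_pos, n_neg = len(self.positive), len(self.negative)
        total = len(self.table)
        assert n_pos + n_neg == total
        return n_pos, n_neg, total

    def __len__(self) -> int:
        return len(self.table)


def consensus_across_regions(
    region_tables: list[CorrelationTable],
    cutoff_c: float,
    min_regions: int = 3,
) -> ConsensusSet:
    """Direction-specific consensus: a feature enters the positive (negative)
    consensus iff r > cutoff (r < -cutoff) in at least ``min_regions``
    regions.  Features absent or flagged in a region do not count toward
    support there."""
    if min_regions > len(region_tables):
        raise ConfigError(
            f"min_regions={min_regions} exceeds number of regions ({len(region_tables)})"
        )
    regions = []
    for i, t in enumerate(region_tables):
        regions.append(t.region or f"region{i + 1}")

    all_features = sorted(set().union(*(set(t.table.index) for t in region_tables)))
    r_cols = {}
    for name, t in zip(regions, region_tables):
        ok = t.table["flag"] == FLAG_OK
        r = t.table["r"].where(ok)
        r_cols[f"r_{name}"] = r.reindex(all_features)
    rmat = pd.DataFrame(r_cols, index=all_features)

    vals = rmat.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        n_pos = (vals > cutoff_c).sum(axis=1)
        n_neg = (vals < -cutoff_c).sum(axis=1)
    take_pos = n_pos >= min_regions
    take_neg = n_neg >= min_regions

    rows = []
    for i, feat in enumerate(all_features):
        if take_pos[i]:
            rows.append((feat, "pos", int(n_pos[i])))
        elif take_neg[i]:
            rows.append((feat, "neg", int(n_neg[i])))
    out = pd.DataFrame(rows, columns=["feature_id", "direction", "n_support"])
    out = out.set_index("feature_id")
    out = out.join(rmat)
    return ConsensusSet(out, min_regions=min_regions, cutoff_c=cutoff_c)


def promoter_windows(
    tss: IntervalTable, window: tuple[int, int] = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Strand-aware promoter windows, half-open, around each TSS record.

    The TSS position is the interval start on '+' (or unstranded) records
    and ``end - 1`` on '-' records; a window (a, b) maps to [t+a, t+b) on
    '+' and [t-b, t-a) on '-' (reflected through the TSS)."""
    a, b = window
    if a >= b:
        raise ConfigError(f"empty promoter window {window}")
    rec = tss.records
    t = np.where(rec["strand"] == "-", rec["end"].to_numpy() - 1, rec["start"].to_numpy())
    minus = (rec["strand"] == "-").to_numpy()
    lo = np.where(minus, t - b, t + a)
    hi = np.where(minus, t - a, t + b)
    return pd.DataFrame(
        {"chrom": rec["chrom"], "lo": lo, "hi": hi, "gene": rec["name"]}
    )


def map_sites_to_genes(
    site_names: set[str] | list[str],
    sites: IntervalTable,
    tss: IntervalTable,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> tuple[set[str], int]:
    """Map selected methylation sites to genes whose promoter window
    contains the site midpoint.

    A site can map to several genes (overlapping promoters all count).
    Returns (gene id set, number of site names with no known position).
    """
    if len(tss) == 0:
        raise ConfigError("TSS table is empty")
    positions = sites.by_name()
    wins = promoter_windows(tss, window)
    genes: set[str] = set()
    n_skipped = 0
    by_chrom = {c: g for c, g in wins.groupby("chrom")}
    for name in sorted(set(site_names)):
        if name not in positions:
            n_skipped += 1
            continue
        chrom, start, end, _ = positions[name]
        mid = (start + end) // 2
        g = by_chrom.get(chrom)
        if g is None:
            continue
        hit = (g["lo"] <= mid) & (mid < g["hi"])
        genes.update(g.loc[hit, "gene"])
    if n_skipped:
        logger.warning("map_sites_to_genes: %d site names had no position", n_skipped)
    return genes, n_skipped


def truncate_pct(numerator: int, denominator: int) -> float:
    """Percentage truncated (not rounded) to one decimal, e.g. 145/2743 -> 5.2."""
    if denominator <= 0:
        raise ConfigError("denominator must be positive")
    return math.floor(1000.0 * numerator / denominator) / 10.0


@dataclass
class UnionReport:
    union: set[str]
    intersection: set[str]
    pct_of_expression: float  # |intersection| / |expression set|, truncated


def union_aging_genes(expr_genes: set[str], meth_genes: set[str]) -> UnionReport:
    """Union of the expression-derived and methylation-derived aging gene
    sets, with the overlap percentage (share of expression-derived genes that
    also carry an aging methylation signal, truncated to one decimal)."""
    expr_genes, meth_genes = set(expr_genes), set(meth_genes)
    inter = expr_genes & meth_genes
    pct = truncate_pct(len(inter), len(expr_genes)) if expr_genes else 0.0
    return UnionReport(expr_genes | meth_genes, inter, pct)
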