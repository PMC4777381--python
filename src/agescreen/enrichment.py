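"""Fisher's-exact enrichment engine and TF-regulator prediction logic.

Two contingency constructions are supported for the one-sided ("greater")
test of x annotated genes among k inputs, with p annotated genes in a
universe of n:

* ``mode="paper"`` — the 2x2 is ``[x, k-x; p-x, n-k]``.  This is the table
  the source analysis used verbatim; note its fourth cell is ``n-k`` rather
  than the hypergeometric remainder, so the implied population is inflated
  to ``n + p - x``.
* ``mode="standard"`` — the standard hypergeometric table
  ``[x, k-x; p-x, n-k-(p-x)]``.

Both are evaluated exactly (hypergeometric survival function), identical to
``fisher.test(m, alternative="greater")`` on the corresponding table.  The
paper-faithful construction is the default so published numbers can be
reproduced; the standard mode is used where a proper hypergeometric test is
wanted (e.g. disease-overlap significance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import promoter_windows
from .errors import ConfigError, InputError
from .io import GeneSetCollection, IntervalTable
from .screen import FLAG_OK, CorrelationTable

logger = logging.getLogger(__name__)

MODES = ("paper", "standard")
DEFAULT_ALPHA = 0.01


@dataclass
class EnrichmentResult:
    set_id: str
    x: int  # input genes annotated
    k: int  # input gene count
    p: int  # universe genes annotated
    n: int  # universe size
    p_value: float
    mode: str

    def __post_init__(self) -> None:
        if not (0 <= self.x <= min(self.k, self.p)):
            raise ValueError(f"invalid contingency: x={self.x}, k={self.k}, p={self.p}")
        if self.k > self.n or self.p > self.n:
            raise ValueError("k and p cannot exceed the universe size n")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value outside [0, 1]")

    @property
    def coverage_fraction(self) -> float:
        return self.x / self.k if self.k else 0.0


def fisher_pvalue(x: int, k: int, p: int, n: int, mode: str = "paper") -> float:
    """One-sided ("greater") Fisher p-value for the chosen 2x2 construction.

    Exact: P(X >= x) for X hypergeometric with the table's margins.
    """
    if mode not in MODES:
        raise ConfigError(f"unknown mode {mode!r}")
    if not (0 <= x <= k and x <= p and k <= n and p <= n):
        raise ValueError(f"invalid counts x={x}, k={k}, p={p}, n={n}")
    if mode == "paper":
        # margins of [x, k-x; p-x, n-k]: population n+p-x, p annotated, k drawn
        total = n + p - x
        return float(stats.hypergeom.sf(x - 1, total, p, k))
    if n - k - (p - x) < 0:
        raise InputError(
            f"standard-mode table has a negative cell: n-k-(p-x) = {n - k - (p - x)}"
        )
    return float(stats.hypergeom.sf(x - 1, n, p, k))


def _universe_size(universe) -> tuple[int, set[str] | None]:
    if isinstance(universe, (int, np.integer)):
        if universe <= 0:
            raise ConfigError("universe size must be positive")
        return int(universe), None
    ids = set(universe)
    return len(ids), ids


def fisher_enrichment(
    input_genes,
    gene_set,
    universe,
    mode: str = "paper",
    set_id: str = "",
) -> EnrichmentResult:
    """Enrichment of ``gene_set`` members among ``input_genes``.

    ``universe`` is either an explicit id collection (inputs and set members
    outside it are dropped, with a logged count) or a bare integer size —
    the universe is never defaulted because published analyses are sensitive
    to it.
    """
    genes = set(input_genes)
    members = set(gene_set)
    n, universe_ids = _universe_size(universe)
    if universe_ids is not None:
        dropped = len(genes - universe_ids)
        if dropped:
            logger.warning("fisher_enrichment: %d input genes outside universe", dropped)
        genes &= universe_ids
        members &= universe_ids
    k = len(genes)
    p = len(members)
    x = len(genes & members)
    if k == 0:
        raise InputError("no input genes inside the universe")
    if k > n or p > n:
        raise InputError("universe size smaller than input or annotation set")
    return EnrichmentResult(
        set_id=set_id, x=x, k=k, p=p, n=n, p_value=fisher_pvalue(x, k, p, n, mode), mode=mode
    )


def enrich_collection(
    input_genes,
    collection: GeneSetCollection,
    universe,
    mode: str = "paper",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Run fisher_enrichment against every set in a collection.

    Returns a DataFrame sorted by ascending p-value (ties by set id) with
    columns set_id, x, k, p, n, p_value, coverage_fraction (and q_value if
    ``bh_correct``; the default reports raw p only).
    """
    rows = []
    for sid in sorted(collection):
        res = fisher_enrichment(
            input_genes, collection.members(sid), universe, mode=mode, set_id=sid
        )
        rows.append(
            (sid, res.x, res.k, res.p, res.n, res.p_value, res.coverage_fraction)
        )
    df = pd.DataFrame(
        rows, columns=["set_id", "x", "k", "p", "n", "p_value", "coverage_fraction"]
    )
    if bh_correct and len(df):
        from statsmodels.stats.multitest import multipletests

        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values(["p_value", "set_id"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# TF prediction chain


def rank_and_select_top(genes, corr: CorrelationTable, limit: int = 200) -> list[str]:
    """Rank genes by |r| with age (descending) and keep the top ``limit``.

    Ties are broken by lexicographic feature id so the selection is
    deterministic; if there are at most ``limit`` genes all are returned.
    """
    genes = list(dict.fromkeys(genes))
    missing = [g for g in genes if g not in corr.table.index]
    if missing:
        raise InputError(f"genes not scored in correlation table: {missing[:5]}")
    order = sorted(genes, key=lambda g: (-abs(corr.r_of(g)), g))
    return order[:limit]


def predict_tfs_per_region(
    input_genes,
    tf_targets: GeneSetCollection,
    universe,
    alpha: float = DEFAULT_ALPHA,
    mode: str = "paper",
) -> pd.DataFrame:
    """Per-region regulator prediction: enrichment of every TF's target set
    among the input genes; TFs with p < alpha, ranked by ascending p."""
    if not input_genes:
        raise InputError("empty input gene list")
    if len(tf_targets) == 0:
        raise ConfigError("empty TF target collection")
    df = enrich_collection(input_genes, tf_targets, universe, mode=mode)
    df = df.rename(columns={"set_id": "tf"})
    return df[df["p_value"] < alpha].reset_index(drop=True)


def tf_consensus(
    per_region: dict[str, pd.DataFrame], min_regions: int = 3
) -> list[str]:
    """TFs enriched in at least ``min_regions`` regions, ordered by total
    -log10 p over the regions in which they are enriched (largest first)."""
    if min_regions > len(per_region):
        raise ConfigError("min_regions exceeds number of regions")
    support: dict[str, int] = {}
    score: dict[str, float] = {}
    for df in per_region.values():
        for row in df.itertuples(index=False):
            support[row.tf] = support.get(row.tf, 0) + 1
            pv = max(row.p_value, 1e-300)
            score[row.tf] = score.get(row.tf, 0.0) - float(np.log10(pv))
    kept = [tf for tf, s in support.items() if s >= min_regions]
    return sorted(kept, key=lambda tf: (-score[tf], tf))


def target_coverage_filter(
    tf: str,
    input_genes,
    tf_targets: GeneSetCollection,
    threshold: float = 0.5,
) -> tuple[float, bool]:
    """Fraction of input genes annotated as targets of ``tf``; passes only
    with strictly more than ``threshold`` covered."""
    genes = set(input_genes)
    if not genes:
        raise InputError("empty input gene list")
    if tf not in tf_targets:
        raise ConfigError(f"TF {tf!r} not in target collection")
    frac = len(set(tf_targets.members(tf)) & genes) / len(genes)
    return frac, frac > threshold


def tf_age_profile_check(
    tf_ids,
    region_tables: list[CorrelationTable],
    cutoff: float = 0.3,
    min_regions: int = 3,
) -> pd.DataFrame:
    """Check whether each TF's own expression is age-correlated: |r| > cutoff
    with a consistent sign in at least ``min_regions`` regions.

    Returns a DataFrame with per-region r, the derived direction
    ('pos'/'neg'/'none'/'unknown') and the age_correlated flag; a TF absent
    from every table is flagged 'unknown'.
    """
    rows = []
    regions = [t.region or f"region{i + 1}" for i, t in enumerate(region_tables)]
    for tf in tf_ids:
        rs = []
        for t in region_tables:
            if tf in t.table.index and t.table.loc[tf, "flag"] == FLAG_OK:
                rs.append(float(t.table.loc[tf, "r"]))
            else:
                rs.append(float("nan"))
        arr = np.array(rs)
        if np.all(np.isnan(arr)):
            direction, corr_flag = "unknown", False
        else:
            n_pos = int(np.nansum(arr > cutoff))
            n_neg = int(np.nansum(arr < -cutoff))
            if n_pos >= min_regions:
                direction, corr_flag = "pos", True
            elif n_neg >= min_regions:
                direction, corr_flag = "neg", True
            else:
                direction, corr_flag = "none", False
        rows.append([tf, *rs, direction, corr_flag])
    return pd.DataFrame(
        rows, columns=["tf", *[f"r_{r}" for r in regions], "direction", "age_correlated"]
    )


@dataclass
class BindingSiteCoverage:
    observed_fraction: float
    random_fraction: float
    p_value: float
    n_genes_used: int
    n_skipped: int


def _genes_with_promoter_site(
    genes: list[str], sites: IntervalTable, tss: IntervalTable, window
) -> tuple[set[str], int]:
    wins = promoter_windows(tss, window)
    wins = wins.set_index("gene")
    mids = sites.midpoints()
    chroms = sites.records["chrom"].to_numpy()
    by_chrom: dict[str, np.ndarray] = {}
    for c in np.unique(chroms):
        by_chrom[c] = np.sort(mids[chroms == c])
    covered: set[str] = set()
    n_skipped = 0
    for g in genes:
        if g not in wins.index:
            n_skipped += 1
            continue
        row = wins.loc[g]
        arr = by_chrom.get(row["chrom"])
        if arr is None:
            continue
        i = np.searchsorted(arr, row["lo"], side="left")
        if i < arr.size and arr[i] < row["hi"]:
            covered.add(g)
    return covered, n_skipped


def binding_site_coverage(
    genes,
    chip_sites: IntervalTable,
    tss: IntervalTable,
    window: tuple[int, int] = (-2000, 2000),
    n_random: int = 1000,
    seed: int | None = None,
) -> BindingSiteCoverage:
    """Fraction of genes with at least one ChIP binding-site midpoint inside
    their strand-aware promoter window, compared against size-matched random
    gene draws from the TSS universe and tested with the standard-mode
    Fisher construction (with-site vs without, input vs universe)."""
    if seed is None:
        raise ConfigError("seed is required for the random draws")
    genes = sorted(set(genes))
    universe_genes = sorted(set(tss.records["name"]))
    covered_univ, _ = _genes_with_promoter_site(universe_genes, chip_sites, tss, window)
    used = [g for g in genes if g in set(universe_genes)]
    n_skipped = len(genes) - len(used)
    if n_skipped:
        logger.warning("binding_site_coverage: %d genes without TSS skipped", n_skipped)
    if not used:
        raise InputError("no input genes with a known TSS")
    obs_cov = [g for g in used if g in covered_univ]
    observed = len(obs_cov) / len(used)

    rng = np.random.default_rng(seed)
    k = len(used)
    fracs = np.empty(n_random)
    univ_arr = np.array(universe_genes)
    for i in range(n_random):
        draw = rng.choice(univ_arr, size=k, replace=False)
        fracs[i] = sum(1 for g in draw if g in covered_univ) / k
    res = fisher_enrichment(
        used, covered_univ, set(universe_genes), mode="standard", set_id="binding_sites"
    )
    return BindingSiteCoverage(
        observed_fraction=observed,
        random_fraction=float(fracs.mean()),
        p_value=res.p_value,
        n_genes_used=len(used),
        n_skipped=n_skipped,
    )
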