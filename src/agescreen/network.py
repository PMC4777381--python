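"""Regulator-network assembly from co-expression plus annotation enrichment.

For each query gene the regulators are predicted in two steps: (1) take the
k genes with the most similar expression profiles (highest positive Pearson
correlation; co-expressed genes are assumed co-regulated), and (2) test
every candidate regulator's annotated target set for enrichment among those
neighbors.  Regulators can be supported by the motif channel, the
literature channel, or both; edges carry that evidence class.  The
assembled network reports the degree summaries used to describe such
networks: how many targets acquired at least one regulator, the histogram
of distinct-regulator counts per target, total edges and dual-evidence
edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .io import FeatureMatrix, GeneSetCollection
from .enrichment import DEFAULT_ALPHA, fisher_enrichment

DEFAULT_K = 200

EVIDENCE = ("motif", "literature", "both")


@dataclass
class RegulatoryNetwork:
    """TF -> target edges with evidence class and degree summaries."""

    edges: pd.DataFrame  # columns: regulator, target, evidence
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.edges):
            bad = ~self.edges["evidence"].isin(EVIDENCE)
            if bad.any():
                raise ValueError("unknown evidence class in edge table")
            loops = self.edges["regulator"] == self.edges["target"]
            if loops.any():
                raise ValueError("self-loops are not allowed")
        self.summary = dict(self.summary)
        hist = self.summary.get("regulator_count_histogram", {})
        n_targets, n_edges = summarize_histogram(hist)
        assert n_targets == self.summary.get("n_targets_with_regulators", n_targets)
        assert n_edges == self.summary.get("n_edges", n_edges)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.regulator, row.target, evidence=row.evidence)
        return g

    def __len__(self) -> int:
        return len(self.edges)


def summarize_histogram(hist: dict[int, int]) -> tuple[int, int]:
    """(n_targets_with_regulators, n_edges) from a {distinct-regulator
    multiplicity: target count} histogram.  E.g. {1: 79, 2: 72, 3: 28}
    yields (179, 307)."""
    n_targets = sum(hist.values())
    n_edges = sum(m * c for m, c in hist.items())
    return n_targets, n_edges


def coexpressed_neighbors(
    gene: str,
    matrix: FeatureMatrix,
    k: int = DEFAULT_K,
    use_abs: bool = False,
) -> list[str]:
    """The k genes most co-expressed with ``gene`` (highest Pearson r,
    positive by default; ``use_abs`` ranks by |r| instead).  Ties break
    lexicographically; the query itself is excluded."""
    if gene not in set(matrix.feature_ids):
        raise InputError(f"gene {gene!r} absent from matrix")
    data = matrix.data
    x = data.loc[gene].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise InputError(f"gene {gene!r} has zero variance")
    vals = data.to_numpy(dtype=float)
    xc = x - x.mean()
    vc = vals - vals.mean(axis=1, keepdims=True)
    denom = np.sqrt((vc * vc).sum(axis=1)) * np.sqrt((xc * xc).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vc @ xc) / denom
    score = np.abs(r) if use_abs else r
    pairs = [
        (float(s), g)
        for g, s in zip(matrix.feature_ids, score)
        if g != gene and np.isfinite(s)
    ]
    pairs.sort(key=lambda t: (-t[0], t[1]))
    return [g for _, g in pairs[:k]]


def predict_regulators_for_gene(
    gene: str,
    matrix: FeatureMatrix,
    motif_sets: GeneSetCollection,
    literature_sets: GeneSetCollection,
    universe,
    alpha: float = DEFAULT_ALPHA,
    k: int = DEFAULT_K,
    mode: str = "paper",
) -> list[tuple[str, str]]:
    """Predicted (regulator, evidence) pairs for one gene.

    A regulator is reported when its target set is enriched (p < alpha)
    among the gene's co-expressed neighbors; evidence is 'motif',
    'literature' or 'both' depending on which channels support it.
    """
    neighbors = coexpressed_neighbors(gene, matrix, k=k)
    hits: dict[str, set[str]] = {}
    for channel, coll in (("motif", motif_sets), ("literature", literature_sets)):
        for tf in sorted(coll):
            res = fisher_enrichment(
                neighbors, coll.members(tf), universe, mode=mode, set_id=tf
            )
            if res.p_value < alpha:
                hits.setdefault(tf, set()).add(channel)
    out = []
    for tf in sorted(hits):
        ch = hits[tf]
        evidence = "both" if len(ch) == 2 else next(iter(ch))
        out.append((tf, evidence))
    return out


def build_network(
    genes,
    matrix: FeatureMatrix,
    motif_sets: GeneSetCollection,
    literature_sets: GeneSetCollection,
    universe,
    alpha: float = DEFAULT_ALPHA,
    k: int = DEFAULT_K,
    regulator_whitelist=None,
    mode: str = "paper",
) -> RegulatoryNetwork:
    """Predict regulators for every query gene and assemble the network.

    ``regulator_whitelist`` restricts reported regulators (e.g. to TFs that
    themselves show age-correlated expression); by default every enriched
    regulator is kept.  Self-edges are dropped.
    """
    if not genes:
        raise ConfigError("empty query gene list")
    whitelist = set(regulator_whitelist) if regulator_whitelist is not None else None
    rows = []
    for gene in sorted(set(genes)):
        for tf, evidence in predict_regulators_for_gene(
            gene, matrix, motif_sets, literature_sets, universe, alpha=alpha, k=k, mode=mode
        ):
            if tf == gene:
                continue
            if whitelist is not None and tf not in whitelist:
                continue
            rows.append((tf, gene, evidence))
    edges = pd.DataFrame(rows, columns=["regulator", "target", "evidence"])
    per_target = edges.groupby("target")["regulator"].nunique() if len(edges) else pd.Series(dtype=int)
    hist_series = per_target.value_counts().sort_index()
    hist = {int(m): int(c) for m, c in hist_series.items()}
    n_targets, n_edges_hist = summarize_histogram(hist)
    summary = {
        "n_targets_with_regulators": n_targets,
        "regulator_count_histogram": hist,
        "n_edges": len(edges),
        "n_dual_evidence_edges": int((edges["evidence"] == "both").sum()) if len(edges) else 0,
    }
    assert n_edges_hist == len(edges)
    assert summary["n_dual_evidence_edges"] <= summary["n_edges"]
    return RegulatoryNetwork(edges=edges, summary=summary)
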