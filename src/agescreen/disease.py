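"""Overlap between aging genes and disease gene sets, and shared pathways.

Two questions: (1) is the overlap between an aging gene set and a disease
(e.g. Alzheimer's) gene set larger than chance, given a declared gene
universe — tested with the standard hypergeometric Fisher construction; and
(2) which pathways are enriched in *both* sets — each pathway is tested
against either list independently and flagged shared when both p-values
clear the significance threshold.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .errors import InputError
from .io import GeneSetCollection
from .enrichment import fisher_enrichment

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def normalize_gene_id(gene: str) -> str:
    """Case-fold and strip trailing version suffixes ('.1', '.2', ...)."""
    return _VERSION_SUFFIX.sub("", gene.strip()).casefold()


@dataclass
class OverlapReport:
    n_a: int
    n_b: int
    n_overlap: int
    universe_n: int
    p_value: float
    members: list[str]

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_a, self.n_b):
            raise ValueError("overlap larger than the smaller set")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value outside [0, 1]")


def gene_set_overlap(set_a, set_b, universe_n: int) -> OverlapReport:
    """Overlap of two gene sets after id normalization, with a one-sided
    hypergeometric (standard-mode Fisher) significance against a declared
    universe size."""
    a = {normalize_gene_id(g) for g in set_a}
    b = {normalize_gene_id(g) for g in set_b}
    if universe_n < len(a | b):
        raise InputError(
            f"universe_n={universe_n} smaller than |A union B|={len(a | b)}"
        )
    inter = sorted(a & b)
    res = fisher_enrichment(a, b, universe_n, mode="standard", set_id="overlap")
    return OverlapReport(
        n_a=len(a),
        n_b=len(b),
        n_overlap=len(inter),
        universe_n=universe_n,
        p_value=res.p_value,
        members=inter,
    )


@dataclass
class SharedPathwayReport:
    table: pd.DataFrame  # pathway, p_a, p_b, shared
    alpha: float

    @property
    def shared(self) -> list[str]:
        return self.table.loc[self.table["shared"], "pathway"].tolist()


def shared_pathways(
    set_a,
    set_b,
    pathway_sets: GeneSetCollection,
    universe_n: int,
    alpha: float = 0.01,
    mode: str = "standard",
) -> SharedPathwayReport:
    """Pathways enriched in both gene lists.

    Each pathway is tested independently against set A and set B; it is
    flagged shared iff both p-values are below ``alpha``.  Rows are sorted
    by the worse of the two p-values (ascending), then pathway id.
    """
    if len(pathway_sets) == 0:
        raise InputError("empty pathway collection")
    a = {normalize_gene_id(g) for g in set_a}
    b = {normalize_gene_id(g) for g in set_b}
    rows = []
    for pid in sorted(pathway_sets):
        members = {normalize_gene_id(g) for g in pathway_sets.members(pid)}
        pa = fisher_enrichment(a, members, universe_n, mode=mode, set_id=pid).p_value
        pb = fisher_enrichment(b, members, universe_n, mode=mode, set_id=pid).p_value
        rows.append((pid, pa, pb, pa < alpha and pb < alpha))
    df = pd.DataFrame(rows, columns=["pathway", "p_a", "p_b", "shared"])
    df["worst_p"] = df[["p_a", "p_b"]].max(axis=1)
    df = df.sort_values(["worst_p", "pathway"], kind="mergesort").drop(columns="worst_p")
    return SharedPathwayReport(table=df.reset_index(drop=True), alpha=alpha)
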