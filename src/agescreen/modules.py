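"""Co-expression modules: correlation-distance clustering plus annotation.

Gene-pair similarity is the correlation distance d = 1 - r (Pearson, over
all shared samples), so d ranges over [0, 2] with 0 for identical and 2 for
exactly anti-correlated profiles.  Modules are found by average-linkage
hierarchical clustering of the distance matrix with a fixed-height tree cut;
clusters smaller than ``min_size`` are left unassigned (label 0, the
analogue of WGCNA's grey module).  This is a deliberately simple, fully
deterministic stand-in for soft-threshold/TOM-based module detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ConfigError, InputError
from .io import FeatureMatrix, GeneSetCollection
from .enrichment import enrich_collection

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 30
DEFAULT_CUT_HEIGHT = 0.75


@dataclass
class ModuleAssignment:
    """gene -> module label; 1..n_modules are real modules (numbered by
    decreasing size), 0 means unassigned."""

    labels: dict[str, int]
    n_modules: int
    min_size: int
    cut_height: float
    method: str = "average"

    def __post_init__(self) -> None:
        found = sorted({m for m in self.labels.values() if m > 0})
        if found != list(range(1, self.n_modules + 1)):
            raise ValueError("module labels must be contiguous 1..n_modules")

    def genes_in(self, module: int) -> list[str]:
        return sorted(g for g, m in self.labels.items() if m == module)

    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for m in self.labels.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes


def correlation_distance(
    matrix: FeatureMatrix, genes=None
) -> tuple[np.ndarray, list[str]]:
    """Correlation-distance matrix d = 1 - Pearson r between gene profiles.

    Zero-variance genes are excluded with a warning.  Returns (distance
    matrix, kept gene ids); the matrix is symmetric with a zero diagonal.
    """
    if genes is None:
        genes = matrix.feature_ids
    genes = [g for g in dict.fromkeys(genes)]
    missing = [g for g in genes if g not in set(matrix.feature_ids)]
    if missing:
        raise InputError(f"genes absent from matrix: {missing[:5]}")
    if len(genes) < 2:
        raise InputError("need at least 2 genes for a distance matrix")
    sub = matrix.data.loc[genes]
    # pandas corr handles pairwise-complete observations
    corr = sub.T.corr(method="pearson")
    var0 = sub.std(axis=1, ddof=0) == 0
    if var0.any():
        dropped = list(sub.index[var0])
        logger.warning("correlation_distance: dropped %d zero-variance genes", len(dropped))
        corr = corr.drop(index=dropped, columns=dropped)
        genes = [g for g in genes if g not in set(dropped)]
    d = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    d = (d + d.T) / 2.0
    assert np.allclose(d, d.T) and float(np.trace(d)) == 0.0
    return d, genes


def detect_modules(
    distance: np.ndarray,
    genes: list[str],
    min_size: int = DEFAULT_MIN_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    method: str = "average",
) -> ModuleAssignment:
    """Average-linkage clustering of a correlation-distance matrix with a
    fixed-height cut.

    Clusters with fewer than ``min_size`` genes become label 0 (unassigned);
    surviving clusters are renumbered 1..n by decreasing size (ties broken
    by the lexicographically smallest member id, so the labelling is
    invariant to input gene order).
    """
    distance = np.asarray(distance, dtype=float)
    if distance.ndim != 2 or distance.shape[0] != distance.shape[1]:
        raise ConfigError("distance must be a square matrix")
    if distance.shape[0] != len(genes):
        raise ConfigError("distance size does not match gene list")
    if len(genes) < 2:
        raise InputError("need at least 2 genes")
    condensed = squareform(distance, checks=False)
    link = hierarchy.linkage(condensed, method=method)
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")

    clusters: dict[int, list[str]] = {}
    for g, c in zip(genes, raw):
        clusters.setdefault(int(c), []).append(g)
    big = [(members, min(members)) for members in clusters.values() if len(members) >= min_size]
    big.sort(key=lambda t: (-len(t[0]), t[1]))
    labels = {g: 0 for g in genes}
    for new_label, (members, _) in enumerate(big, start=1):
        for g in members:
            labels[g] = new_label
    return ModuleAssignment(
        labels=labels,
        n_modules=len(big),
        min_size=min_size,
        cut_height=cut_height,
        method=method,
    )


def module_enrichment(
    assignment: ModuleAssignment,
    annotations: GeneSetCollection,
    universe,
    alpha: float = 0.01,
    mode: str = "paper",
) -> pd.DataFrame:
    """Annotation enrichment for every module (label >= 1).

    Returns a long DataFrame (module, set_id, x, k, p, n, p_value,
    coverage_fraction, significant) sorted by module then p-value.
    """
    if not assignment.labels:
        raise InputError("empty module assignment")
    frames = []
    for m in range(1, assignment.n_modules + 1):
        members = assignment.genes_in(m)
        df = enrich_collection(members, annotations, universe, mode=mode)
        df.insert(0, "module", m)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["module", "set_id", "x", "k", "p", "n", "p_value",
                     "coverage_fraction", "significant"]
        )
    out = pd.concat(frames, ignore_index=True)
    out["significant"] = out["p_value"] < alpha
    return out
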