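"""Per-feature Spearman correlation with age and permutation calibration.

The screen computes, for every feature (gene or methylation site), the
Spearman correlation between its profile and donor age.  Because no
parametric null is assumed, the selection cutoff is calibrated by shuffling:
the age vector is permuted over samples, all feature correlations are
recomputed, and the per-iteration extreme correlations (minimum and maximum)
define the range of correlations attainable by chance.  The symmetric cutoff
``c`` is chosen so that a requested fraction of iterations (default 95%)
have their entire extreme range inside [-c, c] — a family-wise control over
features.  The selected cutoff is also assigned a z-score p-value from the
Fisher-transformed null extremes.

Spearman is computed as Pearson on average ranks (exact tie correction),
vectorized over features; permutation iterations reuse the rank matrix, so a
full 1000-round calibration is a single matrix product per iteration batch.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InputError
from .io import FeatureMatrix, Phenotype

MIN_SHARED_SAMPLES = 10

#: the operating cutoff used when calibration is skipped
DEFAULT_CUTOFF = 0.3

FLAG_OK = ""
FLAG_ZERO_VARIANCE = "zero_variance"
FLAG_TOO_FEW = "too_few_samples"


@dataclass
class CorrelationTable:
    """Per-feature Spearman r against age for one region.

    ``table`` columns: feature_id (index), r, n_used, flag.  Features with
    fewer than 10 usable samples or zero variance are flagged (r = NaN) and
    never selected.
    """

    table: pd.DataFrame
    region: str = ""

    def __post_init__(self) -> None:
        r = self.table["r"].to_numpy(dtype=float)
        ok = self.table["flag"] == FLAG_OK
        if np.any(np.abs(r[ok.to_numpy()]) > 1 + 1e-12):
            raise ValueError("|r| > 1 in correlation table")

    @property
    def r(self) -> pd.Series:
        return self.table["r"]

    def scored(self) -> pd.DataFrame:
        """Rows with a defined correlation."""
        return self.table[self.table["flag"] == FLAG_OK]

    def r_of(self, feature_id: str) -> float:
        return float(self.table.loc[feature_id, "r"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CutoffCalibration:
    """Shuffle-derived cutoff and its z-score significance.

    ``extremes`` holds (min_r, max_r) per iteration; ``cutoff_c`` is the
    smallest symmetric threshold containing the extreme pair of at least a
    ``coverage`` fraction of iterations; ``z_mean``/``z_sd`` summarize the
    Fisher-transformed magnitudes of the recorded extremes; ``p_cutoff`` is
    the upper-tail normal probability of the cutoff on that z scale.
    """

    n_iter: int
    coverage: float
    extremes: np.ndarray  # (n_iter, 2): min_r, max_r
    cutoff_c: float
    z_mean: float
    z_sd: float
    p_cutoff: float
    seed: int | None = None
    pooled: bool = False
    pooled_abs_r: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.extremes = np.asarray(self.extremes, dtype=float)
        if self.extremes.shape != (self.n_iter, 2):
            raise ValueError("extremes must have shape (n_iter, 2)")
        if not 0 < self.cutoff_c <= 1:
            raise ValueError(f"cutoff_c out of (0, 1]: {self.cutoff_c}")
        if not 0 <= self.p_cutoff <= 1:
            raise ValueError("p_cutoff outside [0, 1]")


@dataclass
class ScreenResult:
    positive: set[str]
    negative: set[str]
    cutoff_c: float


# ---------------------------------------------------------------------------
# Spearman machinery


def _average_ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average", axis=-1)


def _standardize(x: np.ndarray) -> np.ndarray:
    """Center and scale rows to unit norm; zero-variance rows become NaN."""
    x = np.asarray(x, dtype=float)
    c = x - x.mean(axis=-1, keepdims=True)
    norm = np.sqrt((c * c).sum(axis=-1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        return c / norm


def spearman_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman r of two 1-D vectors on their pairwise-complete support.

    Ranks are recomputed on the shared support (average ranks for ties);
    returns NaN if fewer than 2 complete pairs or either side is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.isfinite(x) & np.isfinite(y)
    if m.sum() < 2:
        return float("nan")
    rx = _average_ranks(x[m])
    ry = _average_ranks(y[m])
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    sx = _standardize(rx)
    sy = _standardize(ry)
    return float(np.clip(sx @ sy, -1.0, 1.0))


def _align(
    matrix: FeatureMatrix, pheno: Phenotype, min_samples: int = MIN_SHARED_SAMPLES
) -> tuple[pd.DataFrame, np.ndarray]:
    """Intersect matrix and phenotype samples by id (order-independent)."""
    shared = [s for s in matrix.sample_ids if s in set(pheno.sample_ids)]
    if len(shared) < max(min_samples, 3):
        raise InputError(
            f"only {len(shared)} shared samples between matrix and phenotype "
            f"(need >= {max(min_samples, 3)})"
        )
    return matrix.data[shared], pheno.age_of(shared)


def spearman_age_correlation(
    matrix: FeatureMatrix,
    pheno: Phenotype,
    region: str = "",
    min_samples: int = MIN_SHARED_SAMPLES,
) -> CorrelationTable:
    """Spearman correlation of every feature with age.

    Samples are aligned by id.  Features with complete data go through the
    vectorized rank/Pearson path; features with missing values are scored on
    their pairwise-complete samples.  Zero-variance features and features
    with fewer than ``min_samples`` usable samples are flagged with r = NaN
    (the default floor of 10 can be lowered for small exact examples).
    """
    data, age = _align(matrix, pheno, min_samples)
    vals = data.to_numpy(dtype=float)
    n_feat, n = vals.shape
    if np.ptp(_average_ranks(age)) == 0:
        raise InputError("age vector is constant: correlations undefined")

    r = np.full(n_feat, np.nan)
    n_used = np.zeros(n_feat, dtype=int)
    flag = np.array([FLAG_OK] * n_feat, dtype=object)

    complete = np.isfinite(vals).all(axis=1)
    if complete.any():
        ranks = _average_ranks(vals[complete])
        sx = _standardize(ranks)
        sa = _standardize(_average_ranks(age)).ravel()
        rc = sx @ sa
        const = ~np.isfinite(rc)
        rc = np.clip(rc, -1.0, 1.0)
        idx = np.flatnonzero(complete)
        r[idx] = rc
        n_used[idx] = n
        r[idx[const]] = np.nan
        flag[idx[const]] = FLAG_ZERO_VARIANCE

    for i in np.flatnonzero(~complete):
        x = vals[i]
        m = np.isfinite(x)
        n_used[i] = int(m.sum())
        if n_used[i] < max(min_samples, 3):
            flag[i] = FLAG_TOO_FEW
            continue
        ri = spearman_pair(x, age)
        if math.isnan(ri):
            flag[i] = FLAG_ZERO_VARIANCE
        else:
            r[i] = ri

    table = pd.DataFrame(
        {"r": r, "n_used": n_used, "flag": flag},
        index=pd.Index(matrix.feature_ids, name="feature_id"),
    )
    return CorrelationTable(table, region=region)


def fisher_transform(r):
    """Fisher z-transform, z = atanh(r) = 0.5*ln((1+r)/(1-r)); |r| must be < 1."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1):
        raise ValueError("fisher_transform requires |r| < 1")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# permutation calibration


def _null_extremes(
    sx: np.ndarray, age: np.ndarray, perms: np.ndarray
) -> np.ndarray:
    """(min_r, max_r) per permutation.  ``sx`` is the standardized rank
    matrix (features x samples); ``perms`` is (n_iter, n) of permutation
    indices applied to the age vector."""
    sa = _standardize(_average_ranks(age)).ravel()
    permuted = sa[perms]  # (n_iter, n)
    rr = sx @ permuted.T  # (n_features, n_iter)
    rr = np.clip(rr, -1.0, 1.0)
    return np.stack([rr.min(axis=0), rr.max(axis=0)], axis=1)


def _complete_standardized_ranks(
    matrix: FeatureMatrix, pheno: Phenotype, min_samples: int = MIN_SHARED_SAMPLES
):
    data, age = _align(matrix, pheno, min_samples)
    vals = data.to_numpy(dtype=float)
    complete = np.isfinite(vals).all(axis=1)
    ranks = _average_ranks(vals[complete])
    sx = _standardize(ranks)
    keep = np.isfinite(sx).all(axis=1)  # drop zero-variance features
    sx = sx[keep]
    if sx.shape[0] == 0:
        raise InputError("no scoreable features for calibration")
    return sx, age


def cutoff_from_extremes(extremes: np.ndarray, coverage: float) -> float:
    """Smallest symmetric c with >= coverage of iterations inside [-c, c].

    Equals the ``ceil(coverage * n_iter)``-th order statistic of the
    per-iteration extreme magnitude max(|min_r|, max_r).
    """
    ext = np.maximum(np.abs(extremes[:, 0]), np.abs(extremes[:, 1]))
    n = ext.size
    m = int(math.ceil(coverage * n))
    m = min(max(m, 1), n)
    return float(np.sort(ext)[m - 1])


def calibrate_cutoff(
    matrix: FeatureMatrix,
    pheno: Phenotype,
    n_iter: int = 1000,
    coverage: float = 0.95,
    seed: int | None = None,
    exhaustive: bool = False,
    pooled: bool = False,
) -> CutoffCalibration:
    """Permutation calibration of the symmetric selection cutoff.

    Each iteration permutes the age vector over samples (the same
    permutation for every feature, preserving inter-feature correlation) and
    records the minimum and maximum feature correlation.  ``cutoff_c`` is
    the ``coverage``-quantile of the per-iteration extreme magnitude; with
    ``pooled=True`` it is instead the ``coverage``-quantile of the pooled
    magnitudes of all recorded extremes.  ``exhaustive=True`` enumerates all
    n! permutations (small n only) instead of sampling.

    z_mean/z_sd are the mean and standard deviation of the
    Fisher-transformed magnitudes of the recorded extremes (|r| clipped just
    below 1 so degenerate perfect correlations stay finite), and p_cutoff is
    the upper-tail normal probability of the cutoff on that scale.
    """
    if not 0 < coverage <= 1:
        raise ConfigError(f"coverage must be in (0, 1]: {coverage}")
    sx, age = _complete_standardized_ranks(
        matrix, pheno, min_samples=3 if exhaustive else MIN_SHARED_SAMPLES
    )
    n = age.size

    if exhaustive:
        if n > 8:
            raise ConfigError("exhaustive calibration is limited to n <= 8 samples")
        perms = np.array(list(itertools.permutations(range(n))), dtype=int)
        n_iter = perms.shape[0]
    else:
        if n_iter < 100:
            raise ConfigError("n_iter must be >= 100 (or use exhaustive=True)")
        if seed is None:
            raise ConfigError("seed is required for sampled calibration")
        rng = np.random.default_rng(seed)
        perms = np.argsort(rng.random((n_iter, n)), axis=1)

    extremes = _null_extremes(sx, age, perms)

    pooled_abs = None
    if pooled:
        sa = _standardize(_average_ranks(age)).ravel()
        rr = np.clip(sx @ (sa[perms]).T, -1.0, 1.0)
        pooled_abs = np.abs(rr).ravel()
        npool = pooled_abs.size
        m = min(max(int(math.ceil(coverage * npool)), 1), npool)
        cutoff_c = float(np.sort(pooled_abs)[m - 1])
    else:
        cutoff_c = cutoff_from_extremes(extremes, coverage)

    abs_ext = np.abs(extremes).ravel()
    z = np.arctanh(np.clip(abs_ext, None, 1 - 1e-12))
    z_mean = float(z.mean())
    z_sd = float(z.std(ddof=1)) if z.size > 1 else 0.0
    zc = float(np.arctanh(min(cutoff_c, 1 - 1e-12)))
    if z_sd > 0:
        p_cutoff = float(stats.norm.sf((zc - z_mean) / z_sd))
    else:
        p_cutoff = 1.0 if zc <= z_mean else 0.0

    return CutoffCalibration(
        n_iter=n_iter,
        coverage=coverage,
        extremes=extremes,
        cutoff_c=cutoff_c,
        z_mean=z_mean,
        z_sd=z_sd,
        p_cutoff=p_cutoff,
        seed=seed,
        pooled=pooled,
        pooled_abs_r=pooled_abs,
    )


def null_exceedance_rate(
    matrix: FeatureMatrix,
    pheno: Phenotype,
    cutoff_c: float,
    n_iter: int = 500,
    seed: int | None = None,
) -> float:
    """Fraction of fresh shuffles whose extreme correlation exceeds the
    cutoff — a self-consistency check of the calibrated threshold."""
    if seed is None:
        raise ConfigError("seed is required")
    sx, age = _complete_standardized_ranks(matrix, pheno)
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_iter, age.size)), axis=1)
    extremes = _null_extremes(sx, age, perms)
    ext = np.maximum(np.abs(extremes[:, 0]), np.abs(extremes[:, 1]))
    return float(np.mean(ext > cutoff_c))


def screen_features(corr: CorrelationTable, cutoff_c: float) -> ScreenResult:
    """Select features with r > cutoff (positive) or r < -cutoff (negative).

    Inequalities are strict (a feature at exactly the cutoff is excluded);
    flagged features are never selected.
    """
    if not 0 < cutoff_c < 1:
        raise ConfigError(f"cutoff must be in (0, 1): {cutoff_c}")
    scored = corr.scored()
    r = scored["r"]
    pos = set(scored.index[r > cutoff_c])
    neg = set(scored.index[r < -cutoff_c])
    return ScreenResult(positive=pos, negative=neg, cutoff_c=cutoff_c)
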