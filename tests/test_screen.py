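import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from agescreen import (
    ConfigError,
    CorrelationTable,
    FeatureMatrix,
    InputError,
    Phenotype,
    calibrate_cutoff,
    cutoff_from_extremes,
    fisher_transform,
    null_exceedance_rate,
    screen_features,
    spearman_age_correlation,
    spearman_pair,
)
from oracles import spearman_oracle


def _matrix(rows: dict[str, list[float]], sids=None) -> FeatureMatrix:
    sids = sids or [f"S{i}" for i in range(len(next(iter(rows.values()))))]
    return FeatureMatrix(pd.DataFrame(rows, index=sids).T)


class TestSpearman:
    def test_perfect_monotone(self, tiny_matrix):
        fm, ph = tiny_matrix
        corr = spearman_age_correlation(fm, ph, min_samples=5)
        assert corr.r_of("up") == pytest.approx(1.0)
        assert corr.r_of("down") == pytest.approx(-1.0)

    def test_hand_computed_triplet(self):
        # values (3,1,2) vs ages (10,20,30): ranks (3,1,2) vs (1,2,3) -> r = -0.5
        assert spearman_pair(np.array([3.0, 1.0, 2.0]), np.array([10.0, 20.0, 30.0])) == pytest.approx(-0.5)

    def test_zero_variance_flagged(self, tiny_matrix):
        fm, ph = tiny_matrix
        corr = spearman_age_correlation(fm, ph, min_samples=5)
        assert corr.table.loc["flat", "flag"] == "zero_variance"
        assert math.isnan(corr.table.loc["flat", "r"])
        assert "flat" not in corr.scored().index

    def test_alignment_by_id_not_order(self, tiny_matrix):
        fm, ph = tiny_matrix
        shuffled = Phenotype(ph.sample_ids[::-1], ph.age[::-1])
        a = spearman_age_correlation(fm, ph, min_samples=5).table["r"]
        b = spearman_age_correlation(fm, shuffled, min_samples=5).table["r"]
        pd.testing.assert_series_equal(a, b)

    def test_pairwise_complete_missing_values(self):
        ages = np.arange(1.0, 13.0)
        x = ages.copy()
        x[3] = np.nan
        fm = _matrix({"g": list(x)})
        ph = Phenotype([f"S{i}" for i in range(12)], ages)
        corr = spearman_age_correlation(fm, ph)
        assert corr.table.loc["g", "n_used"] == 11
        assert corr.r_of("g") == pytest.approx(1.0)

    def test_too_few_shared_samples_rejected(self):
        fm = _matrix({"g": [1.0, 2.0, 3.0]})
        ph = Phenotype(["S0", "S1", "S2"], [1.0, 2.0, 3.0])
        with pytest.raises(InputError):
            spearman_age_correlation(fm, ph)

    def test_matches_rank_pearson_oracle_with_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(4, 30)
            x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            y = rng.integers(0, 6, size=n).astype(float)
            expected = spearman_oracle(x, y)
            got = spearman_pair(x, y)
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)


class TestFisherTransform:
    def test_closed_form(self):
        assert fisher_transform(0.0) == 0.0
        assert fisher_transform(0.5) == pytest.approx(0.5 * math.log(3), abs=1e-12)

    def test_boundary(self):
        assert np.isfinite(fisher_transform(0.99999))
        with pytest.raises(ValueError):
            fisher_transform(1.0)

    def test_strictly_increasing(self):
        rs = np.linspace(-0.999, 0.999, 101)
        zs = fisher_transform(rs)
        assert np.all(np.diff(zs) > 0)


class TestCalibration:
    def test_exhaustive_three_sample_null(self):
        # feature == ages, n=3: the 6 permutations give r in {1, .5, .5, -.5, -.5, -1}
        ages = np.array([10.0, 20.0, 30.0])
        fm = _matrix({"g": list(ages)}, sids=["a", "b", "c"])
        ph = Phenotype(["a", "b", "c"], ages)
        cal = calibrate_cutoff(fm, ph, coverage=1.0, exhaustive=True)
        assert cal.n_iter == 6
        ext = np.maximum(np.abs(cal.extremes[:, 0]), np.abs(cal.extremes[:, 1]))
        assert sorted(np.round(ext, 12)) == [0.5, 0.5, 0.5, 0.5, 1.0, 1.0]
        assert cal.cutoff_c == pytest.approx(1.0)

    def test_constant_age_rejected(self):
        fm = _matrix({"g": list(np.arange(10.0))})
        ph = Phenotype([f"S{i}" for i in range(10)], np.full(10, 50.0))
        with pytest.raises(InputError):
            spearman_age_correlation(fm, ph)
        with pytest.raises(Exception):
            calibrate_cutoff(fm, ph, seed=1)

    def test_coverage_validation(self):
        fm = _matrix({"g": list(np.arange(12.0))})
        ph = Phenotype([f"S{i}" for i in range(12)], np.arange(12.0))
        with pytest.raises(ConfigError):
            calibrate_cutoff(fm, ph, coverage=1.5, seed=1)
        with pytest.raises(ConfigError):
            calibrate_cutoff(fm, ph, coverage=0.95)  # seed required

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        fm = _matrix({f"g{i}": list(rng.normal(size=20)) for i in range(15)})
        ph = Phenotype([f"S{i}" for i in range(20)], rng.uniform(15, 101, 20))
        a = calibrate_cutoff(fm, ph, n_iter=150, seed=7)
        b = calibrate_cutoff(fm, ph, n_iter=150, seed=7)
        assert a.cutoff_c == b.cutoff_c
        np.testing.assert_array_equal(a.extremes, b.extremes)

    def test_rank_invariance(self):
        # Spearman depends only on ranks: calibrating on rank-transformed data
        # with the same seed gives the same cutoff
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(10, 25))
        sids = [f"S{i}" for i in range(25)]
        fm_raw = FeatureMatrix(pd.DataFrame(vals, index=[f"g{i}" for i in range(10)], columns=sids))
        from scipy.stats import rankdata

        fm_rank = FeatureMatrix(
            pd.DataFrame(rankdata(vals, axis=1), index=[f"g{i}" for i in range(10)], columns=sids)
        )
        ph = Phenotype(sids, rng.uniform(15, 101, 25))
        a = calibrate_cutoff(fm_raw, ph, n_iter=120, seed=9)
        b = calibrate_cutoff(fm_rank, ph, n_iter=120, seed=9)
        np.testing.assert_allclose(a.extremes, b.extremes, atol=1e-12)

    def test_cutoff_shrinks_with_sample_size(self):
        # larger cohorts admit tighter thresholds
        cutoffs = []
        for n in (50, 150, 300):
            vals = np.random.default_rng(11).normal(size=(100, n))
            sids = [f"S{i}" for i in range(n)]
            fm = FeatureMatrix(pd.DataFrame(vals, index=[f"g{i}" for i in range(100)], columns=sids))
            ph = Phenotype(sids, np.random.default_rng(12).uniform(15, 101, n))
            cs = [
                calibrate_cutoff(fm, ph, n_iter=150, seed=s).cutoff_c
                for s in (1, 2, 3)
            ]
            cutoffs.append(np.mean(cs))
        assert cutoffs[0] > cutoffs[1] > cutoffs[2]

    def test_pooled_mode_not_larger_than_extreme_mode(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(50, 40))
        sids = [f"S{i}" for i in range(40)]
        fm = FeatureMatrix(pd.DataFrame(vals, index=[f"g{i}" for i in range(50)], columns=sids))
        ph = Phenotype(sids, rng.uniform(15, 101, 40))
        ext = calibrate_cutoff(fm, ph, n_iter=150, seed=2)
        pooled = calibrate_cutoff(fm, ph, n_iter=150, seed=2, pooled=True)
        # the pooled 95%-quantile is over all correlations, the extreme-pair
        # quantile over per-iteration maxima, so the latter dominates
        assert pooled.cutoff_c <= ext.cutoff_c

    def test_p_cutoff_in_unit_interval(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(30, 30))
        sids = [f"S{i}" for i in range(30)]
        fm = FeatureMatrix(pd.DataFrame(vals, index=[f"g{i}" for i in range(30)], columns=sids))
        ph = Phenotype(sids, rng.uniform(15, 101, 30))
        cal = calibrate_cutoff(fm, ph, n_iter=200, seed=4)
        assert 0 <= cal.p_cutoff <= 1
        assert 0 < cal.cutoff_c <= 1


class TestScreening:
    def _corr(self, rs: dict[str, float]) -> CorrelationTable:
        df = pd.DataFrame(
            {"r": pd.Series(rs), "n_used": 50, "flag": ""},
        )
        df.index.name = "feature_id"
        return CorrelationTable(df)

    def test_strict_inequality_at_cutoff(self):
        corr = self._corr({"a": 0.31, "b": 0.30, "c": -0.31, "d": -0.30})
        sel = screen_features(corr, 0.3)
        assert sel.positive == {"a"}
        assert sel.negative == {"c"}

    def test_flagged_never_selected(self):
        df = pd.DataFrame({"r": [np.nan], "n_used": [3], "flag": ["too_few_samples"]}, index=["x"])
        sel = screen_features(CorrelationTable(df), 0.3)
        assert sel.positive == set() and sel.negative == set()

    @given(
        st.dictionaries(
            st.text(alphabet="abcdef", min_size=1, max_size=3),
            st.floats(min_value=-1.0, max_value=1.0),
            min_size=1,
            max_size=20,
        ),
        st.floats(min_value=0.05, max_value=0.9),
        st.floats(min_value=0.05, max_value=0.9),
    )
    def test_nesting_in_cutoff(self, rs, c1, c2):
        lo, hi = sorted((c1, c2))
        corr = self._corr(rs)
        s_lo, s_hi = screen_features(corr, lo), screen_features(corr, hi)
        assert s_hi.positive <= s_lo.positive
        assert s_hi.negative <= s_lo.negative


def test_cutoff_from_extremes_is_order_statistic():
    ext = np.array([[-0.1, 0.2], [-0.5, 0.3], [-0.2, 0.4], [-0.3, 0.1]])
    # magnitudes: 0.2, 0.5, 0.4, 0.3 -> 75% coverage needs the 3rd smallest
    assert cutoff_from_extremes(ext, 0.75) == pytest.approx(0.4)
    assert cutoff_from_extremes(ext, 1.0) == pytest.approx(0.5)


def test_null_exceedance_matches_coverage():
    rng = np.random.default_rng(21)
    n, n_feat = 80, 300
    sids = [f"S{i}" for i in range(n)]
    fm = FeatureMatrix(pd.DataFrame(rng.normal(size=(n_feat, n)), index=[f"g{i}" for i in range(n_feat)], columns=sids))
    ph = Phenotype(sids, rng.uniform(15, 101, n))
    cal = calibrate_cutoff(fm, ph, n_iter=400, coverage=0.95, seed=31)
    rate = null_exceedance_rate(fm, ph, cal.cutoff_c, n_iter=400, seed=99)
    assert rate == pytest.approx(0.05, abs=0.04)
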