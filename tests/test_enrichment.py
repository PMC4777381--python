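import numpy as np
import pandas as pd
import pytest
from fractions import Fraction
from scipy.stats import fisher_exact

from agescreen import (
    ConfigError,
    CorrelationTable,
    GeneSet,
    GeneSetCollection,
    InputError,
    IntervalTable,
    binding_site_coverage,
    enrich_collection,
    fisher_enrichment,
    fisher_pvalue,
    predict_tfs_per_region,
    rank_and_select_top,
    target_coverage_filter,
    tf_age_profile_check,
    tf_consensus,
)
from oracles import fisher_greater_oracle


class TestFisherEngine:
    def test_paper_mode_hand_enumerated(self):
        # margins (3, 10) x (5, 8) on the inflated 13-gene population
        assert fisher_pvalue(2, 3, 5, 10, "paper") == pytest.approx(90 / 286, abs=1e-12)

    def test_standard_mode_hand_enumerated(self):
        # margins (3, 7) x (5, 5) on the true 10-gene universe
        assert fisher_pvalue(2, 3, 5, 10, "standard") == pytest.approx(0.5, abs=1e-12)

    def test_zero_hits_gives_p_one(self):
        assert fisher_pvalue(0, 3, 5, 10, "paper") == pytest.approx(1.0)
        assert fisher_pvalue(0, 3, 5, 10, "standard") == pytest.approx(1.0)

    def test_matches_r_style_fisher_test_on_the_built_table(self):
        # cross-check against the generic conditional-exact test applied to
        # the literal 2x2 each mode constructs
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            k = int(rng.integers(1, n + 1))
            p = int(rng.integers(1, n + 1))
            x = int(rng.integers(0, min(k, p) + 1))
            table_paper = [[x, k - x], [p - x, n - k]]
            assert fisher_pvalue(x, k, p, n, "paper") == pytest.approx(
                fisher_exact(table_paper, alternative="greater")[1], abs=1e-9
            )
            if n - k - (p - x) >= 0:
                table_std = [[x, k - x], [p - x, n - k - (p - x)]]
                assert fisher_pvalue(x, k, p, n, "standard") == pytest.approx(
                    fisher_exact(table_std, alternative="greater")[1], abs=1e-9
                )

    def test_modes_agree_at_zero_overlap_and_diverge_otherwise(self):
        assert fisher_pvalue(0, 4, 6, 20, "paper") == fisher_pvalue(0, 4, 6, 20, "standard")
        # a regression guard against silently swapping constructions
        assert fisher_pvalue(3, 4, 6, 20, "paper") != pytest.approx(
            fisher_pvalue(3, 4, 6, 20, "standard"), abs=1e-6
        )

    def test_p_nonincreasing_in_x(self):
        for mode in ("paper", "standard"):
            ps = [fisher_pvalue(x, 8, 10, 40, mode) for x in range(0, 9)]
            assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_standard_mode_negative_cell_rejected(self):
        with pytest.raises(InputError):
            fisher_pvalue(0, 6, 6, 10, "standard")

    def test_exact_oracle_spot_checks(self):
        for (x, k, p, n) in [(1, 5, 5, 12), (4, 6, 9, 15), (2, 2, 2, 4)]:
            for mode in ("paper", "standard"):
                if mode == "standard" and n - k - (p - x) < 0:
                    continue
                oracle = float(fisher_greater_oracle(x, k, p, n, mode))
                assert fisher_pvalue(x, k, p, n, mode) == pytest.approx(oracle, abs=1e-12)


class TestEnrichmentOp:
    def test_counts_from_gene_sets(self):
        res = fisher_enrichment({"a", "b", "c"}, {"a", "b", "d", "e", "f"}, 10)
        assert (res.x, res.k, res.p, res.n) == (2, 3, 5, 10)
        assert res.p_value == pytest.approx(90 / 286, abs=1e-12)
        assert res.coverage_fraction == pytest.approx(2 / 3)

    def test_inputs_outside_explicit_universe_dropped(self):
        universe = {f"g{i}" for i in range(10)}
        res = fisher_enrichment({"g1", "g2", "alien"}, {"g1"}, universe)
        assert res.k == 2 and res.x == 1

    def test_collection_sorted_by_p(self):
        coll = GeneSetCollection(
            {"hit": GeneSet("", ("a", "b", "c")), "miss": GeneSet("", ("x", "y", "z"))}
        )
        df = enrich_collection({"a", "b", "c"}, coll, 30)
        assert list(df["set_id"]) == ["hit", "miss"]
        assert df["p_value"].iloc[0] < df["p_value"].iloc[1]


class TestTopRanking:
    def _corr(self, rs):
        df = pd.DataFrame({"r": pd.Series(rs), "n_used": 50, "flag": ""})
        df.index.name = "feature_id"
        return CorrelationTable(df)

    def test_truncates_at_limit_by_abs_r(self):
        rng = np.random.default_rng(1)
        rs = {f"g{i:03d}": float(r) for i, r in enumerate(rng.uniform(-1, 1, 300))}
        corr = self._corr(rs)
        top = rank_and_select_top(list(rs), corr, limit=200)
        assert len(top) == 200
        kept = min(abs(rs[g]) for g in top)
        dropped = max(abs(rs[g]) for g in set(rs) - set(top))
        assert kept >= dropped

    def test_small_input_returned_whole(self):
        rs = {f"g{i}": 0.5 for i in range(150)}
        assert len(rank_and_select_top(list(rs), self._corr(rs), 200)) == 150

    def test_tie_at_cut_kept_lexicographically(self):
        rs = {"aa": 0.9, "ab": 0.5, "ba": -0.5, "zz": 0.2}
        top = rank_and_select_top(list(rs), self._corr(rs), limit=2)
        assert top == ["aa", "ab"]  # 'ab' beats 'ba' at |r|=0.5


class TestTfPrediction:
    def _setup(self):
        tf_sets = GeneSetCollection(
            {
                "TFA": GeneSet("", tuple(f"g{i}" for i in range(10))),
                "TFB": GeneSet("", tuple(f"h{i}" for i in range(10))),
            }
        )
        inputs = [f"g{i}" for i in range(8)] + ["h0"]
        return tf_sets, inputs

    def test_alpha_one_reports_all_and_alpha_zero_none(self):
        tf_sets, inputs = self._setup()
        assert len(predict_tfs_per_region(inputs, tf_sets, 100, alpha=1.0)) == 2
        assert len(predict_tfs_per_region(inputs, tf_sets, 100, alpha=0.0)) == 0

    def test_true_regulator_ranks_first(self):
        tf_sets, inputs = self._setup()
        df = predict_tfs_per_region(inputs, tf_sets, 100, alpha=0.05)
        assert df["tf"].iloc[0] == "TFA"

    def test_consensus_requires_min_regions(self):
        tf_sets, inputs = self._setup()
        hit = predict_tfs_per_region(inputs, tf_sets, 100, alpha=0.05)
        empty = hit.iloc[0:0]
        per_region = {"r1": hit, "r2": hit, "r3": hit, "r4": empty}
        assert tf_consensus(per_region, min_regions=3) == ["TFA"]
        per_region = {"r1": hit, "r2": hit, "r3": empty, "r4": empty}
        assert tf_consensus(per_region, min_regions=3) == []

    def test_empty_input_rejected(self):
        tf_sets, _ = self._setup()
        with pytest.raises(InputError):
            predict_tfs_per_region([], tf_sets, 100)


class TestCoverageFilter:
    coll = GeneSetCollection({"TF": GeneSet("", tuple(f"g{i}" for i in range(60)))})

    def test_sixty_percent_passes(self):
        inputs = [f"g{i}" for i in range(60)] + [f"x{i}" for i in range(40)]
        frac, ok = target_coverage_filter("TF", inputs, self.coll)
        assert frac == pytest.approx(0.6) and ok

    def test_exactly_half_fails_strict_threshold(self):
        inputs = [f"g{i}" for i in range(50)] + [f"x{i}" for i in range(50)]
        frac, ok = target_coverage_filter("TF", inputs, self.coll)
        assert frac == pytest.approx(0.5) and not ok

    def test_full_coverage(self):
        frac, ok = target_coverage_filter("TF", [f"g{i}" for i in range(10)], self.coll)
        assert frac == 1.0 and ok


class TestTfAgeProfile:
    def _tables(self, rs):
        out = []
        for j in range(4):
            df = pd.DataFrame({"r": {tf: v[j] for tf, v in rs.items()}, "n_used": 100, "flag": ""})
            df.index.name = "feature_id"
            out.append(CorrelationTable(df, region=f"R{j + 1}"))
        return out

    def test_published_tf_profiles(self):
        # per-region correlations as printed for SP1 / EGR1 / ESR1
        rs = {
            "SP1": [0.40, 0.39, 0.39, 0.39],
            "EGR1": [-0.57, -0.45, -0.57, -0.41],
            "ESR1": [-0.14, 0.02, -0.13, 0.001],
        }
        df = tf_age_profile_check(list(rs), self._tables(rs), cutoff=0.3, min_regions=3)
        out = df.set_index("tf")
        assert out.loc["SP1", "age_correlated"] and out.loc["SP1", "direction"] == "pos"
        assert out.loc["EGR1", "age_correlated"] and out.loc["EGR1", "direction"] == "neg"
        assert not out.loc["ESR1", "age_correlated"]

    def test_absent_tf_flagged_unknown(self):
        df = tf_age_profile_check(["ghost"], self._tables({"SP1": [0.4] * 4}), 0.3)
        assert df.set_index("tf").loc["ghost", "direction"] == "unknown"


class TestBindingSiteCoverage:
    def _genome(self):
        tss = IntervalTable(
            pd.DataFrame(
                [("chr1", 10_000 * (i + 1), 10_000 * (i + 1) + 1, f"g{i}", "+") for i in range(20)],
                columns=["chrom", "start", "end", "name", "strand"],
            )
        )
        return tss

    def test_all_promoters_hit_gives_one(self):
        tss = self._genome()
        sites = IntervalTable(
            pd.DataFrame(
                [("chr1", 10_000 * (i + 1) + 100, 10_000 * (i + 1) + 110, f"s{i}", ".") for i in range(20)],
                columns=["chrom", "start", "end", "name", "strand"],
            )
        )
        cov = binding_site_coverage([f"g{i}" for i in range(5)], sites, tss, seed=1, n_random=50)
        assert cov.observed_fraction == 1.0

    def test_sites_on_missing_chromosome_give_zero(self):
        tss = self._genome()
        sites = IntervalTable(
            pd.DataFrame([("chrX", 100, 110, "s", ".")], columns=["chrom", "start", "end", "name", "strand"])
        )
        cov = binding_site_coverage([f"g{i}" for i in range(5)], sites, tss, seed=1, n_random=20)
        assert cov.observed_fraction == 0.0

    def test_random_fraction_tracks_universe_rate(self):
        tss = self._genome()
        # sites in the promoters of exactly half the universe
        sites = IntervalTable(
            pd.DataFrame(
                [("chr1", 10_000 * (i + 1) + 100, 10_000 * (i + 1) + 110, f"s{i}", ".") for i in range(0, 20, 2)],
                columns=["chrom", "start", "end", "name", "strand"],
            )
        )
        cov = binding_site_coverage([f"g{i}" for i in range(4)], sites, tss, seed=3, n_random=400)
        assert cov.random_fraction == pytest.approx(0.5, abs=0.05)
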