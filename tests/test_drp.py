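"""DRP identification, the permutation association test, and enrichment."""

import numpy as np
import pytest
from scipy import stats

from gpspbs.drp import (
    SiteAnnotationTable,
    associate_all,
    hypergeometric_enrichment,
    identify_drps,
    permutation_test,
)


def toy_table():
    universe = [f"s{i}" for i in range(20)]
    return SiteAnnotationTable(
        universe,
        ppbd_sets={"14-3-3": set(universe[:5]), "SH2": set(universe[10:14])},
        pk_sets={"AKT": set(universe[:8]), "CDK": set(universe[15:])})


class TestIdentifyDrps:
    def test_intersection(self):
        t = toy_table()
        assert identify_drps(t, "14-3-3", "AKT") == {f"s{i}" for i in range(5)}

    def test_disjoint_sets(self):
        assert identify_drps(toy_table(), "SH2", "CDK") == set()

    def test_subset_case(self):
        t = toy_table()  # 14-3-3 sites are all AKT substrates
        assert identify_drps(t, "14-3-3", "AKT") == t.ppbd_sets["14-3-3"]

    def test_unknown_family(self):
        with pytest.raises(KeyError):
            identify_drps(toy_table(), "WW", "AKT")

    def test_brute_force_membership(self):
        t = toy_table()
        expected = {s for s in t.universe
                    if s in t.ppbd_sets["14-3-3"] and s in t.pk_sets["AKT"]}
        assert identify_drps(t, "14-3-3", "AKT") == expected


class TestPermutationTest:
    def test_null_is_hypergeometric(self):
        """With T=20, m_K=5, n_L=8 and full overlap x=5, the empirical
        p-value converges to the exact hypergeometric tail P(X >= 5)."""
        t = toy_table()
        exact = float(stats.hypergeom.sf(4, 20, 5, 8))  # ~0.00361
        res = permutation_test(t, "14-3-3", "AKT", rounds=10_000, seed=3)
        se = np.sqrt(exact * (1 - exact) / 10_000)
        assert res.observed == 5
        assert abs(res.p_value - exact) <= 3 * se + 1 / 10_001

    def test_null_mean_matches_expectation(self):
        t = toy_table()
        res = permutation_test(t, "14-3-3", "AKT", rounds=5_000, seed=1)
        expected_mean = 5 * 8 / 20
        se = res.null_sd / np.sqrt(res.rounds)
        assert abs(res.null_mean - expected_mean) <= 3 * se

    def test_degenerate_full_coverage(self):
        universe = [f"s{i}" for i in range(10)]
        t = SiteAnnotationTable(universe, {"K": set(universe)},
                                {"L": set(universe[:4])})
        res = permutation_test(t, "K", "L", rounds=500, seed=0)
        assert res.p_value == 1.0  # x' == n_L every round

    def test_empirical_p_never_zero(self):
        universe = [f"s{i}" for i in range(30)]
        t = SiteAnnotationTable(universe, {"K": set(universe[:15])},
                                {"L": set(universe[:15])})
        res = permutation_test(t, "K", "L", rounds=200, seed=0)
        assert res.p_value > 0

    def test_gaussian_mode_agrees_when_null_is_symmetric(self):
        # moderate overlap (x=12, expectation 10) keeps the p-value well
        # inside the resolution of the empirical estimate
        universe = [f"s{i}" for i in range(40)]
        t = SiteAnnotationTable(
            universe, {"K": set(universe[:20])},
            {"L": set(universe[:12]) | set(universe[25:33])})
        emp = permutation_test(t, "K", "L", rounds=4_000, seed=2)
        gau = permutation_test(t, "K", "L", rounds=4_000, seed=2,
                               mode="gaussian")
        assert abs(gau.null_skew) < 0.5
        assert 0.5 <= emp.p_value / gau.p_value <= 2.0

    def test_relabeling_invariance(self):
        t1 = toy_table()
        relabel = {f"s{i}": f"site_{i:03d}" for i in range(20)}
        t2 = SiteAnnotationTable(
            [relabel[s] for s in t1.universe],
            {k: {relabel[s] for s in v} for k, v in t1.ppbd_sets.items()},
            {k: {relabel[s] for s in v} for k, v in t1.pk_sets.items()})
        a = permutation_test(t1, "14-3-3", "AKT", rounds=2_000, seed=7)
        b = permutation_test(t2, "14-3-3", "AKT", rounds=2_000, seed=7)
        assert a.p_value == b.p_value

    def test_oversized_pk_set_rejected(self):
        universe = ["a", "b"]
        with pytest.raises(ValueError):
            SiteAnnotationTable(universe, {"K": {"a"}}, {"L": {"a", "b", "c"}})

    def test_grid_with_bonferroni(self):
        df = associate_all(toy_table(), rounds=500, seed=0)
        assert len(df) == 4  # 2 PPBD x 2 PK families
        assert (df["p_adjusted"] >= df["p_value"]).all()


class TestEnrichment:
    def test_tail_sum_oracle(self):
        background = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(10)}
        foreground = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
        df = hypergeometric_enrichment(foreground, background, {"T": term})
        from math import comb

        expected = sum(comb(10, k) * comb(90, 10 - k) for k in range(5, 11)) \
            / comb(100, 10)
        assert df.loc[0, "p_value"] == pytest.approx(expected)
        assert df.loc[0, "overlap"] == 5

    def test_no_enrichment_when_rates_match(self):
        background = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(0, 100, 10)}  # 10% of background
        foreground = {f"g{i}" for i in range(0, 50)}  # contains 5 term genes
        df = hypergeometric_enrichment(foreground, background, {"T": term})
        assert df.loc[0, "fold_enrichment"] == pytest.approx(1.0)
        assert df.loc[0, "p_value"] >= 0.5

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(set(), {"a"}, {})

    def test_foreground_outside_background_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment({"x"}, {"a"}, {})
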