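"""Homolog assignment, arm expected/observed ratios, rank-sum test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from whitemap.synteny import (
    arm_ratio_test,
    assign_arms,
    assign_homologs,
    filter_mappings,
    load_arms,
    ranksum,
)
from whitemap.synthetic_cross import simulate_arm_hits


def records(rows):
    return pd.DataFrame(rows, columns=["marker", "chrom", "pos", "mapq"])


def two_arm_table():
    return pd.DataFrame(
        {
            "arm": ["c1a", "c1b"],
            "chrom": ["c1", "c1"],
            "start": [0, 100],
            "end": [100, 400],
            "class": ["AORe", "LORe"],
        }
    )


@pytest.fixture(scope="module")
def arms():
    return load_arms()


class TestArmTable:
    def test_packaged_class_counts(self, arms):
        counts = arms["class"].value_counts().to_dict()
        assert counts == {"AORe": 30, "LORe": 14, "mixed": 6}

    def test_named_lore_and_mixed_arms_present(self, arms):
        lore = set(arms.loc[arms["class"] == "LORe", "arm"])
        assert {"Ssa2p", "Ssa5q", "Ssa8q", "Ssa17qa", "Ssa17qb", "Ssa26"} <= lore
        mixed = set(arms.loc[arms["class"] == "mixed", "arm"])
        assert mixed == {"Ssa3p", "Ssa5p", "Ssa9qb", "Ssa13qa", "Ssa15qb", "Ssa23"}


class TestFiltering:
    def test_mapq_boundary_strict(self):
        recs = records([("m1", "c1", 10, 30), ("m2", "c1", 20, 31)])
        out = filter_mappings(recs, min_mapq=30)
        assert list(out["marker"]) == ["m2"]

    def test_markers_absent_from_map_dropped(self):
        recs = records([("m1", "c1", 10, 60), ("mX", "c1", 20, 60)])
        map_table = pd.DataFrame({"marker": ["m1"], "group": ["LG01"]})
        out = filter_mappings(recs, map_table)
        assert list(out["marker"]) == ["m1"]


class TestHomologs:
    def map_table(self, markers, group="LG01"):
        return pd.DataFrame({"marker": markers, "group": group})

    def test_majority_with_discordant_minority(self):
        # 18 hits to one chromosome, 16 to another: majority wins
        rows = [(f"m{i}", "Ssa01", 1000 * i, 60) for i in range(18)]
        rows += [(f"m{i}", "Ssa19", 1000 * i, 60) for i in range(18, 34)]
        asg, hits = assign_homologs(self.map_table([r[0] for r in rows]), records(rows))
        row = asg.iloc[0]
        assert row["homolog"] == "Ssa01"
        assert row["n_support"] == 18 and row["n_discordant"] == 16
        assert (~hits["concordant"]).sum() == 16

    def test_single_chrom_no_discordance(self):
        rows = [(f"m{i}", "Ssa05", i, 60) for i in range(5)]
        asg, _ = assign_homologs(self.map_table([r[0] for r in rows]), records(rows))
        assert asg.iloc[0]["homolog"] == "Ssa05" and asg.iloc[0]["n_discordant"] == 0

    def test_tie_breaks_to_lower_chromosome_with_flag(self, caplog):
        rows = [(f"m{i}", "Ssa07", i, 60) for i in range(7)]
        rows += [(f"n{i}", "Ssa03", i, 60) for i in range(7)]
        asg, _ = assign_homologs(self.map_table([r[0] for r in rows]), records(rows))
        assert asg.iloc[0]["homolog"] == "Ssa03"
        assert bool(asg.iloc[0]["ambiguous"])

    def test_w_names_follow_reference_order(self):
        mt = pd.DataFrame({"marker": ["a1", "a2", "b1", "b2"],
                           "group": ["LG01", "LG01", "LG02", "LG02"]})
        rows = [("a1", "Ssa09", 5, 60), ("a2", "Ssa09", 6, 60),
                ("b1", "Ssa02", 1, 60), ("b2", "Ssa02", 2, 60)]
        asg, _ = assign_homologs(mt, records(rows))
        w = asg.set_index("group")["w_name"]
        assert w["LG02"] == "W01" and w["LG01"] == "W02"

    def test_group_without_hits_gets_no_w_name(self):
        mt = pd.DataFrame({"marker": ["a1", "b1"], "group": ["LG01", "LG02"]})
        asg, _ = assign_homologs(mt, records([("a1", "Ssa01", 5, 60)]))
        row = asg.set_index("group").loc["LG02"]
        assert pd.isna(row["homolog"]) and pd.isna(row["w_name"])


class TestArmAssignment:
    def test_half_open_intervals(self):
        arms = two_arm_table()
        recs = records([("m0", "c1", 0, 60), ("m1", "c1", 99, 60),
                        ("m2", "c1", 100, 60), ("m3", "c1", 399, 60),
                        ("m4", "c1", 400, 60)])
        out = assign_arms(recs, arms)
        assert list(out["arm"][:4]) == ["c1a", "c1a", "c1b", "c1b"]
        assert pd.isna(out["arm"].iloc[4])


class TestArmRatios:
    def test_proportional_hits_give_unit_ratios(self):
        arms = two_arm_table()
        rows = [(f"m{i}", "c1", 50, 60) for i in range(10)]          # arm c1a
        rows += [(f"n{i}", "c1", 200, 60) for i in range(30)]        # arm c1b
        res = arm_ratio_test(records(rows), arms)
        stats_by_arm = res.arm_stats.set_index("arm")
        assert stats_by_arm.loc["c1a", "expected"] == pytest.approx(10)
        assert stats_by_arm.loc["c1b", "expected"] == pytest.approx(30)
        assert np.allclose(stats_by_arm["ratio"], 1.0)

    def test_zero_observed_arm_gets_na_ratio(self):
        arms = two_arm_table()
        rows = [(f"m{i}", "c1", 50, 60) for i in range(10)]
        res = arm_ratio_test(records(rows), arms)
        assert np.isnan(res.arm_stats.set_index("arm").loc["c1b", "ratio"])
        assert res.method == "skipped"  # LORe side has no defined ratio

    def test_expected_counts_conserve_total(self, arms):
        hits = simulate_arm_hits(arms, 900, lore_rate=0.5, seed=4)
        res = arm_ratio_test(hits, arms)
        assert res.arm_stats["expected"].sum() == pytest.approx(res.n_total)
        assert res.arm_stats["observed"].sum() == res.n_total

    def test_mixed_arms_excluded_everywhere(self, arms):
        hits = simulate_arm_hits(arms, 500, seed=5)
        res = arm_ratio_test(hits, arms)
        assert not (res.arm_stats["class"] == "mixed").any()

    def test_ratio_invariant_to_length_rescaling(self, arms):
        hits = simulate_arm_hits(arms, 600, seed=6)
        res1 = arm_ratio_test(hits, arms)
        arms2 = arms.copy()
        arms2["start"] = arms2["start"] * 3
        arms2["end"] = arms2["end"] * 3
        hits2 = hits.copy()
        hits2["pos"] = hits2["pos"] * 3
        res2 = arm_ratio_test(hits2, arms2)
        a = res1.arm_stats.set_index("arm")["ratio"]
        b = res2.arm_stats.set_index("arm")["ratio"]
        pd.testing.assert_series_equal(a, b)


def enumeration_pvalue(x, y):
    """Independent brute-force two-sided rank-sum p over all assignments."""
    combined = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(xi > yj for xi in x for yj in y)
    us = []
    for subset in itertools.combinations(range(len(combined)), n1):
        xs = combined[list(subset)]
        ys = np.delete(combined, list(subset))
        us.append(sum(a > b for a in xs for b in ys))
    us = np.array(us)
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


class TestRankSum:
    def test_exact_complete_separation_three_vs_three(self):
        res = ranksum([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert res.statistic == 0.0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.10)

    def test_exact_matches_enumeration_on_random_inputs(self):
        rng = np.random.default_rng(1)
        for n1, n2 in [(2, 3), (4, 4), (3, 6), (5, 5)]:
            x = rng.normal(size=n1)
            y = rng.normal(0.8, size=n2)
            res = ranksum(x, y)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(enumeration_pvalue(x, y), abs=1e-12)

    def test_normal_approximation_matches_scipy(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=25)
        y = rng.normal(0.5, size=30)
        res = ranksum(x, y)
        ref = sstats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.method == "normal"
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_side_skipped(self):
        assert ranksum([], [1.0]).method == "skipped"


def test_lore_depletion_yields_extreme_statistic(arms=None):
    """Hits drawn with LORe arms at 20% of their length-proportional rate:
    every LORe expected/observed ratio exceeds every AORe ratio, so the
    rank-sum statistic sits at its extreme (W = 0 orientation)."""
    arms = load_arms()
    hits = simulate_arm_hits(arms, 5000, lore_rate=0.2, seed=7)
    res = arm_ratio_test(hits, arms)
    assert res.statistic == 0.0
    assert res.p_value < 1e-6
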