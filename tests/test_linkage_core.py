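"""Two-point estimation, EM, grouping, ordering and map positions."""

import numpy as np
import pandas as pd
import pytest

from whitemap import (
    SegType,
    SimConfig,
    classify_segregation,
    haldane_r,
    pairwise_all,
    pairwise_rf_lod,
    separate_groups,
    simulate_cross,
)
from whitemap.core import GenotypeMatrix, HET, HOM_ALT, HOM_REF
from whitemap.linkage_core import (
    OrderingError,
    PairwiseEstimates,
    build_genetic_map,
    em_rf_lod,
    map_positions,
    order_exhaustive,
    order_markers,
    ordering_matrix,
    sarf,
)
from whitemap.synthetic_cross import TrueMap, simulate_offspring_genotypes


def mat_inf_pair(n, k):
    """Two mother-informative markers with exactly k recombinant meioses."""
    t1 = np.zeros(n, dtype=np.int8)
    t2 = np.zeros(n, dtype=np.int8)
    t2[:k] = 1
    return GenotypeMatrix(
        marker_ids=np.array(["A", "B"], dtype=object),
        rad_locus=np.array(["LA", "LB"], dtype=object),
        mother=np.array([HET, HET], dtype=np.int8),
        father=np.array([HOM_REF, HOM_REF], dtype=np.int8),
        offspring=np.vstack([t1, t2]),
    )


class TestTwoPointLOD:
    @pytest.mark.parametrize(
        "n, k, rf, lod",
        [
            (156, 0, 0.0, 46.96),      # no recombinants: LOD = n log10 2
            (156, 78, 0.5, 0.0),       # free recombination
            (100, 10, 0.1, 15.98),     # 10 log10(0.2) + 90 log10(1.8)
        ],
    )
    def test_counting_estimates(self, n, k, rf, lod):
        mat = mat_inf_pair(n, k)
        calls = classify_segregation(mat)
        est = pairwise_rf_lod(mat, calls, ("A", "B"), context="maternal")
        assert est.rf == pytest.approx(rf, abs=1e-9)
        assert est.lod == pytest.approx(lod, abs=0.01)
        assert est.n_meioses == n

    def test_symmetric_in_marker_order(self):
        mat = mat_inf_pair(120, 17)
        calls = classify_segregation(mat)
        ab = pairwise_rf_lod(mat, calls, ("A", "B"), "maternal")
        ba = pairwise_rf_lod(mat, calls, ("B", "A"), "maternal")
        assert ab.rf == ba.rf and ab.lod == ba.lod

    def test_invariant_to_allele_relabeling(self):
        mat = mat_inf_pair(120, 17)
        flipped = GenotypeMatrix(
            marker_ids=mat.marker_ids.copy(),
            rad_locus=mat.rad_locus.copy(),
            mother=mat.mother.copy(),
            father=np.array([HOM_REF, HOM_ALT], dtype=np.int8),
            offspring=np.vstack([mat.offspring[0], 2 - mat.offspring[1]]),
        )
        a = pairwise_rf_lod(mat, classify_segregation(mat), ("A", "B"), "maternal")
        b = pairwise_rf_lod(flipped, classify_segregation(flipped), ("A", "B"), "maternal")
        assert a.rf == pytest.approx(b.rf) and a.lod == pytest.approx(b.lod)

    def test_no_shared_meioses_returns_none(self):
        # mother-informative x father-informative: nothing to estimate
        mat = GenotypeMatrix(
            marker_ids=np.array(["A", "B"], dtype=object),
            rad_locus=np.array(["LA", "LB"], dtype=object),
            mother=np.array([HET, HOM_REF], dtype=np.int8),
            father=np.array([HOM_REF, HET], dtype=np.int8),
            offspring=np.vstack([np.zeros(50, dtype=np.int8), np.ones(50, dtype=np.int8)]),
        )
        calls = classify_segregation(mat)
        assert pairwise_rf_lod(mat, calls, ("A", "B"), "maternal") is None


class TestEM:
    @staticmethod
    def sim_both_pair(r, n, phase_m, phase_f, seed):
        rng = np.random.default_rng(seed)
        recm = rng.random(n) < r
        recf = rng.random(n) < r
        m1 = rng.integers(0, 2, n)
        f1 = rng.integers(0, 2, n)

        def second(h1, rec, phase):
            h2 = np.where(rec, 1 - h1, h1)
            return np.where(phase, 1 - h2, h2)

        g1 = (m1 + f1).astype(np.int8)
        g2 = (second(m1, recm, phase_m) + second(f1, recf, phase_f)).astype(np.int8)
        return g1, g2

    @pytest.mark.parametrize("phase_m, phase_f", [(0, 0), (0, 1), (1, 0), (1, 1)])
    def test_recovers_r_under_all_phase_configurations(self, phase_m, phase_f):
        g1, g2 = self.sim_both_pair(0.12, 6000, phase_m, phase_f, seed=3)
        rf, lod, n = em_rf_lod(g1, g2)
        assert rf == pytest.approx(0.12, abs=0.02)
        assert lod > 50
        assert n == 12000

    def test_unlinked_pair_has_near_zero_lod(self):
        g1, _ = self.sim_both_pair(0.5, 2000, 0, 0, seed=4)
        _, g2 = self.sim_both_pair(0.5, 2000, 0, 0, seed=5)
        rf, lod, _ = em_rf_lod(g1, g2)
        assert rf == pytest.approx(0.5, abs=0.03)
        assert lod < 2

    def test_single_pair_api_matches_vectorized_path(self):
        g1, g2 = self.sim_both_pair(0.07, 1500, 0, 1, seed=6)
        mat = GenotypeMatrix(
            marker_ids=np.array(["A", "B"], dtype=object),
            rad_locus=np.array(["LA", "LB"], dtype=object),
            mother=np.array([HET, HET], dtype=np.int8),
            father=np.array([HET, HET], dtype=np.int8),
            offspring=np.vstack([g1, g2]),
        )
        calls = classify_segregation(mat)
        single = pairwise_rf_lod(mat, calls, ("A", "B"), "joint")
        bulk = pairwise_all(mat, calls)
        assert single.method == "em"
        assert single.rf == pytest.approx(bulk.rf_joint[0, 1], abs=1e-3)


def toy_estimates(lod):
    lod = np.asarray(lod, dtype=float)
    m = lod.shape[0]
    ids = np.array([f"M{i}" for i in range(m)], dtype=object)
    n = np.full_like(lod, 100.0)
    rf = np.full_like(lod, 0.1)
    return PairwiseEstimates(ids, rf, lod, n, rf, lod, n, rf, lod, n)


class TestGrouping:
    def test_threshold_inclusive(self):
        est = toy_estimates([[0, 16.0], [16.0, 0]])
        gs = separate_groups(est, lod_limit=16, min_markers=2)
        assert gs.n_groups == 1 and len(gs.groups[0]) == 2

    def test_single_linkage_chain(self):
        lod = [[0, 20, 3], [20, 0, 20], [3, 20, 0]]
        gs = separate_groups(toy_estimates(lod), lod_limit=16, min_markers=2)
        assert gs.n_groups == 1 and len(gs.groups[0]) == 3

    def test_small_components_dissolved(self):
        lod = np.zeros((5, 5))
        lod[0, 1] = lod[1, 0] = 20
        gs = separate_groups(toy_estimates(lod), lod_limit=16, min_markers=3)
        assert gs.n_groups == 0 and len(gs.unassigned) == 5

    def test_raising_limit_never_merges(self, small_cross_estimates):
        _, _, est = small_cross_estimates
        lo = separate_groups(est, lod_limit=10, min_markers=1)
        hi = separate_groups(est, lod_limit=25, min_markers=1)
        lo_label = lo.labels()
        hi_groups = hi.labels()
        # each high-threshold group sits inside one low-threshold group
        for members in hi.groups:
            assert len({lo_label[m] for m in members}) == 1
        assert hi.n_groups >= lo.n_groups


class TestOrdering:
    def test_three_marker_unique_optimum(self):
        est = toy_estimates(np.full((3, 3), 30.0))
        est.rf_joint[:] = [[np.nan, 0.05, 0.10], [0.05, np.nan, 0.05], [0.10, 0.05, np.nan]]
        est.n_joint[:] = 100.0
        order, score = order_markers(["M0", "M1", "M2"], est, seed=0)
        assert order in (["M0", "M1", "M2"], ["M2", "M1", "M0"])
        assert score == pytest.approx(0.10, abs=0.03)

    def test_heuristic_matches_exhaustive_on_small_groups(self):
        hits = attempted = 0
        for t in range(30):
            rng = np.random.default_rng(400 + t)
            m = int(rng.integers(4, 9))
            cfg = SimConfig(n_groups=1, markers_per_group=m, mean_spacing_cM=8.0,
                            seg_mixture=(0.3, 0.3, 0.4), error_rate=0.0,
                            missing_rate=0.05, rad_multi_snp=(1, 0, 0, 0),
                            seed=500 + t)
            _, mat, _ = simulate_cross(cfg)
            calls = classify_segregation(mat)
            est = pairwise_all(mat, calls)
            ids = list(mat.marker_ids)
            try:
                order, score = order_markers(ids, est, seed=t)
            except OrderingError:
                continue
            R, _, _ = ordering_matrix(ids, est)
            _, best = order_exhaustive(R)
            attempted += 1
            hits += score <= best + 1e-9
        assert attempted >= 25
        assert hits == attempted

    def test_recovers_true_order_on_identifiable_group(self):
        # fixed 12-cM spacing, large family: adjacent r ~ 0.11 >> its SE
        m = 8
        pos = np.arange(m) * 12.0
        table = pd.DataFrame(
            {
                "marker": [f"RAD{i:06d}_1" for i in range(m)],
                "group": "LG01",
                "order": range(m),
                "female_cM": pos,
                "male_cM": pos,
                "segtype": [SegType.MAT_INF.value, SegType.PAT_INF.value,
                            SegType.BOTH_INF.value, SegType.MAT_INF.value,
                            SegType.PAT_INF.value, SegType.BOTH_INF.value,
                            SegType.MAT_INF.value, SegType.PAT_INF.value],
                "rad_locus": [f"RAD{i:06d}" for i in range(m)],
            }
        )
        tm = TrueMap(table)
        cfg = SimConfig(n_offspring=500, error_rate=0.0, missing_rate=0.0, seed=9)
        mat, _ = simulate_offspring_genotypes(tm, cfg)
        calls = classify_segregation(mat)
        est = pairwise_all(mat, calls)
        order, _ = order_markers(list(mat.marker_ids), est, seed=1)
        truth = list(table["marker"])
        assert order == truth or order == truth[::-1]

    def test_disconnected_group_raises_with_name(self):
        # two mother-informative and two father-informative markers share no meioses
        mat = GenotypeMatrix(
            marker_ids=np.array(["A", "B", "C", "D"], dtype=object),
            rad_locus=np.array(["LA", "LB", "LC", "LD"], dtype=object),
            mother=np.array([HET, HET, HOM_REF, HOM_REF], dtype=np.int8),
            father=np.array([HOM_REF, HOM_REF, HET, HET], dtype=np.int8),
            offspring=np.zeros((4, 60), dtype=np.int8),
        )
        calls = classify_segregation(mat)
        est = pairwise_all(mat, calls)
        with pytest.raises(OrderingError, match="LGX"):
            order_markers(["A", "B", "C", "D"], est, group_name="LGX")


class TestMapPositions:
    def test_no_recombination_gives_zero_length(self):
        mat = mat_inf_pair(150, 0)
        calls = classify_segregation(mat)
        pos = map_positions(["A", "B"], mat, calls, "female")
        np.testing.assert_allclose(pos, [0.0, 0.0])

    def test_single_interval_haldane(self):
        mat = mat_inf_pair(150, 30)  # r = 0.2
        calls = classify_segregation(mat)
        pos = map_positions(["A", "B"], mat, calls, "female")
        assert pos[-1] == pytest.approx(25.54, abs=0.01)

    def test_paternal_only_group_has_zero_female_map(self):
        cfg = SimConfig(n_groups=1, markers_per_group=20, seg_mixture=(0.0, 1.0, 0.0),
                        error_rate=0.0, missing_rate=0.0, seed=14)
        tm, mat, _ = simulate_cross(cfg)
        calls = classify_segregation(mat)
        order = list(mat.marker_ids)
        female = map_positions(order, mat, calls, "female")
        male = map_positions(order, mat, calls, "male")
        averaged = map_positions(order, mat, calls, "averaged")
        assert female.max() == 0.0
        assert male.max() > 0.0
        np.testing.assert_allclose(averaged, male / 2.0)

    def test_build_map_invariants(self, small_cross_estimates):
        mat, calls, est = small_cross_estimates
        gs = separate_groups(est, 16, 25)
        gmap = build_genetic_map(mat, calls, gs, est, seed=2)
        for _, sub in gmap.table.groupby("group"):
            sub = sub.sort_values("order_index")
            for col in ("female_cM", "male_cM", "averaged_cM"):
                assert sub[col].iloc[0] == 0.0
                assert (sub[col].diff().dropna() >= -1e-9).all()
            np.testing.assert_allclose(
                sub["averaged_cM"], (sub["female_cM"] + sub["male_cM"]) / 2.0
            )


def test_two_point_distances_inflate_with_genotyping_error():
    """Genotyping errors create spurious recombinants, so summed adjacent
    two-point Haldane distances along the true order grow strictly with the
    error rate and exceed the true length already at 1% error.  (The
    least-squares position fit deliberately damps this inflation at the
    whole-map level by reconciling short- and long-range estimates.)"""
    totals = []
    truth_total = None
    for err in (0.0, 0.01, 0.03):
        tot = 0.0
        truth = 0.0
        for seed in (31, 32):
            cfg = SimConfig(n_groups=2, markers_per_group=40, mean_spacing_cM=4.0,
                            seg_mixture=(1.0, 0.0, 0.0), error_rate=err,
                            missing_rate=0.0, rad_multi_snp=(1, 0, 0, 0), seed=seed)
            tm, mat, _ = simulate_cross(cfg)
            calls = classify_segregation(mat)
            est = pairwise_all(mat, calls)
            order = {mid: i for i, mid in enumerate(est.marker_ids)}
            for g in tm.groups:
                sub = tm.group_table(g)
                sel = [order[m] for m in sub["marker"]]
                r = est.rf_maternal[sel[:-1], sel[1:]]
                tot += float(np.sum(-50.0 * np.log(1.0 - 2.0 * np.clip(r, 0, 0.49))))
                truth += float(sub["female_cM"].max())
        totals.append(tot)
        truth_total = truth
    assert totals[0] < totals[1] < totals[2]
    assert totals[1] > truth_total
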