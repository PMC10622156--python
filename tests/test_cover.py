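"""Rank tests, effect sizes, QC rules, and the cover-comparison routines.

Brute-force oracles: U as the count of (a, b) pairs with a > b plus half the
ties; H from an explicit average-rank computation. Both stay independent of
the implementation under test.
"""

import numpy as np
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kruskal as scipy_kruskal
from scipy.stats import mannwhitneyu as scipy_mwu
from scipy.stats import rankdata

import seagrassmap as sm


def brute_force_u(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    gt = (a[:, None] > b[None, :]).sum()
    ties = (a[:, None] == b[None, :]).sum()
    return gt + 0.5 * ties


def brute_force_h(groups):
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = rankdata(pooled)
    idx = np.cumsum([0] + [len(g) for g in groups])
    h = 12.0 / (n * (n + 1)) * sum(
        ranks[i:j].sum() ** 2 / (j - i) for i, j in zip(idx, idx[1:])
    ) - 3 * (n + 1)
    _, t = np.unique(pooled, return_counts=True)
    corr = 1 - (t**3 - t).sum() / (n**3 - n)
    return 0.0 if corr <= 0 else h / corr


class TestMannWhitneyU:
    def test_complete_separation(self):
        u, p = sm.mann_whitney_u([1, 2, 3], [4, 5, 6], tail="less")
        assert u == 0.0
        assert p == pytest.approx(1 / 20)  # exact: 1 of C(6,3)=20 assignments

    def test_interleaved_equals_pair_count(self):
        u, _ = sm.mann_whitney_u([1, 3, 5], [2, 4, 6])
        assert u == brute_force_u([1, 3, 5], [2, 4, 6]) == 3.0

    def test_u_complement_identity_and_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n1, n2 = rng.integers(1, 13, size=2)
            a = rng.integers(0, 8, size=n1).astype(float)  # heavy ties
            b = rng.integers(0, 8, size=n2).astype(float)
            u_a, _ = sm.mann_whitney_u(a, b)
            u_b, _ = sm.mann_whitney_u(b, a)
            assert u_a == pytest.approx(brute_force_u(a, b), abs=1e-12)
            assert u_a + u_b == pytest.approx(n1 * n2, abs=1e-12)

    def test_statistic_matches_scipy(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=30), rng.normal(0.5, size=25)
        u, p = sm.mann_whitney_u(a, b, tail="two-sided")
        res = scipy_mwu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue, rel=1e-6)

    def test_exact_p_matches_scipy_exact_without_ties(self):
        a, b = [1.0, 4.0, 7.0], [2.0, 9.0, 11.0]
        for tail, alt in [("greater", "greater"), ("less", "less"),
                          ("two-sided", "two-sided")]:
            u, p = sm.mann_whitney_u(a, b, tail=tail)
            res = scipy_mwu(a, b, alternative=alt, method="exact")
            assert p == pytest.approx(res.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(sm.ParameterError):
            sm.mann_whitney_u([], [1.0])


class TestRankBiserial:
    @pytest.mark.parametrize("u,n1,n2,expected", [
        (291, 26, 48, 0.53),     # continuous cover points vs satellite class
        (2204.5, 161, 57, 0.52),  # patchy vs continuous, large site
        (189, 53, 41, 0.83),
        (53, 21, 16, 0.68),      # post hoc pairs
        (49, 25, 6, 0.35),
    ])
    def test_reported_effect_sizes(self, u, n1, n2, expected):
        assert round(sm.rank_biserial(u, n1, n2), 2) == expected

    def test_null_at_half_product(self):
        assert sm.rank_biserial(12.0, 6, 4) == 0.0

    @given(st.integers(1, 30), st.integers(1, 30), st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_complement_invariance(self, n1, n2, frac):
        u = frac * n1 * n2
        assert sm.rank_biserial(u, n1, n2) == pytest.approx(
            sm.rank_biserial(n1 * n2 - u, n2, n1)
        )

    def test_out_of_range_u_rejected(self):
        with pytest.raises(sm.ParameterError):
            sm.rank_biserial(25.0, 4, 6)


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        h, p = sm.kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_all_constant_degenerate(self):
        h, p = sm.kruskal_wallis([[5, 5], [5, 5], [5]])
        assert (h, p) == (0.0, 1.0)

    def test_hand_ranked_three_pairs(self):
        # groups [1,2],[3,4],[5,6]: rank sums 3,7,11 -> H = 32/7
        h, _ = sm.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(32 / 7)

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            k = rng.integers(2, 5)
            groups = [rng.integers(0, 6, size=rng.integers(2, 13)).astype(float)
                      for _ in range(k)]
            h, p = sm.kruskal_wallis(groups)
            assert h == pytest.approx(brute_force_h(groups), abs=1e-12)
            if h > 0:
                res = scipy_kruskal(*groups)
                assert h == pytest.approx(res.statistic, abs=1e-10)
                assert p == pytest.approx(res.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(sm.ParameterError):
            sm.kruskal_wallis([[1.0], []])


class TestEpsilonSquared:
    @pytest.mark.parametrize("h,n,expected", [(31.74, 100, 0.32), (7.59, 57, 0.14)])
    def test_reported_effect_sizes(self, h, n, expected):
        assert round(sm.epsilon_squared(h, n), 2) == expected

    def test_zero_statistic(self):
        assert sm.epsilon_squared(0.0, 10) == 0.0

    @given(st.floats(0, 50), st.integers(3, 500))
    @settings(max_examples=100, deadline=None)
    def test_identity_eps2_times_n_minus_1_is_h(self, h, n):
        eps2 = sm.epsilon_squared(h, n)
        if eps2 < 1.0:  # identity holds below the clip
            assert eps2 * (n - 1) == pytest.approx(h, abs=1e-9)


class TestInterpretation:
    @pytest.mark.parametrize("value,scheme,expected", [
        (0.53, sm.RRB_INTERPRETATION, "large"),
        (0.35, sm.RRB_INTERPRETATION, "moderate"),
        (0.05, sm.RRB_INTERPRETATION, "negligible"),
        (0.1, sm.RRB_INTERPRETATION, "small"),
        (0.32, sm.EPS2_INTERPRETATION, "large"),
        (0.14, sm.EPS2_INTERPRETATION, "moderate"),
        (0.005, sm.EPS2_INTERPRETATION, "negligible"),
    ])
    def test_magnitude_labels(self, value, scheme, expected):
        assert sm.interpret_effect(value, scheme) == expected


class TestSampleSizeGate:
    @pytest.mark.parametrize("sizes,expected", [
        ((1, 2, 1, 16), "failed_min_per_group"),
        ((6, 14, 25, 12), "passed"),
        ((5, 5, 5, 5), "failed_min_total"),  # boundary: N=20 < 24
        ((16, 33, 30, 21), "passed"),
    ])
    def test_gate(self, sizes, expected):
        assert sm.sample_size_gate(sizes) == expected


class TestClipAndCover:
    def test_nodata_fraction_rule(self, general_classmap):
        labels = np.full((10, 10), sm.NO_DATA, dtype=np.int16)
        labels[0, :5] = sm.SEAGRASS  # 95 no-data / 100 total
        cmap = general_classmap(labels)
        poly = shapely.box(0, 0, 10, 10)
        rec, = sm.clip_and_cover(cmap, sm.ReferenceSet(
            "density_polygons", [sm.ReferenceFeature("a", poly, {"dens_cls": "x"})]))
        assert rec.n_total_pixels == 100 and rec.n_nodata == 95
        assert rec.qc_status == "discarded_nodata_fraction"

    def test_too_few_valid_rule(self, general_classmap):
        labels = np.full((4, 5), sm.NO_SEAGRASS, dtype=np.int16)
        labels.flat[:12] = sm.NO_DATA  # 20 px: 12 no-data (60%), 8 valid
        cmap = general_classmap(labels)
        poly = shapely.box(0, 0, 5, 4)
        rec, = sm.clip_and_cover(cmap, sm.ReferenceSet(
            "density_polygons", [sm.ReferenceFeature("a", poly, {"dens_cls": "x"})]))
        assert (rec.n_nodata, rec.n_valid) == (12, 8)
        assert rec.qc_status == "discarded_too_few_valid"

    def test_cover_percentage_arithmetic(self, general_classmap):
        labels = np.full((5, 8), sm.NO_SEAGRASS, dtype=np.int16)  # 40 valid
        labels.flat[:10] = sm.SEAGRASS
        cmap = general_classmap(labels)
        poly = shapely.box(0, 0, 8, 5)
        rec, = sm.clip_and_cover(cmap, sm.ReferenceSet(
            "density_polygons", [sm.ReferenceFeature("a", poly, {"dens_cls": "x"})]))
        assert rec.qc_status == "kept"
        assert rec.satellite_cover_pct == pytest.approx(25.0)

    def test_zero_center_polygon_flagged_not_error(self, general_classmap):
        cmap = general_classmap(np.full((4, 4), sm.SEAGRASS, dtype=np.int16))
        poly = shapely.box(0.6, 3.6, 0.9, 3.9)
        rec, = sm.clip_and_cover(cmap, sm.ReferenceSet(
            "density_polygons", [sm.ReferenceFeature("a", poly, {"dens_cls": "x"})]))
        assert rec.n_total_pixels == 0
        assert rec.qc_status == "discarded_too_few_valid"

    def test_land_in_nodata_denominator_but_not_valid(self, general_classmap):
        labels = np.full((4, 10), sm.LAND, dtype=np.int16)  # 40 px
        labels[0, :] = sm.SEAGRASS
        labels[1, :] = sm.NO_SEAGRASS
        cmap = general_classmap(labels)
        poly = shapely.box(0, 0, 10, 4)
        rec, = sm.clip_and_cover(cmap, sm.ReferenceSet(
            "density_polygons", [sm.ReferenceFeature("a", poly, {"dens_cls": "x"})]))
        assert (rec.n_total_pixels, rec.n_land, rec.n_valid) == (40, 20, 20)
        assert rec.satellite_cover_pct == pytest.approx(50.0)

    def test_every_polygon_in_exactly_one_qc_category(self, truth_field):
        cm = sm.degrade_to_classmap(truth_field,
                                    sm.ErrorModel(nodata_fraction=0.4), seed=5)
        ref = sm.delineate_reference(truth_field, "density_polygons",
                                     scheme=sm.CHESAPEAKE_SCHEME, polygon_size=8)
        records = sm.clip_and_cover(cm, ref)
        assert len(records) == len(ref)
        statuses = {"kept", "discarded_nodata_fraction", "discarded_too_few_valid"}
        assert all(r.qc_status in statuses for r in records)
        for r in records:
            assert r.n_total_pixels == r.n_nodata + r.n_land + r.n_valid


def _records(values_by_class):
    recs = []
    for cls, values in values_by_class.items():
        for i, v in enumerate(values):
            recs.append(sm.PolygonCoverRecord(
                ref_id=f"{cls}{i}", reference_label=cls, n_total_pixels=100,
                n_nodata=0, n_land=0, n_valid=100, n_seagrass=int(v),
                satellite_cover_pct=float(v), qc_status="kept",
            ))
    return recs


class TestTwoClassComparison:
    def test_complete_separation(self):
        recs = _records({"patchy": [10, 20, 30], "continuous": [80, 90, 95]})
        rep = sm.compare_cover_two_class(recs, sm.TAMPA_SCHEME)
        assert rep.effect_size == 1.0
        assert rep.statistic == 0.0
        assert rep.p_value == pytest.approx(1 / 20)  # minimal one-sided p for 3+3

    def test_hand_ranked_six_plus_six(self):
        patchy = [10, 25, 30, 45, 50, 55]
        cont = [40, 60, 70, 80, 90, 95]
        recs = _records({"patchy": patchy, "continuous": cont})
        rep = sm.compare_cover_two_class(recs, sm.TAMPA_SCHEME)
        assert rep.statistic == brute_force_u(patchy, cont)
        assert rep.medians["patchy"] == pytest.approx(np.median(patchy))
        assert rep.medians["continuous"] == pytest.approx(np.median(cont))

    def test_missing_class_rejected(self):
        recs = _records({"patchy": [10, 20]})
        with pytest.raises(sm.ParameterError):
            sm.compare_cover_two_class(recs, sm.TAMPA_SCHEME)

    def test_discarded_records_excluded(self):
        recs = _records({"patchy": [10, 20, 30], "continuous": [80, 90]})
        recs[0].qc_status = "discarded_nodata_fraction"
        rep = sm.compare_cover_two_class(recs, sm.TAMPA_SCHEME)
        assert rep.group_sizes == (2, 2)


class TestMulticlassComparison:
    def test_disjoint_supports_maximal_effect(self):
        recs = _records({
            "1-10%": [1, 2, 3, 4, 5, 6], "11-40%": [20, 21, 22, 23, 24, 25],
            "41-70%": [50, 51, 52, 53, 54, 55], "71-100%": [90, 91, 92, 93, 94, 95],
        })
        rep = sm.compare_cover_multiclass(recs, sm.CHESAPEAKE_SCHEME)
        assert rep.gate_status == "passed"
        assert rep.effect_size > 0.9
        assert rep.posthoc is not None and len(rep.posthoc) == 6
        assert all(p.effect_size == 1.0 for p in rep.posthoc)
        assert all(p.tail == "two-sided" for p in rep.posthoc)

    def test_gate_failure_reports_descriptive_medians_only(self):
        recs = _records({
            "1-10%": [0], "11-40%": [3, 3], "41-70%": [21], "71-100%": [72] * 16,
        })
        rep = sm.compare_cover_multiclass(recs, sm.CHESAPEAKE_SCHEME)
        assert rep.test == "descriptive"
        assert rep.gate_status == "failed_min_per_group"
        assert rep.statistic is None and rep.effect_size is None
        assert rep.medians["11-40%"] == pytest.approx(3.0)
        assert rep.medians["71-100%"] == pytest.approx(72.0)

    def test_posthoc_u_matches_oracle(self):
        rng = np.random.default_rng(3)
        data = {c: list(rng.integers(0, 100, size=8))
                for c in sm.CHESAPEAKE_SCHEME.labels}
        rep = sm.compare_cover_multiclass(_records(data), sm.CHESAPEAKE_SCHEME)
        if rep.posthoc:
            for pair in rep.posthoc:
                lo, hi = pair.group_names
                assert pair.statistic == pytest.approx(
                    brute_force_u(data[lo], data[hi])
                )


class TestReferenceCoverBySatelliteClass:
    def test_brute_force_on_constructed_points(self, general_classmap):
        labels = np.array([[sm.NO_SEAGRASS] * 5, [sm.SEAGRASS] * 5])
        cmap = general_classmap(labels)
        no_sg_cov = [10.0, 20.0, 30.0, 15.0, 25.0]
        sg_cov = [60.0, 75.0, 85.0, 90.0, 70.0]
        feats = []
        for i, v in enumerate(no_sg_cov):
            feats.append(sm.ReferenceFeature(
                f"n{i}", shapely.Point(i + 0.5, 1.5), {"cover_pct": v}))
        for i, v in enumerate(sg_cov):
            feats.append(sm.ReferenceFeature(
                f"s{i}", shapely.Point(i + 0.5, 0.5), {"cover_pct": v}))
        ref = sm.ReferenceSet("cover_points", feats)
        rep = sm.compare_reference_cover_by_satellite_class(ref, cmap)
        assert rep.statistic == brute_force_u(no_sg_cov, sg_cov)
        assert rep.group_sizes == (5, 5)
        assert rep.medians["seagrass"] > rep.medians["no_seagrass"]

    def test_all_points_on_nodata_is_error(self, general_classmap):
        cmap = general_classmap(np.full((2, 2), sm.NO_DATA, dtype=np.int16))
        feats = [sm.ReferenceFeature("a", shapely.Point(0.5, 0.5),
                                     {"cover_pct": 50.0})]
        with pytest.raises(sm.ParameterError, match="zero usable groups"):
            sm.compare_reference_cover_by_satellite_class(
                sm.ReferenceSet("cover_points", feats), cmap)

    def test_synthetic_recovery(self, truth_field):
        cm = sm.degrade_to_classmap(truth_field, sm.ErrorModel(p_miss=0.1), seed=2)
        ref = sm.delineate_reference(truth_field, "cover_points",
                                     n_points=120, seed=5)
        rep = sm.compare_reference_cover_by_satellite_class(ref, cm)
        # reference cover genuinely higher on satellite-seagrass pixels
        assert rep.medians["seagrass"] > rep.medians["no_seagrass"]
        assert rep.effect_size > 0.5


class TestHolmAdjustment:
    def test_matches_hand_computation_and_is_monotone(self):
        p = [0.01, 0.04, 0.03, 0.005]
        # hand Holm: sorted (0.005,0.01,0.03,0.04) * (4,3,2,1) with running max
        assert sm.holm_adjusted(p) == pytest.approx([0.03, 0.06, 0.06, 0.02])

    def test_off_by_default_and_recorded_when_on(self):
        rng = np.random.default_rng(5)
        data = {c: list(rng.integers(0, 100, size=8))
                for c in sm.CHESAPEAKE_SCHEME.labels}
        plain = sm.compare_cover_multiclass(_records(data), sm.CHESAPEAKE_SCHEME)
        adjusted = sm.compare_cover_multiclass(_records(data), sm.CHESAPEAKE_SCHEME,
                                               holm_adjust=True)
        if plain.posthoc:
            assert all("p_value_holm" not in r.notes for r in plain.posthoc)
            assert all(r.notes["p_value_holm"] >= r.p_value - 1e-15
                       for r in adjusted.posthoc)
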