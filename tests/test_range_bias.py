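"""Equal-area-circle null model, class-area accounting, and cohort statistics."""

import math

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import box

import catrange as cr
from catrange.bias import ALL_ROWS, compare_all_classes
from catrange.types import CoverageError


class TestEqualAreaCircle:
    @pytest.mark.parametrize(
        "area_ha,expected_radius",
        [(0.728, 48.14), (0.839, 51.68), (0.711, 47.57)],
    )
    def test_radius_from_median_areas(self, area_ha, expected_radius):
        """Radius of the equal-area circle from cohort median AOI areas,
        sqrt(A/pi), to 2 decimal places."""
        r = cr.radius_for_area(area_ha * 10_000)
        assert round(r, 2) == expected_radius

    def test_pi_hectares_gives_100m(self):
        assert cr.radius_for_area(math.pi * 1e4) == pytest.approx(100.0)

    def test_center_is_coordinatewise_median(self, fixset_factory):
        fs = fixset_factory([[0, 0], [0, 10], [10, 0]])
        circ = cr.equal_area_circle(fs, 1000.0)
        assert circ.center == (0.0, 0.0)

    def test_polygon_area_within_tolerance(self):
        circ = cr.equal_area_circle(np.array([[3.0, 4.0]]), 7280.0)
        assert abs(circ.area_m2 - 7280.0) / 7280.0 < 1e-3

    def test_radius_area_identity_and_monotonicity(self):
        areas = np.linspace(100.0, 50_000.0, 25)
        radii = [cr.radius_for_area(a) for a in areas]
        for a, r in zip(areas, radii):
            assert math.pi * r**2 == pytest.approx(a, rel=1e-6)
        assert np.all(np.diff(radii) > 0)

    def test_median_radius_equals_radius_of_median_area(self):
        """sqrt(x/pi) is strictly monotone, so the two commute."""
        rng = np.random.default_rng(0)
        areas = rng.lognormal(np.log(7000), 0.5, size=49)
        radii = np.sqrt(areas / math.pi)
        assert np.median(radii) == pytest.approx(
            cr.radius_for_area(float(np.median(areas))), rel=1e-12
        )

    def test_nonpositive_area_errors(self):
        with pytest.raises(ValueError):
            cr.equal_area_circle(np.array([[0.0, 0.0]]), 0.0)


class TestClassAreas:
    def test_region_inside_single_class(self):
        lc = cr.LandCoverMap([cr.LandCoverPolygon(box(0, 0, 100, 100),
                                                  landcover="Natural", is_green=True)])
        region = box(10, 10, 30, 30)
        areas = cr.class_areas(lc, region)
        assert areas["Natural"] == pytest.approx(400.0)
        assert areas["Green"] == pytest.approx(400.0)
        assert areas["Roads"] == 0.0

    def test_half_half_symmetry(self):
        lc = cr.LandCoverMap([
            cr.LandCoverPolygon(box(-50, -50, 0, 50), landcover="Roads"),
            cr.LandCoverPolygon(box(0, -50, 50, 50), landcover="Open urban",
                                is_green=True),
        ])
        circle = shapely.Point(0, 0).buffer(20, quad_segs=64)
        areas = cr.class_areas(lc, circle)
        assert areas["Roads"] == pytest.approx(circle.area / 2, rel=1e-9)
        assert areas["Open urban"] == pytest.approx(circle.area / 2, rel=1e-9)
        assert areas["Green"] == pytest.approx(areas["Open urban"])

    def test_derived_rows_follow_composition(self):
        lm = cr.simulate_landscape(
            cr.LandscapeSimConfig(extent=(-40, -40, 40, 40), pixel_size=2.0, seed=1)
        )
        region = box(-30, -30, 30, 30)
        a = cr.class_areas(lm, region)
        assert a["Open all"] == pytest.approx(
            a["Open urban"] + a["Open urban natural"] + a["Natural"] + a["Agriculture"]
        )
        assert a["Open urban all"] == pytest.approx(a["Open urban"] + a["Open urban natural"])
        assert a["Open outside settlement"] == pytest.approx(a["Natural"] + a["Agriculture"])
        assert a["Green"] + a["Not green"] == pytest.approx(region.area, rel=1e-9)
        assert sum(a[c] for c in cr.BASE_CLASSES) == pytest.approx(region.area, rel=1e-9)

    def test_coverage_gap_errors(self):
        lc = cr.LandCoverMap([cr.LandCoverPolygon(box(0, 0, 10, 10), landcover="Natural")])
        with pytest.raises(CoverageError, match="uncovered"):
            cr.class_areas(lc, box(5, 5, 20, 20))


class TestRangeBias:
    def test_identical_tables_zero_bias(self):
        tab = pd.DataFrame({"Natural": [10.0, 20.0]}, index=["a", "b"])
        bias = cr.range_bias(tab, tab.copy())
        assert (bias == 0).all().all()

    def test_swap_gives_opposite_signs(self):
        aoi = pd.DataFrame({"Natural": [100.0], "Roads": [0.0]}, index=["a"])
        circ = pd.DataFrame({"Natural": [0.0], "Roads": [100.0]}, index=["a"])
        bias = cr.range_bias(aoi, circ)
        assert bias.loc["a", "Natural"] == 100.0
        assert bias.loc["a", "Roads"] == -100.0

    def test_missing_cat_skipped_with_warning(self):
        aoi = pd.DataFrame({"Natural": [1.0, 2.0]}, index=["a", "b"])
        circ = pd.DataFrame({"Natural": [1.0]}, index=["a"])
        with pytest.warns(UserWarning, match="'b'"):
            bias = cr.range_bias(aoi, circ)
        assert list(bias.index) == ["a"]


def _cohort_tables(n=12, seed=0):
    """AOI/circle tables from lognormal class areas, one pair per cat."""
    rng = np.random.default_rng(seed)
    idx = [f"c{i}" for i in range(n)]
    aoi = pd.DataFrame(rng.lognormal(7, 0.7, (n, len(ALL_ROWS))), index=idx,
                       columns=list(ALL_ROWS))
    circ = pd.DataFrame(rng.lognormal(7, 0.7, (n, len(ALL_ROWS))), index=idx,
                        columns=list(ALL_ROWS))
    return aoi, circ


class TestPairedCompare:
    def test_all_zero_differences(self):
        aoi, _ = _cohort_tables()
        res = cr.paired_compare(aoi, aoi.copy(), "Natural")
        assert res.test == "wilcoxon"
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_insufficient_pairs(self):
        aoi, circ = _cohort_tables(n=3)
        res = cr.paired_compare(aoi, circ, "Natural")
        assert res.test == "insufficient data"
        assert np.isnan(res.p)

    def test_absent_in_both_excluded_from_n(self):
        aoi, circ = _cohort_tables(n=10)
        aoi.loc[["c0", "c1"], "Natural"] = 0.0
        circ.loc[["c0", "c1"], "Natural"] = 0.0
        res = cr.paired_compare(aoi, circ, "Natural")
        assert res.n == 8

    def test_large_shift_detected(self):
        aoi, circ = _cohort_tables(n=20, seed=3)
        aoi["Natural"] = circ["Natural"] * 50.0
        res = cr.paired_compare(aoi, circ, "Natural")
        assert res.p < 0.001
        assert res.mean_bias_m2 > 0

    def test_signed_rank_statistic_is_centered(self):
        """For the signed-rank branch, S = R+ - n(n+1)/4, so a symmetric
        sample has |S| far below n(n+1)/4."""
        aoi, circ = _cohort_tables(n=15, seed=5)
        res = cr.paired_compare(aoi, circ, "Roads")
        n = res.n
        if res.test == "wilcoxon":
            assert abs(res.statistic) <= n * (n + 1) / 4

    def test_table_shape(self):
        aoi, circ = _cohort_tables(n=15, seed=7)
        frame = compare_all_classes(aoi, circ, holm=True)
        assert list(frame.index) == list(ALL_ROWS)
        valid = frame["p"].notna()
        assert (frame.loc[valid, "p_holm"] >= frame.loc[valid, "p"] - 1e-12).all()


class TestNaturalAreaGroupTest:
    def _tables(self, areas_with, areas_without, agri=()):
        n = len(areas_with) + len(areas_without) + len(agri)
        idx = [f"c{i}" for i in range(n)]
        tab = pd.DataFrame(0.0, index=idx, columns=list(ALL_ROWS))
        areas = pd.Series(0.0, index=idx)
        i = 0
        for a in areas_with:
            tab.loc[idx[i], "Natural"] = 50.0
            areas[idx[i]] = a
            i += 1
        for a in areas_without:
            areas[idx[i]] = a
            i += 1
        for a in agri:
            tab.loc[idx[i], "Agriculture"] = 20.0
            tab.loc[idx[i], "Natural"] = 50.0
            areas[idx[i]] = a
            i += 1
        return tab, areas

    def test_u_statistic_within_range(self):
        rng = np.random.default_rng(1)
        tab, areas = self._tables(rng.lognormal(9, 0.4, 24), rng.lognormal(9, 0.4, 25))
        res = cr.natural_area_group_test(tab, areas)
        assert 0 <= res.statistic <= 24 * 25

    def test_large_shift_significant(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(9, 0.2, 20)
        tab, areas = self._tables(base * 20.0, rng.lognormal(9, 0.2, 20))
        res = cr.natural_area_group_test(tab, areas)
        assert res.p < 0.001
        assert res.median_with > res.median_without

    def test_agriculture_cats_excluded(self):
        rng = np.random.default_rng(3)
        tab, areas = self._tables(rng.lognormal(9, 0.3, 10),
                                  rng.lognormal(9, 0.3, 10), agri=[1e5] * 9)
        res = cr.natural_area_group_test(tab, areas)
        assert res.n_excluded == 9
        assert res.n_with + res.n_without == 20

    def test_empty_group_insufficient(self):
        tab, areas = self._tables([1e4] * 6, [])
        res = cr.natural_area_group_test(tab, areas)
        assert res.test == "insufficient data"

    def test_null_pvalues_roughly_uniform(self):
        """Both groups from one distribution: p-values near-uniform (KS)."""
        from scipy import stats

        rng = np.random.default_rng(8)
        ps = []
        for _ in range(200):
            tab, areas = self._tables(rng.lognormal(9, 0.4, 12),
                                      rng.lognormal(9, 0.4, 12))
            ps.append(cr.natural_area_group_test(tab, areas).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestCovariateTests:
    def _meta(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"c{i}" for i in range(n)]
        meta = pd.DataFrame(
            {
                "sex": rng.choice(["F", "M"], n),
                "season": rng.choice(["winter", "summer"], n),
                "age": rng.integers(1, 13, n),
            },
            index=idx,
        )
        areas = pd.Series(rng.lognormal(9, 0.4, n), index=idx)
        return meta, areas

    def test_perfect_negative_age_correlation(self):
        meta, areas = self._meta()
        meta["age"] = np.arange(len(meta))
        areas[:] = np.arange(len(meta))[::-1]
        out = cr.covariate_tests(meta, areas)
        assert out["age"]["rho"] == pytest.approx(-1.0)

    def test_sex_and_season_report_z_and_p(self):
        meta, areas = self._meta()
        out = cr.covariate_tests(meta, areas)
        for key in ("sex", "season"):
            assert out[key]["test"] == "Wilcoxon rank-sum"
            assert 0 <= out[key]["p"] <= 1

    def test_constant_covariate_skipped(self):
        meta, areas = self._meta()
        meta["sex"] = "F"
        with pytest.warns(UserWarning, match="constant"):
            out = cr.covariate_tests(meta, areas)
        assert "skipped" in out["sex"]["test"]

    def test_permuted_labels_null_distributed(self):
        meta, areas = self._meta(n=40, seed=4)
        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            meta["sex"] = rng.permutation(meta["sex"].to_numpy())
            out = cr.covariate_tests(meta, areas)
            if out["sex"]["p"] < 0.05:
                rejections += 1
        assert 0.01 <= rejections / n_rep <= 0.10
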