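"""ROI geometry, ROI statistics, time courses and one-way ANOVA."""

import numpy as np
import pytest
from scipy import stats

from speckleflow.contrast import FlowIndexMap
from speckleflow.roi import (
    Calibration,
    CircularRoi,
    VesselRoi,
    anova_oneway,
    flow_time_course,
    roi_mask,
    roi_mean,
    roi_relative_flow,
    significance_code,
    time_course,
)

CAL = Calibration(0.1, (50.0, 50.0))


def _flow_map(values):
    values = np.asarray(values, dtype=float)
    return FlowIndexMap(values, ~np.isfinite(values))


class TestRoiMask:
    def test_circle_area_near_analytic(self):
        mask = roi_mask(CircularRoi((0.0, 0.0), 1.0), CAL, (100, 100))
        assert abs(mask.sum() - np.pi * 5**2) / (np.pi * 5**2) < 0.04

    def test_doubling_diameter_quadruples_area(self):
        a1 = roi_mask(CircularRoi((0.0, 0.0), 1.0), CAL, (100, 100)).sum()
        a2 = roi_mask(CircularRoi((0.0, 0.0), 2.0), CAL, (100, 100)).sum()
        r_px = 5
        assert abs(a2 / a1 - 4.0) < 4 * 2 / r_px  # rasterization tolerance

    def test_circle_outside_image_raises(self):
        with pytest.raises(ValueError, match="empty"):
            roi_mask(CircularRoi((40.0, 40.0), 1.0), CAL, (100, 100))

    def test_ap_ml_convention(self):
        """Negative AP (caudal) moves down; positive ML moves right."""
        mask = roi_mask(CircularRoi((-2.0, 2.0), 0.4), CAL, (100, 100))
        rr, cc = np.nonzero(mask)
        assert rr.mean() == pytest.approx(70.0, abs=1.0)  # 50 + 2/0.1
        assert cc.mean() == pytest.approx(70.0, abs=1.0)

    def test_vessel_mask_area_scales_with_width(self):
        v1 = VesselRoi(((0.0, -3.0), (0.0, 3.0)), width=0.2)
        v2 = VesselRoi(((0.0, -3.0), (0.0, 3.0)), width=0.4)
        a1 = roi_mask(v1, CAL, (100, 100)).sum()
        a2 = roi_mask(v2, CAL, (100, 100)).sum()
        assert a2 > 1.5 * a1

    def test_field_of_view_dimensions(self):
        # 1x field of view 9 mm x 6.7 mm at its native resolution
        from speckleflow.roi import FIELD_OF_VIEW_MM

        w_mm, h_mm = FIELD_OF_VIEW_MM["1x"]
        mmpp = w_mm / 900
        assert round(h_mm / mmpp) == pytest.approx(670, abs=1)


class TestRoiMean:
    def test_constant_map(self):
        m = _flow_map(np.full((10, 10), 0.44))
        assert roi_mean(m, np.ones((10, 10), bool)) == pytest.approx(0.44)

    def test_half_and_half(self):
        vals = np.zeros((10, 10))
        vals[:, 5:] = 1.0
        assert roi_mean(_flow_map(vals), np.ones((10, 10), bool)) == pytest.approx(0.5)

    def test_invalid_pixels_excluded_not_imputed(self):
        vals = np.full((4, 4), 2.0)
        vals[0, 0] = np.nan
        assert roi_mean(_flow_map(vals), np.ones((4, 4), bool)) == pytest.approx(2.0)

    def test_all_invalid_raises(self):
        with pytest.raises(ValueError, match="invalid"):
            roi_mean(_flow_map(np.full((3, 3), np.nan)), np.ones((3, 3), bool))

    def test_linear_in_the_map(self, rng):
        vals = rng.uniform(1, 2, (8, 8))
        mask = rng.uniform(size=(8, 8)) > 0.5
        a = roi_mean(_flow_map(vals), mask)
        b = roi_mean(_flow_map(3.0 * vals), mask)
        assert b == pytest.approx(3.0 * a, rel=1e-12)


class TestTimeCourse:
    def test_flow_course_baseline_is_one_and_ratios_exact(self):
        base = _flow_map(np.full((100, 100), 40.0))
        half = _flow_map(np.full((100, 100), 20.0))
        roi = CircularRoi((0.0, 0.0), 1.0)
        df = flow_time_course([base, half], roi, CAL, times=[0, 2])
        assert df["mean"].tolist() == pytest.approx([1.0, 0.5])
        assert (df["roi"] == "roi").all()

    def test_replicate_sd_reported(self):
        reps = [
            [_flow_map(np.full((20, 20), 10.0)), _flow_map(np.full((20, 20), v))]
            for v in (4.0, 5.0, 6.0)
        ]
        roi = CircularRoi((0.0, 0.0), 1.0)
        df = flow_time_course(reps, roi, Calibration(0.1, (10.0, 10.0)))
        assert df.loc[1, "mean"] == pytest.approx(0.5)
        assert df.loc[1, "sd"] == pytest.approx(np.std([0.4, 0.5, 0.6], ddof=1))
        assert df.loc[1, "n"] == 3

    def test_replicate_permutation_invariance(self):
        reps = [
            [_flow_map(np.full((20, 20), 10.0)), _flow_map(np.full((20, 20), v))]
            for v in (4.0, 5.0, 6.0)
        ]
        roi = CircularRoi((0.0, 0.0), 1.0)
        cal = Calibration(0.1, (10.0, 10.0))
        df1 = flow_time_course(reps, roi, cal)
        df2 = flow_time_course(reps[::-1], roi, cal)
        assert df1["mean"].tolist() == pytest.approx(df2["mean"].tolist())

    def test_rcbf_map_course_identity_at_baseline(self):
        from speckleflow.contrast import RelativeCbfMap

        maps = [RelativeCbfMap(np.ones((20, 20)), np.zeros((20, 20), bool))]
        df = time_course(maps, CircularRoi((0.0, 0.0), 1.0), Calibration(0.1, (10.0, 10.0)))
        assert df.loc[0, "mean"] == pytest.approx(1.0)

    def test_roi_relative_flow_offset(self):
        base = _flow_map(np.full((10, 10), 5.0))
        cur = _flow_map(np.full((10, 10), 3.0))
        mask = np.ones((10, 10), bool)
        assert roi_relative_flow(cur, base, mask, noflow_offset=1.0) == pytest.approx(0.5)


class TestAnova:
    def test_identical_groups_degenerate_path(self):
        res = anova_oneway({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        # equal means with within-group spread: F = 0, ns
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.significance == "ns"

    def test_constant_equal_groups_flagged(self):
        res = anova_oneway({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert res.degenerate and res.p_value == 1.0 and res.significance == "ns"

    def test_separated_groups_highly_significant(self):
        res = anova_oneway({"a": [0.0, 1e-4, -1e-4], "b": [10.0, 10.0001, 9.9999]})
        assert res.p_value < 0.001
        assert res.significance == "***"

    def test_matches_scipy_oracle(self, rng):
        groups = {f"g{i}": rng.normal(i * 0.5, 1.0, 3).tolist() for i in range(4)}
        res = anova_oneway(groups)
        f_ref, p_ref = stats.f_oneway(*groups.values())
        assert res.f_statistic == pytest.approx(f_ref, rel=1e-8)
        assert res.p_value == pytest.approx(p_ref, rel=1e-8)

    def test_two_groups_equal_t_squared(self, rng):
        a, b = rng.normal(0, 1, 6).tolist(), rng.normal(0.8, 1, 5).tolist()
        res = anova_oneway({"a": a, "b": b})
        t, _ = stats.ttest_ind(a, b)
        assert res.f_statistic == pytest.approx(t**2, rel=1e-8)

    def test_significance_codes(self):
        assert [significance_code(p) for p in (0.5, 0.04, 0.005, 0.0005)] == [
            "ns", "*", "**", "***",
        ]

    def test_input_validation(self):
        with pytest.raises(ValueError, match="2 groups"):
            anova_oneway({"a": [1, 2]})
        with pytest.raises(ValueError, match="2 values"):
            anova_oneway({"a": [1, 2], "b": [1]})

    def test_summary_mentions_f_and_p(self):
        res = anova_oneway({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert "F =" in res.summary() and "p =" in res.summary()
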