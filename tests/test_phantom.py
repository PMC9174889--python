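"""Phantom generator: geometry, scenario, speckle-statistics and truth checks."""

import numpy as np
import pytest

from speckleflow.contrast import temporal_contrast
from speckleflow.phantom import (
    AcquisitionConfig,
    StrokeScenario,
    VesselSegment,
    apply_scenario,
    dose_recovery_scenario,
    integrated_contrast,
    make_beam_scene,
    make_flow_map,
    make_section_stack,
    short_term_scenario,
    simulate_speckle_stack,
)


class TestFlowMap:
    def test_uniform_parenchyma_tau(self):
        fmap = make_flow_map(8, 8, 0.1, parenchyma_speed=1.0, calibration_a=1.0)
        assert np.all(fmap.tau_c == 1.0)
        assert np.all(fmap.label == "parenchyma")

    def test_vessel_arithmetic(self):
        # horizontal vessel, width 0.1 mm, speed 4 over parenchyma speed 1, a=2
        seg = VesselSegment((0.5, 0.0), (0.5, 1.0), width_mm=0.1, speed=4.0)
        fmap = make_flow_map(10, 10, 0.1, [seg], parenchyma_speed=1.0, calibration_a=2.0)
        on = fmap.label == "large_vessel"
        assert on.any() and not on.all()
        assert np.allclose(fmap.tau_c[on], 0.5)
        assert np.allclose(fmap.tau_c[~on], 2.0)

    def test_spot_labels_core(self):
        fmap = make_flow_map(64, 64, 0.02, spot_center_mm=(0.64, 0.64), spot_diameter_mm=1.0)
        core = fmap.label == "core"
        # rasterized 1-mm disk area ~ pi * 25^2 px
        assert abs(core.sum() - np.pi * 25**2) / (np.pi * 25**2) < 0.04

    @pytest.mark.parametrize(
        "kwargs, err",
        [
            (dict(vessel_spec=[VesselSegment((0, 0), (0, 1), 99.0, 1.0)]), "wider"),
            (dict(vessel_spec=[VesselSegment((0, 0), (0, 1), 0.1, -1.0)]), "positive"),
            (dict(parenchyma_speed=0.0), "positive"),
        ],
    )
    def test_invalid_specs_raise(self, kwargs, err):
        with pytest.raises(ValueError, match=err):
            make_flow_map(10, 10, 0.1, **kwargs)


class TestScenario:
    def test_identity_at_t0(self):
        fmap = make_flow_map(16, 16, 0.02, spot_center_mm=(0.16, 0.16))
        out = apply_scenario(fmap, short_term_scenario(2.0), 0.0)
        np.testing.assert_array_equal(out.speed, fmap.speed)
        np.testing.assert_array_equal(out.tau_c, fmap.tau_c)

    def test_linear_interpolation(self):
        scen = short_term_scenario(2.0)  # core: 1 @ 0h, 0.5 @ 2h, 0.3 @ 6h
        assert scen.multiplier("core", 4.0) == pytest.approx(0.4)
        assert scen.multiplier("core", 2.0) == pytest.approx(0.5)

    def test_dose0_stays_near_baseline(self):
        fmap = make_flow_map(16, 16, 0.02, spot_center_mm=(0.16, 0.16))
        scen = short_term_scenario(0.0)
        for t in (0.0, 1.0, 3.0, 6.0):
            out = apply_scenario(fmap, scen, t)
            for lbl in np.unique(fmap.label):
                sel = fmap.label == lbl
                ratio = out.speed[sel].mean() / fmap.speed[sel].mean()
                assert 0.9 <= ratio <= 1.1

    def test_dose0_constructor_rejects_large_multipliers(self):
        with pytest.raises(ValueError, match="light-only"):
            StrokeScenario(0.0, {"core": [(0.0, 1.0), (2.0, 0.5)]})

    def test_time_outside_timeline_raises(self):
        with pytest.raises(ValueError, match="outside timeline"):
            short_term_scenario(2.0).multiplier("core", 7.0)

    def test_nonunit_multiplier_at_t0_rejected(self):
        with pytest.raises(ValueError, match="t=0"):
            StrokeScenario(2.0, {"core": [(0.0, 0.8), (2.0, 0.5)]})

    def test_recovery_course_endpoints(self):
        scen = dose_recovery_scenario(5.0)
        assert scen.multiplier("core", 1.0) == 0.0
        assert scen.multiplier("core", 14.0) == pytest.approx(0.64)


class TestSpeckleStatistics:
    def test_closed_form_contrast(self):
        """Ensemble temporal contrast matches the integrated-speckle K(x)."""
        x = 10.0
        fmap = make_flow_map(4, 4, 0.02, parenchyma_speed=1.0, calibration_a=20.0 / x)
        cfg = AcquisitionConfig(n_frames=2000, pixel_size=0.02, seed=3)
        stack = simulate_speckle_stack(fmap, cfg)
        k_emp = stack.frames.std(axis=0) / stack.frames.mean(axis=0)
        assert abs(k_emp.mean() / integrated_contrast(x) - 1.0) < 0.05

    def test_monotone_in_speed(self):
        """Faster flow -> lower expected Kt on a 5-point speed ladder."""
        ks = []
        for speed in (0.5, 1.0, 2.0, 4.0, 8.0):
            fmap = make_flow_map(8, 8, 0.02, parenchyma_speed=speed, calibration_a=2.0)
            stack = simulate_speckle_stack(fmap, AcquisitionConfig(n_frames=200, seed=11))
            ks.append(float(temporal_contrast(stack).kt.mean()))
        assert all(a > b for a, b in zip(ks, ks[1:]))

    def test_quasi_static_contrast_vanishes(self):
        """tau_c far beyond the acquisition span: frames nearly identical."""
        fmap = make_flow_map(4, 4, 0.02, parenchyma_speed=1e-6, calibration_a=1.0)
        assert np.all(fmap.tau_c == 200.0)  # residual-dynamics cap
        fmap.tau_c[:] = 1e8  # genuinely frozen-scale dynamics
        stack = simulate_speckle_stack(fmap, AcquisitionConfig(seed=5))
        kt = temporal_contrast(stack).kt
        assert np.nanmean(kt) < 0.02

    def test_frozen_frames_follow_exponential_law(self):
        """Frozen-within-frame, decorrelated-between-frames intensities are
        exponential: mean ~ std (fully developed speckle)."""
        fmap = make_flow_map(16, 16, 0.02, parenchyma_speed=1.0, calibration_a=1.0)
        cfg = AcquisitionConfig(n_frames=400, exposure_T=0.05, frame_interval=50.0, seed=9)
        I = simulate_speckle_stack(fmap, cfg).frames.ravel()
        assert abs(I.std() / I.mean() - 1.0) < 0.03
        # exponential quantile check: P(I > mean) = 1/e
        assert abs((I > I.mean()).mean() - np.exp(-1.0)) < 0.02

    def test_reproducible_given_seed(self):
        fmap = make_flow_map(8, 8, 0.02)
        cfg = AcquisitionConfig(n_frames=10, seed=42)
        a = simulate_speckle_stack(fmap, cfg).frames
        b = simulate_speckle_stack(fmap, cfg).frames
        np.testing.assert_array_equal(a, b)
        c = simulate_speckle_stack(fmap, AcquisitionConfig(n_frames=10, seed=43)).frames
        assert not np.array_equal(a, c)

    def test_undersampled_substep_raises(self):
        fmap = make_flow_map(4, 4, 0.02, parenchyma_speed=1.0, calibration_a=0.5)
        with pytest.raises(ValueError, match="undersample"):
            simulate_speckle_stack(fmap, AcquisitionConfig(seed=0), substep_ms=1.0)


class TestSectionStack:
    def test_zero_volume_has_no_infarct(self):
        st = make_section_stack(n_slices=5, target_volume_mm3=0.0, shape=(64, 64))
        assert all(m.sum() == 0 for m in st.truth_infarct_masks)
        assert st.truth_volume_mm3 == 0.0

    def test_truth_volume_matches_target_within_one_quantum(self):
        st = make_section_stack(
            n_slices=20, slice_spacing_h=100.0, pixel_size=0.02,
            shape=(256, 256), target_volume_mm3=10.0,
        )
        quantum = 0.02**2 * 0.1
        assert abs(st.truth_volume_mm3 - 10.0) <= quantum
        # exactness of the truth bookkeeping itself
        total = sum(int(m.sum()) for m in st.truth_infarct_masks)
        assert st.truth_volume_mm3 == total * quantum

    def test_density_truths_exact_at_pixel_resolution(self):
        st = make_section_stack(n_slices=2, pixel_size=0.02, shape=(256, 256),
                                density_truths=(0.12, 0.10))
        roi_px = 50  # 1 mm at 0.02 mm/px
        for dens, col in ((0.12, 64), (0.10, 192)):
            r0, c0 = 128 - roi_px // 2, col - roi_px // 2
            frac = st.vessel_channel[0][r0:r0 + roi_px, c0:c0 + roi_px].mean()
            assert frac == pytest.approx(round(dens * roi_px**2) / roi_px**2, abs=0)

    def test_unachievable_volume_raises(self):
        with pytest.raises(ValueError, match="unachievable"):
            make_section_stack(n_slices=3, shape=(32, 32), target_volume_mm3=1000.0)


class TestBeamScene:
    def test_tophat_half_radius_is_edge(self):
        scene = make_beam_scene("top-hat", radius_mm=0.5)
        assert scene.truth_half_radius_mm == 0.5

    def test_gaussian_half_radius_closed_form(self):
        s = 0.4926
        scene = make_beam_scene("gaussian", sigma_mm=s)
        assert scene.truth_half_radius_mm == pytest.approx(s * np.sqrt(2 * np.log(2)))
        assert scene.truth_half_radius_mm == pytest.approx(0.580, abs=1e-3)

    def test_total_power_configured(self):
        a = make_beam_scene("gaussian", total_power=1.0)
        b = make_beam_scene("gaussian", total_power=5.0)
        assert a.image.sum() == pytest.approx(1.0)
        assert b.image.sum() == pytest.approx(5.0)

    def test_unknown_profile_raises(self):
        with pytest.raises(ValueError, match="unknown profile"):
            make_beam_scene("bessel")
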