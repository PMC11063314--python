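"""Scaling profiles, extremal directions, demixing and the per-trial pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ofsca import (
    AngularFluctuation,
    ComponentSpec,
    CopTrajectory,
    ScaleGrid,
    ScalingProfile,
    analyze_trial,
    component_directions,
    default_angle_grid,
    delta_theta,
    find_extremal_angles,
    generate_trial,
    mix_components,
    reconstruct_components,
    scaling_profile,
    sd_h,
)

ANGLES = default_angle_grid()


def _profile(hurst):
    return ScalingProfile(
        angles=ANGLES,
        hurst=np.asarray(hurst, float),
        local_slopes=np.zeros((ANGLES.size, 1)),
        fit_range=(1.5, 2.0),
    )


class TestScalingProfile:
    def test_exact_power_law_gives_constant_exponent(self):
        grid = ScaleGrid(windows=np.array([89, 115, 149, 193, 249]), order=4)
        F = np.tile(3.0 * grid.scales_eff**0.7, (ANGLES.size, 1))
        prof = scaling_profile(AngularFluctuation(ANGLES, grid, F))
        assert np.allclose(prof.hurst, 0.7, atol=1e-12)

    def test_too_few_scales_in_range_rejected(self):
        grid = ScaleGrid(windows=np.array([99, 179]), order=4)
        F = np.ones((ANGLES.size, 2))
        with pytest.raises(ValueError, match="scale points"):
            scaling_profile(AngularFluctuation(ANGLES, grid, F))


class TestExtremalAngles:
    def test_constructed_cosine_squared_profile(self):
        h = 0.8 - 0.2 * np.cos(ANGLES - np.radians(30.0)) ** 2
        ext = find_extremal_angles(_profile(h))
        assert not ext.degenerate
        assert ext.theta_min_deg == pytest.approx(30.0, abs=0.6)
        assert ext.theta_max_deg == pytest.approx(120.0, abs=0.6)
        assert ext.h1 == pytest.approx(0.8, abs=1e-3)
        assert ext.h2 == pytest.approx(0.6, abs=1e-3)

    def test_constant_profile_is_flagged_degenerate(self):
        ext = find_extremal_angles(_profile(np.full(ANGLES.size, 0.7)))
        assert ext.degenerate
        assert np.isnan(ext.theta_max_deg)

    @pytest.mark.parametrize("peak_deg", [2.0, 178.0])
    def test_wraparound_extrema_near_the_axial_seam(self, peak_deg):
        # single circular harmonic: unique max at peak_deg, min 90 deg away,
        # with the max lying a couple of grid steps from the 0/180 seam
        h = 0.7 + 0.1 * np.cos(2.0 * (ANGLES - np.radians(peak_deg)))
        ext = find_extremal_angles(_profile(h))
        step = np.degrees(np.pi / 179)
        err_max = min(abs(ext.theta_max_deg - peak_deg), 180 - abs(ext.theta_max_deg - peak_deg))
        expected_min = (peak_deg + 90.0) % 180.0
        err_min = min(abs(ext.theta_min_deg - expected_min), 180 - abs(ext.theta_min_deg - expected_min))
        assert err_max <= step and err_min <= step

    def test_smoothing_suppresses_single_point_spikes(self):
        h = np.full(ANGLES.size, 0.6)
        h[50:90] = 0.8  # broad plateau
        h[10] = 0.95  # single-point artefact
        raw = find_extremal_angles(_profile(h))
        smoothed = find_extremal_angles(_profile(h), smoothing=True)
        assert raw.theta_max_deg == pytest.approx(np.degrees(ANGLES[10]))
        assert 45.0 < smoothed.theta_max_deg < 95.0


class TestDirectionsAndDelta:
    def test_component_axes_are_orthogonal_flips(self):
        assert component_directions(120.0, 30.0) == (120.0, 30.0)
        assert component_directions(90.0, 0.0) == (90.0, 0.0)

    def test_delta_theta_folds_axially(self):
        assert delta_theta(83.0, 1.0) == pytest.approx(82.0)
        assert delta_theta(105.0, 8.0) == pytest.approx(83.0)  # 97 folds to 83
        assert delta_theta(42.0, 42.0) == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(a=st.floats(0.0, 180.0, exclude_max=True), b=st.floats(0.0, 180.0, exclude_max=True))
    def test_delta_theta_is_a_symmetric_axial_metric(self, a, b):
        d = delta_theta(a, b)
        assert 0.0 <= d <= 90.0
        assert d == pytest.approx(delta_theta(b, a))
        assert delta_theta((a + 90.0) % 180.0, (b + 90.0) % 180.0) == pytest.approx(d, abs=1e-9)

    @settings(max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_sd_h_matches_brute_force_definition(self, seed):
        h = np.random.default_rng(seed).uniform(0.3, 1.0, ANGLES.size)
        prof = _profile(h)
        brute = np.sqrt(np.sum((h - h.mean()) ** 2) / h.size)
        assert sd_h(prof) == pytest.approx(brute, abs=1e-12)


class TestReconstruction:
    def test_orthogonal_unmixing_returns_the_axes(self, rng):
        ml, ap = rng.standard_normal((2, 128))
        traj = CopTrajectory(ml, ap)
        e1, e2 = reconstruct_components(traj, 90.0, 0.0)
        assert np.allclose(e1, ap)
        assert np.allclose(e2, ml)

    def test_round_trip_through_oblique_mixing(self, rng):
        e1, e2 = np.cumsum(rng.standard_normal((2, 500)), axis=1)
        s1 = ComponentSpec(0.9, 90.0, amplitude=1.7)
        s2 = ComponentSpec(0.6, 30.0, amplitude=0.4)  # delta-theta 60 deg
        traj = mix_components(e1, e2, s1, s2)
        r1, r2 = reconstruct_components(traj, 90.0, 30.0)
        assert np.allclose(r1, 1.7 * e1, rtol=1e-9)
        assert np.allclose(r2, 0.4 * e2, rtol=1e-9)

    def test_near_collinear_axes_rejected(self, rng):
        traj = CopTrajectory(*rng.standard_normal((2, 32)))
        with pytest.raises(ValueError, match="singular"):
            reconstruct_components(traj, 45.0, 45.0001)


class TestAnalyzeTrial:
    def test_zero_input_is_degenerate_with_no_angles(self):
        res = analyze_trial(CopTrajectory(np.zeros(2000), np.zeros(2000)))
        assert res.degenerate
        assert np.isnan(res.theta1_deg) and np.isnan(res.delta_theta_deg)

    def test_result_satisfies_orthogonality_relations(self, standard_trial):
        res = analyze_trial(standard_trial)
        assert res.theta1_deg == pytest.approx((res.theta_min_deg + 90.0) % 180.0)
        assert res.theta2_deg == pytest.approx((res.theta_max_deg + 90.0) % 180.0)
        assert res.h1 >= res.h2
        assert 0.0 <= res.delta_theta_deg <= 90.0

    def test_rotation_equivariance_of_the_full_pipeline(self, standard_trial):
        res = analyze_trial(standard_trial, reconstruct=False)
        step_deg = np.degrees(np.pi / 179)
        phi = 40 * step_deg
        res_rot = analyze_trial(standard_trial.rotated(phi), reconstruct=False)
        d1 = delta_theta(res_rot.theta1_deg, (res.theta1_deg + phi) % 180.0)
        d2 = delta_theta(res_rot.theta2_deg, (res.theta2_deg + phi) % 180.0)
        assert d1 <= step_deg and d2 <= step_deg
        assert res_rot.delta_theta_deg == pytest.approx(res.delta_theta_deg, abs=2 * step_deg)
        assert res_rot.h1 == pytest.approx(res.h1, abs=1e-6)
        assert res_rot.h2 == pytest.approx(res.h2, abs=1e-6)
        assert res_rot.sd_h == pytest.approx(res.sd_h, abs=1e-6)

    def test_amplitude_scaling_leaves_every_exponent_and_angle_unchanged(
        self, standard_trial
    ):
        res = analyze_trial(standard_trial)
        scaled = CopTrajectory(
            7.3 * standard_trial.ml,
            7.3 * standard_trial.ap,
            standard_trial.sampling_rate,
        )
        res_s = analyze_trial(scaled)
        assert res_s.theta1_deg == res.theta1_deg
        assert res_s.theta2_deg == res.theta2_deg
        assert res_s.delta_theta_deg == res.delta_theta_deg
        assert res_s.h1 == pytest.approx(res.h1, abs=1e-9)
        assert res_s.h2 == pytest.approx(res.h2, abs=1e-9)
        assert res_s.sd_h == pytest.approx(res.sd_h, abs=1e-9)
        # components scale with the trajectory
        assert np.allclose(res_s.eps1_hat, 7.3 * res.eps1_hat, rtol=1e-9)

    def test_mean_recovered_delta_increases_with_true_delta(self):
        """Monotone response: larger true axis separation, larger estimate."""
        means = []
        for true_delta in (30.0, 45.0, 60.0, 75.0, 90.0):
            vals = []
            for seed in range(20):
                traj = generate_trial(
                    ComponentSpec(0.9, 90.0),
                    ComponentSpec(0.6, 90.0 - true_delta),
                    seed=seed,
                )
                vals.append(analyze_trial(traj, reconstruct=False).delta_theta_deg)
            means.append(np.mean(vals))
        assert np.all(np.diff(means) >= 0.0)
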