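"""Generators: stationary statistics, ground truth, reproducibility."""

import numpy as np
import pytest

from memfluct.constants import K_B
from memfluct.synthetic import (
    GroundTruth,
    MembraneSimParams,
    OpticsConfig,
    irm_intensity,
    render_irm_movie,
    render_linescan,
    render_puncta_pair,
    simulate_area_decay,
    simulate_membrane_patch,
    simulate_trap_trace,
    simulate_two_temperature_beads,
    stationary_pixel_variance,
    two_bead_entropy_rate,
)


class TestMembranePatch:
    def test_zero_activity_freezes_the_membrane(self):
        p = MembraneSimParams(active_A=0.0, n_frames=256, seed=0,
                              domain_side=3.4656, n_modes_per_axis=48)
        mv = simulate_membrane_patch(p)
        assert np.allclose(mv.h, mv.h[0])
        assert mv.h.std(axis=0).max() == pytest.approx(0.0, abs=1e-12)

    def test_mean_height_is_preserved(self, small_membrane_params):
        mv = simulate_membrane_patch(small_membrane_params)
        assert mv.h.mean() == pytest.approx(
            small_membrane_params.mean_height, rel=1e-6)

    def test_pixel_variance_matches_mode_sum(self):
        """Stationary single-pixel variance equals the closed-form sum of
        A k_B T / (L^2 (kappa q^4 + sigma q^2 + gamma)) over the mode grid,
        within 5% (median over 10 seeds)."""
        p0 = MembraneSimParams(domain_side=3.4656, n_modes_per_axis=48,
                               n_frames=1024)
        expected = stationary_pixel_variance(p0)
        ratios = []
        for s in range(10):
            p = MembraneSimParams(domain_side=3.4656, n_modes_per_axis=48,
                                  n_frames=1024, seed=s)
            mv = simulate_membrane_patch(p)
            ratios.append(np.mean(np.var(mv.h, axis=0)) / expected)
        assert abs(np.median(ratios) - 1.0) < 0.05

    def test_reproducible_for_identical_seed(self, small_membrane_params):
        a = simulate_membrane_patch(small_membrane_params)
        b = simulate_membrane_patch(small_membrane_params)
        assert np.array_equal(a.h, b.h)

    def test_different_seed_differs(self, small_membrane_params):
        import dataclasses
        other = dataclasses.replace(small_membrane_params, seed=99)
        a = simulate_membrane_patch(small_membrane_params)
        b = simulate_membrane_patch(other)
        assert not np.allclose(a.h, b.h)

    def test_thinning_invariance_of_stationary_variance(self):
        """Statistics are set by the exact OU update, not the frame rate."""
        vars_ = []
        for rate in (10.0, 40.0):
            acc = 0.0
            for s in range(5):
                p = MembraneSimParams(domain_side=3.4656,
                                      n_modes_per_axis=48, frame_rate=rate,
                                      n_frames=1024, seed=s)
                acc += np.mean(np.var(simulate_membrane_patch(p).h, axis=0))
            vars_.append(acc / 5)
        assert vars_[0] == pytest.approx(vars_[1], rel=0.1)

    def test_store_window_crops_but_matches_dynamics(self):
        p = MembraneSimParams(domain_side=3.4656, n_modes_per_axis=48,
                              n_frames=256, seed=3)
        full = simulate_membrane_patch(p)
        crop = simulate_membrane_patch(p, store_window=(10, 20, 12))
        assert crop.h.shape == (256, 12, 12)
        assert np.allclose(crop.h, full.h[:, 10:22, 20:32])

    @pytest.mark.parametrize("bad", [
        dict(frame_rate=0.0), dict(n_modes_per_axis=1),
        dict(sigma_true=-1e-9), dict(eta_eff=0.0)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            MembraneSimParams(**bad)

    def test_too_few_frames_rejected(self):
        p = MembraneSimParams(n_frames=260)
        p.n_frames = 100  # bypass ctor check to hit the simulator guard
        with pytest.raises(ValueError):
            simulate_membrane_patch(p)


class TestIRMRendering:
    def test_contact_is_darkest(self, default_optics):
        o = default_optics
        assert irm_intensity(0.0, o) == pytest.approx(
            o.intensity_offset - o.intensity_amplitude)

    def test_first_branch_maximum_at_quarter_wavelength(self, default_optics):
        o = default_optics
        h_max = o.wavelength / (4 * o.refractive_index)
        assert irm_intensity(h_max, o) == pytest.approx(
            o.intensity_offset + o.intensity_amplitude)

    def test_periodic_in_height(self, default_optics):
        o = default_optics
        period = o.wavelength / (2 * o.refractive_index)
        h = np.linspace(0, 90, 10)
        assert np.allclose(irm_intensity(h, o), irm_intensity(h + period, o))

    def test_camera_noise_reproducible(self, small_membrane_params):
        mv = simulate_membrane_patch(small_membrane_params)
        o = OpticsConfig(camera_noise_sd=2.0)
        assert np.array_equal(render_irm_movie(mv, o, seed=5),
                              render_irm_movie(mv, o, seed=5))


class TestTrapTrace:
    def test_equipartition_variance(self):
        """Var(x) -> k_B T / k; at k = 1e-5 N/m, T = 300 K the stationary
        variance is 4.141e-16 m^2."""
        tr = simulate_trap_trace(1e-5, temperature=300.0, n_samples=200_000,
                                 seed=0)
        assert np.var(tr.x) == pytest.approx(4.141e-16, rel=0.03)

    def test_zero_temperature_is_constant(self):
        tr = simulate_trap_trace(1e-5, temperature=1e-30, n_samples=1000,
                                 seed=0)
        assert np.ptp(tr.x) < 1e-15

    def test_plateau_shifts_mean_by_force_over_k(self):
        F, k = 7.0, 1e-5
        tr = simulate_trap_trace(k, n_samples=100_000, seed=1,
                                 plateau_force_pN=F,
                                 plateau_window_s=(300.0, 500.0))
        t = np.arange(tr.x.size) / tr.sample_rate
        sel = (t >= 300) & (t <= 500)
        assert np.mean(tr.x[sel]) == pytest.approx(F * 1e-12 / k, rel=0.05)


class TestPunctaPair:
    def test_single_square_area_fraction(self):
        _, _, gt = render_puncta_pair(
            [{"center": (49.5, 49.5), "half_side": 4.6}], [], (100, 100))
        assert gt.values["area_px_a"] == 100
        assert gt.values["area_fraction_a"] == pytest.approx(0.01)

    def test_identical_channels_full_overlap(self):
        objs = [{"center": (30, 30), "radius": 6}]
        _, _, gt = render_puncta_pair(objs, objs)
        assert gt.values["overlap_px"] == gt.values["area_px_a"]

    def test_disjoint_channels_no_overlap(self):
        a = [{"center": (20, 20), "radius": 5}]
        b = [{"center": (80, 80), "radius": 5}]
        _, _, gt = render_puncta_pair(a, b)
        assert gt.values["overlap_px"] == 0

    def test_within_channel_merging(self):
        """Two overlapping discs count by their union area."""
        a = [{"center": (50, 48), "radius": 5},
             {"center": (50, 52), "radius": 5}]
        _, _, gt = render_puncta_pair(a, [])
        single = render_puncta_pair([a[0]], [])[2].values["area_px_a"]
        assert gt.values["area_px_a"] < 2 * single


class TestLinescan:
    def test_flat_baseline_no_peaks(self):
        pos, y, gt = render_linescan([], baseline=5.0, noise_sd=0.0)
        assert gt.values["n_qualifying_peaks"] == 0
        assert np.allclose(y, 5.0)

    def test_qualifying_peak_count(self):
        peaks = [(0.5, 10, 0.15), (1.5, 10, 0.15), (2.5, 10, 0.15),
                 (3.2, 3, 0.15), (3.7, 3, 0.15)]
        _, _, gt = render_linescan(peaks, count_thresholds=(6.0, 5.0))
        assert gt.values["n_qualifying_peaks"] == 3

    def test_zero_noise_reproduces_analytic_profile(self):
        peaks = [(2.0, 8.0, 0.2)]
        pos, y, _ = render_linescan(peaks, baseline=3.0, noise_sd=0.0)
        expected = 3.0 + 8.0 * np.exp(-0.5 * ((pos - 2.0) / 0.2) ** 2)
        assert np.allclose(y, expected)

    def test_out_of_range_peak_rejected(self):
        with pytest.raises(ValueError):
            render_linescan([(5.0, 10, 0.1)], length_um=4.0)


class TestAreaDecay:
    def test_t67_matches_analytic_inversion(self):
        _, _, gt = simulate_area_decay(tau_min=10.0, pre_plateau_min=5.0)
        assert gt.values["t67_min"] - 5.0 == pytest.approx(
            10.0 * np.log(1 / 0.67), rel=1e-9)

    def test_zero_noise_series_monotone_non_increasing(self):
        _, a, _ = simulate_area_decay(noise_sd=0.0)
        assert np.all(np.diff(a) <= 1e-12)

    def test_plateau_clips_the_decay(self):
        _, a, _ = simulate_area_decay(A0=1000.0, final_fraction=0.3,
                                      total_min=200.0)
        assert a.min() == pytest.approx(300.0)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            simulate_area_decay(final_fraction=1.5)


class TestTwoTemperatureBeads:
    def test_equal_temperatures_zero_entropy_rate(self):
        rate = two_bead_entropy_rate(1.0, 1.0, 1.0, 300.0, 300.0)
        assert abs(rate) < 1e-12

    def test_rate_symmetric_under_temperature_swap(self):
        r12 = two_bead_entropy_rate(1.0, 0.5, 1.0, 250.0, 350.0)
        r21 = two_bead_entropy_rate(1.0, 0.5, 1.0, 350.0, 250.0)
        assert r12 == pytest.approx(r21, rel=1e-10)
        assert r12 > 0

    def test_analytic_rate_matches_empirical_heat_flux(self):
        """Brute-force trajectory thermodynamics: the Stratonovich heat into
        each bath, divided by its temperature, averages to the
        Lyapunov-equation entropy rate within 5%."""
        k, kc, drag = 1.0, 1.0, 1.0
        T1, T2 = 1.0 / K_B, 4.0 / K_B
        dt = 0.01
        x, rate = simulate_two_temperature_beads(k, kc, drag, T1, T2,
                                                 dt=dt, n=400_000, seed=42)
        dx = np.diff(x, axis=0)
        xm = 0.5 * (x[1:] + x[:-1])
        f1 = -(k + kc) * xm[:, 0] + kc * xm[:, 1]   # force on bead 1
        f2 = -(k + kc) * xm[:, 1] + kc * xm[:, 0]
        # Stratonovich work of the conservative force along each bead's
        # path; in steady state it is dissipated into that bead's bath
        heat1 = np.sum(f1 * dx[:, 0])
        heat2 = np.sum(f2 * dx[:, 1])
        total_time = dt * (x.shape[0] - 1)
        empirical = (heat1 / T1 + heat2 / T2) / K_B / total_time
        assert empirical == pytest.approx(rate, rel=0.05)


class TestGroundTruth:
    def test_round_trip_through_json(self, tmp_path):
        gt = GroundTruth("demo", {"sigma": 5e-7, "count": 3,
                                  "arr": [1.0, 2.0]})
        path = tmp_path / "gt.json"
        gt.to_json(path)
        back = GroundTruth.from_json(path)
        assert back.artifact == gt.artifact
        assert back.values == gt.values
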