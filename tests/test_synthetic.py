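"""Synthetic trajectory, image-stack, and nuclei generators."""

import numpy as np
import pytest

from atckit.acoustics import BubbleGeom, PulseTrain
from atckit.synthetic import (KVParams, NucleiSceneSpec, SceneSpec,
                              default_calibration, kv_trajectory,
                              peak_residual_recursion, render_frames,
                              render_nuclei_image, simulate_scene)


class TestDefaultCalibration:
    def test_5pct_parameters(self):
        kv = default_calibration(0.05)
        assert kv.tau == pytest.approx(0.5776, abs=2e-4)
        assert kv.x_inf == pytest.approx(15.037, abs=5e-3)

    def test_50pct_parameters(self):
        kv = default_calibration(0.50)
        assert kv.tau == pytest.approx(1.0696, abs=2e-4)
        assert kv.x_inf == pytest.approx(8.842, abs=5e-3)

    def test_unsupported_duty_raises(self):
        with pytest.raises(KeyError):
            default_calibration(0.25)

    @pytest.mark.parametrize("duty,peak,resid",
                             [(0.05, 1.45, 0.28), (0.50, 4.74, 2.97)])
    def test_calibration_reproduces_measured_five_pulse_means(
            self, duty, peak, resid):
        """Forward recursion of the calibrated model returns the measured
        five-pulse mean peak and residual exactly."""
        kv = default_calibration(duty)
        train = PulseTrain.constant(1.0, duty, 5)
        peaks, residuals = peak_residual_recursion(kv, train)
        assert peaks.mean() == pytest.approx(peak, rel=1e-9)
        assert residuals.mean() == pytest.approx(resid, rel=1e-9)


class TestKVTrajectory:
    def test_first_pulse_peak_closed_form(self, kv_5pct, train_5pct):
        # x_inf*(1 - exp(-t_on/tau)) ≈ 1.247 µm
        traj = kv_trajectory(kv_5pct, train_5pct, 5.0, 1000.0)
        on_mask = traj.t < 0.05
        expected = kv_5pct.x_inf * (1 - np.exp(-0.05 / kv_5pct.tau))
        assert expected == pytest.approx(1.247, abs=1e-3)
        # last on-phase sample is one sample before the analytic peak
        peak_sampled = traj.x[traj.t < 0.05 + 1e-9].max()
        assert peak_sampled == pytest.approx(expected, rel=2e-3)

    def test_creep_limit_under_continuous_force(self):
        kv = KVParams(tau=0.3, x_inf=5.0)
        train = PulseTrain.constant(1.0, 1.0, 10)    # duty 1: force held on
        traj = kv_trajectory(kv, train, 10.0, 100.0)
        assert traj.x[-1] == pytest.approx(5.0, rel=1e-4)
        assert np.all(np.diff(traj.x) >= -1e-12)

    def test_zero_pressure_train_is_identically_zero(self, kv_5pct):
        train = PulseTrain.constant(1.0, 0.5, 5, pressure=0.0)
        traj = kv_trajectory(kv_5pct, train, 5.0, 100.0)
        np.testing.assert_array_equal(traj.x, 0.0)

    @pytest.mark.parametrize("rate", [1000.0, 2000.0, 5000.0])
    def test_matches_recursion_at_any_sample_rate(self, kv_50pct,
                                                  train_50pct, rate):
        """Per-pulse peaks/residuals of the sampled record match the linear
        recursion to numerical tolerance for all rates >= 1 kHz."""
        traj = kv_trajectory(kv_50pct, train_50pct, 5.0, rate)
        peaks_ref, resid_ref = peak_residual_recursion(kv_50pct, train_50pct)
        for k in range(5):
            m = (traj.t >= k) & (traj.t < k + 1)
            assert traj.x[m].max() == pytest.approx(peaks_ref[k], rel=5e-3)
            assert traj.x[m][-1] == pytest.approx(resid_ref[k], rel=5e-3)

    def test_peaks_nondecreasing_and_converge_to_fixed_point(self, kv_50pct):
        train = PulseTrain.constant(1.0, 0.5, 40)
        peaks, _ = peak_residual_recursion(kv_50pct, train)
        assert np.all(np.diff(peaks) >= 0)
        a = np.exp(-train.on_time / kv_50pct.tau)
        b = np.exp(-train.off_time / kv_50pct.tau)
        p_star = kv_50pct.x_inf * (1 - a) / (1 - a * b)
        assert peaks[-1] == pytest.approx(p_star, rel=1e-6)

    def test_undersampled_request_raises(self, kv_5pct, train_5pct):
        with pytest.raises(ValueError, match="undersamples"):
            kv_trajectory(kv_5pct, train_5pct, 5.0, sample_rate=10.0)

    def test_secondary_creep_and_plasticity_terms(self):
        kv = KVParams(tau=0.5, x_inf=3.0, beta=1.0, plastic_fraction=0.2)
        train = PulseTrain.constant(1.0, 0.5, 3)
        traj = kv_trajectory(kv, train, 3.0, 1000.0)
        # residual floor never recovers below the locked-in displacement
        lin = kv_trajectory(KVParams(tau=0.5, x_inf=3.0), train, 3.0, 1000.0)
        assert traj.x[-1] > lin.x[-1]


class TestSimulateScene:
    def test_single_bubble_reduces_to_1d_case(self, kv_50pct, train_50pct):
        spec = SceneSpec(bubbles=[BubbleGeom("b", (5.0, 7.0), 2.0)],
                         kv_params=kv_50pct, noise_sd=0.0, frame_rate=100.0)
        trajs, truth = simulate_scene(spec, train_50pct, 5.0)
        ref = kv_trajectory(kv_50pct, train_50pct, 5.0, 100.0)
        np.testing.assert_allclose(trajs[0].x - 5.0, ref.x, atol=1e-12)
        np.testing.assert_allclose(trajs[0].y, 7.0, atol=1e-12)

    def test_same_seed_bit_reproducible(self, kv_50pct, train_50pct):
        spec = SceneSpec(bubbles=[BubbleGeom("b", (5.0, 7.0), 2.0)],
                         kv_params=kv_50pct, noise_sd=0.2, frame_rate=100.0,
                         rng_seed=42)
        t1, g1 = simulate_scene(spec, train_50pct, 5.0)
        t2, g2 = simulate_scene(spec, train_50pct, 5.0)
        np.testing.assert_array_equal(t1[0].x, t2[0].x)
        assert g1.equals(g2)

    def test_coupling_deviates_directions_from_primary(self, kv_50pct,
                                                       train_50pct):
        from atckit.acoustics import net_force_direction, \
            primary_radiation_force
        bubbles = [BubbleGeom("a", (8.0, 10.0), 2.0),
                   BubbleGeom("b", (8.0, 18.0), 2.0)]
        spec = SceneSpec(bubbles=bubbles, kv_params=kv_50pct, noise_sd=0.0,
                         frame_rate=100.0, bjerknes_coupling=-1e-3)
        trajs, truth = simulate_scene(spec, train_50pct, 5.0)
        # recompute expected directions independently from the force vectors
        fp = [primary_radiation_force(spec.acoustic, b.radius)
              for b in bubbles]
        expected = net_force_direction(bubbles, (1.0, 0.0), fp, -1e-3)
        got = truth.groupby("bubble_id")[["dir_x", "dir_y"]].first()
        np.testing.assert_allclose(got.loc["a"], expected[0], rtol=1e-9)
        assert abs(expected[0][1]) > 1e-3     # genuinely deviated
        # the y-coordinate actually moves for a coupled bubble
        assert np.ptp(trajs[0].y) > 1e-3

    def test_overlapping_bubbles_rejected(self, kv_50pct, train_50pct):
        spec = SceneSpec(bubbles=[BubbleGeom("a", (5.0, 5.0), 2.0),
                                  BubbleGeom("b", (5.0, 8.0), 2.0)],
                         kv_params=kv_50pct, frame_rate=100.0)
        with pytest.raises(ValueError, match="overlap"):
            simulate_scene(spec, train_50pct, 5.0)

    def test_radius_decay(self, kv_50pct, train_50pct):
        spec = SceneSpec(bubbles=[BubbleGeom("b", (5.0, 7.0), 2.0)],
                         kv_params=kv_50pct, noise_sd=0.0, frame_rate=100.0,
                         radius_decay_rate=0.002)
        trajs, _ = simulate_scene(spec, train_50pct, 5.0)
        assert trajs[0].radius[-1] == pytest.approx(
            2.0 * np.exp(-0.002 * trajs[0].t[-1]), rel=1e-12)


class TestRenderFrames:
    def test_static_bubble_argmax_at_center(self):
        spec = SceneSpec(bubbles=[], kv_params=KVParams(1.0, 1.0),
                         fov_px=(41, 41), image_noise_sd=0.0)
        from atckit.trajectory import Trajectory
        traj = Trajectory("b", t=[0.0], x=[6.6], y=[3.3],
                          radius=np.array([2.0]))
        stack = render_frames([traj], spec)
        r, c = np.unravel_index(np.argmax(stack[0]), stack[0].shape)
        assert abs(c - 6.6 / 0.33) <= 1 and abs(r - 3.3 / 0.33) <= 1

    def test_brightness_additive_in_bubble_count(self):
        from atckit.trajectory import Trajectory
        spec = SceneSpec(bubbles=[], kv_params=KVParams(1.0, 1.0),
                         fov_px=(64, 64), image_noise_sd=0.0)
        t1 = Trajectory("a", t=[0.0], x=[5.0], y=[5.0], radius=np.array([2.0]))
        t2 = Trajectory("b", t=[0.0], x=[15.0], y=[15.0],
                        radius=np.array([2.0]))
        one = render_frames([t1], spec).astype(float)
        two = render_frames([t1, t2], spec).astype(float)
        excess_one = one.sum() - 100.0 * 64 * 64
        excess_two = two.sum() - 100.0 * 64 * 64
        assert excess_two == pytest.approx(2 * excess_one, rel=2e-2)

    def test_out_of_view_bubble_warns(self):
        from atckit.trajectory import Trajectory
        spec = SceneSpec(bubbles=[], kv_params=KVParams(1.0, 1.0),
                         fov_px=(32, 32))
        traj = Trajectory("b", t=[0.0], x=[-50.0], y=[5.0],
                          radius=np.array([2.0]))
        with pytest.warns(UserWarning, match="field of view"):
            render_frames([traj], spec)


class TestRenderNuclei:
    def test_all_positive_by_construction(self):
        scene = render_nuclei_image(NucleiSceneSpec(
            n_nuclei=12, fraction_yap_positive=1.0, noise_sd=0.0))
        assert (scene.truth["nuclear_cyto_ratio"] >= 1.1).all()
        assert scene.truth["yap_positive"].all()

    def test_positive_fraction_exact_count(self):
        scene = render_nuclei_image(NucleiSceneSpec(
            n_nuclei=20, fraction_yap_positive=0.6, noise_sd=0.0))
        assert scene.truth["yap_positive"].sum() == 12

    def test_zero_nuclei_empty_mask(self):
        scene = render_nuclei_image(NucleiSceneSpec(n_nuclei=0))
        assert scene.labels.max() == 0
        assert len(scene.truth) == 0

    def test_flat_marker_normalization_arithmetic(self):
        """With the marker equal to DAPI everywhere, the normalized nuclear
        marker equals dapi_level / image-mean DAPI, computable from levels."""
        spec = NucleiSceneSpec(n_nuclei=9, noise_sd=0.0,
                               nuclear_marker_level=200.0,
                               cytoplasmic_marker_level=200.0 / 1.2,
                               dapi_level=200.0, background_level=20.0)
        scene = render_nuclei_image(spec)
        from atckit.imagequant import quantify_marker
        recs = quantify_marker(scene.dapi, scene.labels, scene.dapi)
        expected = 200.0 / scene.dapi.mean()
        for r in recs:
            assert r.normalized_marker == pytest.approx(expected, rel=1e-9)

    def test_seeded_determinism(self):
        spec = NucleiSceneSpec(n_nuclei=6, noise_sd=5.0, rng_seed=3)
        s1, s2 = render_nuclei_image(spec), render_nuclei_image(spec)
        np.testing.assert_array_equal(s1.dapi, s2.dapi)
        np.testing.assert_array_equal(s1.marker, s2.marker)
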