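"""Spot detection, linking (vs brute-force assignment oracle), calibration."""

import itertools

import numpy as np
import pandas as pd
import pytest

from atckit.synthetic import KVParams, SceneSpec, render_frames
from atckit.tracking import (Detection, detect_spots, link, radius_series,
                             to_physical)
from atckit.trajectory import Trajectory


def _spots_frame(centers, fov=(64, 64), radius_um=2.0):
    """Render one noise-free frame with Gaussian spots at µm positions."""
    spec = SceneSpec(bubbles=[], kv_params=KVParams(1.0, 1.0), fov_px=fov,
                     image_noise_sd=0.0)
    trajs = [Trajectory(f"s{i}", t=[0.0], x=[x], y=[y],
                        radius=np.array([radius_um]))
             for i, (x, y) in enumerate(centers)]
    return render_frames(trajs, spec)[0], spec.pixel_size


class TestDetectSpots:
    def test_blank_frame_empty(self):
        assert detect_spots(np.zeros((32, 32)), 9) == []

    def test_three_spots_subpixel_accuracy(self):
        centers = [(5.3, 6.1), (14.8, 5.2), (10.1, 15.6)]
        frame, px = _spots_frame(centers)
        dets = detect_spots(frame, 13, min_mass=5000)
        assert len(dets) == 3
        errs = []
        for (x_um, y_um) in centers:
            cx, cy = x_um / px, y_um / px
            d = min(dets, key=lambda d: (d.x - cx) ** 2 + (d.y - cy) ** 2)
            errs.append(np.hypot(d.x - cx, d.y - cy))
        assert np.sqrt(np.mean(np.square(errs))) < 0.2

    def test_close_pair_merges_to_one_detection(self):
        # centers 1.2 µm apart ≈ 3.6 px < expected_diameter
        frame, _ = _spots_frame([(8.0, 8.0), (9.2, 8.0)])
        dets = detect_spots(frame, 13, min_mass=5000)
        assert len(dets) == 1

    def test_min_mass_filters_dim_spots(self):
        frame, _ = _spots_frame([(8.0, 8.0)])
        assert detect_spots(frame, 13, min_mass=1e9) == []

    def test_non_finite_pixels_rejected(self):
        frame = np.zeros((16, 16))
        frame[5, 5] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            detect_spots(frame, 9)

    def test_even_diameter_rejected(self):
        with pytest.raises(ValueError):
            detect_spots(np.zeros((16, 16)), 8)


def _dets(frame, positions):
    return [Detection(frame=frame, x=float(x), y=float(y), mass=1.0, size=1.0)
            for x, y in positions]


def link_bruteforce(dets_per_frame, max_disp, memory=0):
    """Exhaustive per-frame minimum-cost assignment oracle (<=4 spots).

    Mirrors the augmented-assignment semantics: matching costs squared
    displacement (within the gate) and each unmatched track or detection
    costs gate^2.
    """
    gate2 = max_disp ** 2
    tracks = []     # dicts: frames, pts, last_frame
    for f, dets in enumerate(dets_per_frame):
        active = [tr for tr in tracks if f - tr["last"] <= memory + 1]
        best, best_cost = None, np.inf
        n, m = len(active), len(dets)
        for k in range(min(n, m) + 1):
            for track_idx in itertools.combinations(range(n), k):
                for det_idx in itertools.permutations(range(m), k):
                    cost, ok = 0.0, True
                    for i, j in zip(track_idx, det_idx):
                        d2 = ((active[i]["pts"][-1][0] - dets[j].x) ** 2
                              + (active[i]["pts"][-1][1] - dets[j].y) ** 2)
                        if d2 > gate2:
                            ok = False
                            break
                        cost += d2
                    if not ok:
                        continue
                    cost += gate2 * ((n - k) + (m - k))
                    if cost < best_cost - 1e-12:
                        best_cost, best = cost, (track_idx, det_idx)
        matched = set()
        if best is not None:
            for i, j in zip(*best):
                active[i]["frames"].append(f)
                active[i]["pts"].append((dets[j].x, dets[j].y))
                active[i]["last"] = f
                matched.add(j)
        for j, d in enumerate(dets):
            if j not in matched:
                tracks.append({"frames": [f], "pts": [(d.x, d.y)], "last": f})
    return sorted(tuple(zip(tr["frames"],
                            [p[0] for p in tr["pts"]],
                            [p[1] for p in tr["pts"]]))
                  for tr in tracks)


def _as_tuples(track_frames):
    out = []
    for df in track_frames:
        out.append(tuple(zip(df["frame"].tolist(), df["x_px"].tolist(),
                             df["y_px"].tolist())))
    return sorted(out)


class TestLink:
    def test_single_drifting_spot_full_track(self):
        dets = [_dets(f, [(1.0 + 0.5 * f, 2.0)]) for f in range(10)]
        tracks = link(dets, max_displacement=2.0)
        assert len(tracks) == 1 and len(tracks[0]) == 10

    def test_jump_beyond_gate_splits_track(self):
        dets = [_dets(0, [(1.0, 1.0)]), _dets(1, [(1.2, 1.0)]),
                _dets(2, [(9.0, 9.0)])]
        tracks = link(dets, max_displacement=2.0, memory=0)
        assert len(tracks) == 2

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_on_random_fixtures(self, seed):
        """Linking equals exhaustive minimum-cost assignment on <=4 spots
        over <=6 frames."""
        rng = np.random.default_rng(seed)
        n_spots = rng.integers(2, 5)
        n_frames = rng.integers(3, 7)
        pos = rng.uniform(0, 20, size=(n_spots, 2))
        dets_per_frame = []
        for f in range(n_frames):
            pos = pos + rng.normal(0, 1.2, size=pos.shape)
            keep = rng.random(n_spots) > 0.15    # occasional missed detection
            dets_per_frame.append(_dets(f, pos[keep]))
        got = _as_tuples(link(dets_per_frame, max_displacement=5.0, memory=0))
        want = link_bruteforce(dets_per_frame, max_disp=5.0, memory=0)
        assert got == want

    def test_crossing_spots_resolved_by_minimum_cost(self):
        dets = [_dets(f, [(f * 1.0, 0.0), (4.0 - f * 1.0, 0.2)])
                for f in range(5)]
        got = _as_tuples(link(dets, max_displacement=1.6, memory=0))
        want = link_bruteforce(dets, max_disp=1.6, memory=0)
        assert got == want
        assert len(got) == 2 and all(len(tr) == 5 for tr in got)

    def test_memory_resumes_with_interpolated_gap(self):
        dets = [_dets(0, [(1.0, 1.0)]), _dets(1, []),
                _dets(2, [(2.0, 1.0)])]
        tracks = link(dets, max_displacement=2.0, memory=2)
        assert len(tracks) == 1
        df = tracks[0]
        assert df["x_px"].tolist() == [1.0, 1.5, 2.0]

    def test_empty_input_empty_output(self):
        assert link([], 2.0) == []


class TestToPhysical:
    def test_calibration_scaling(self):
        df = pd.DataFrame({"track_id": 0, "frame": [0, 1000],
                           "x_px": [0.0, 10.0], "y_px": [0.0, 0.0]})
        traj = to_physical(df, pixel_size=0.33, frame_rate=1000.0)
        assert traj.x[1] == pytest.approx(3.3)
        assert traj.t[1] == pytest.approx(1.0)

    def test_identity_calibration(self):
        df = pd.DataFrame({"track_id": 0, "frame": [0, 1],
                           "x_px": [1.5, 2.5], "y_px": [0.5, 0.25]})
        traj = to_physical(df, 1.0, 1.0)
        np.testing.assert_allclose(traj.x, df["x_px"])
        np.testing.assert_allclose(traj.t, df["frame"])

    def test_invalid_calibration(self):
        df = pd.DataFrame({"track_id": 0, "frame": [0], "x_px": [1.0],
                           "y_px": [1.0]})
        with pytest.raises(ValueError):
            to_physical(df, 0.0, 1.0)


class TestRadiusSeries:
    def _static_stack(self, radii_um, pos=(8.0, 8.0)):
        spec = SceneSpec(bubbles=[], kv_params=KVParams(1.0, 1.0),
                         fov_px=(48, 48), image_noise_sd=0.0)
        n = len(radii_um)
        traj = Trajectory("b", t=np.arange(n) / 100.0,
                          x=np.full(n, pos[0]), y=np.full(n, pos[1]),
                          radius=np.asarray(radii_um))
        return render_frames([traj], spec), spec

    def test_constant_radius_recovered_within_5pct(self):
        stack, spec = self._static_stack(np.full(20, 2.0))
        track = pd.DataFrame({"track_id": 0, "frame": np.arange(20),
                              "x_px": 8.0 / 0.33, "y_px": 8.0 / 0.33})
        s = radius_series(track, stack, pixel_size=spec.pixel_size)
        assert np.nanmax(np.abs(s.to_numpy() - 2.0)) / 2.0 < 0.05

    def test_decay_rate_recovered_within_10pct(self):
        t = np.arange(40) / 8.0     # 5 s at 8 fps
        radii = 2.0 * np.exp(-0.05 * t)
        stack, spec = self._static_stack(radii)
        track = pd.DataFrame({"track_id": 0, "frame": np.arange(40),
                              "x_px": 8.0 / 0.33, "y_px": 8.0 / 0.33})
        s = radius_series(track, stack, pixel_size=spec.pixel_size,
                          smooth_window=1)
        fit = np.polyfit(t, np.log(s.to_numpy()), 1)
        assert fit[0] == pytest.approx(-0.05, rel=0.10)

    def test_empty_track_empty_series(self):
        stack = np.zeros((3, 32, 32), dtype=np.uint16)
        track = pd.DataFrame({"track_id": [], "frame": [], "x_px": [],
                              "y_px": []})
        assert len(radius_series(track, stack)) == 0
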