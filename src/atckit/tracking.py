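"""Blob detection and trajectory linking for bubble image stacks.

Detection follows the classic centroid-refinement recipe for blob-like
objects: a band-pass filter (short-scale Gaussian smoothing minus long-scale
boxcar background), local-maximum candidates separated by at least the
expected diameter, and iterative intensity-weighted centroid refinement to
subpixel precision.  Linking solves a per-frame minimum-cost assignment
(squared displacement, gated by a maximum displacement) with optional track
memory across missed frames.

Coordinate convention: pixel centers sit at integer coordinates, origin at
the top-left pixel, x rightward along columns, y downward along rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, uniform_filter
from scipy.optimize import curve_fit, linear_sum_assignment

from .trajectory import Trajectory

__all__ = [
    "Detection",
    "Trajectory",
    "detect_spots",
    "link",
    "to_physical",
    "radius_series",
]


@dataclass(frozen=True)
class Detection:
    """A single-frame spot detection (subpixel pixel coordinates)."""

    frame: int
    x: float            # column, px
    y: float            # row, px
    mass: float         # integrated band-passed intensity
    size: float         # radius of gyration, px

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be > 0")


def _bandpass(frame: np.ndarray, diameter: int) -> np.ndarray:
    """Gaussian noise smoothing minus boxcar background, clipped at zero."""
    noise_scale = max(diameter / 8.0, 0.5)
    smoothed = gaussian_filter(frame.astype(float), noise_scale)
    background = uniform_filter(frame.astype(float), 2 * diameter + 1)
    return np.maximum(smoothed - background, 0.0)


def _disc_mask(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (xx**2 + yy**2) <= radius**2


def detect_spots(frame: np.ndarray, expected_diameter: int,
                 min_mass: float = 0.0, frame_index: int = 0,
                 max_iterations: int = 10) -> list[Detection]:
    """Detect bright blobs of roughly ``expected_diameter`` pixels.

    Candidates are local maxima of the band-passed image separated by at
    least ``expected_diameter``; each is refined by iterated
    intensity-weighted centroids over a disc of radius ``diameter//2 + 1``
    (the window recenters whenever the centroid drifts more than half a
    pixel).  Mass is the summed band-passed intensity over the disc and size
    its radius of gyration.  Detections with mass below ``min_mass`` are
    dropped.  Two true spots closer than ``expected_diameter`` merge into
    one detection.
    """
    if expected_diameter < 3 or expected_diameter % 2 == 0:
        raise ValueError("expected_diameter must be an odd integer >= 3")
    frame = np.asarray(frame)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite pixels")
    bp = _bandpass(frame, expected_diameter)
    if not np.any(bp > 0):
        return []

    sep = expected_diameter
    # grayscale dilation local-max test with separation ~ diameter
    from scipy.ndimage import maximum_filter
    local_max = (bp == maximum_filter(bp, size=sep)) & (bp > 0)
    cand = np.argwhere(local_max)
    if cand.size == 0:
        return []
    # sort brightest first so merged/duplicate maxima favor the strong spot
    order = np.argsort(-bp[cand[:, 0], cand[:, 1]], kind="stable")
    cand = cand[order]

    w = expected_diameter // 2 + 1
    mask = _disc_mask(w)
    yy, xx = np.mgrid[-w:w + 1, -w:w + 1]
    ny, nx = bp.shape
    results: list[Detection] = []
    taken: list[tuple[float, float]] = []
    for r0, c0 in cand:
        cy, cx = float(r0), float(c0)
        for _ in range(max_iterations):
            ir, ic = int(round(cy)), int(round(cx))
            if not (w <= ir < ny - w and w <= ic < nx - w):
                ir = min(max(ir, w), ny - w - 1)
                ic = min(max(ic, w), nx - w - 1)
            win = bp[ir - w:ir + w + 1, ic - w:ic + w + 1] * mask
            total = win.sum()
            if total <= 0:
                break
            dy = (win * yy).sum() / total
            dx = (win * xx).sum() / total
            new_cy, new_cx = ir + dy, ic + dx
            shifted = abs(new_cy - cy) > 0.5 or abs(new_cx - cx) > 0.5
            cy, cx = new_cy, new_cx
            if not shifted:
                break
        total = win.sum() if win.sum() > 0 else 0.0
        if total <= 0 or total < min_mass:
            continue
        if any((cy - py) ** 2 + (cx - px) ** 2 < (sep / 2) ** 2
               for py, px in taken):
            continue    # duplicate of an already-refined (brighter) spot
        rg2 = ((win * ((yy - dy) ** 2 + (xx - dx) ** 2)).sum() / total)
        results.append(Detection(frame=frame_index, x=cx, y=cy,
                                 mass=float(total),
                                 size=float(np.sqrt(max(rg2, 0.0)))))
        taken.append((cy, cx))
    results.sort(key=lambda d: (d.y, d.x))
    return results


def detect_stack(stack: np.ndarray, expected_diameter: int,
                 min_mass: float = 0.0) -> list[list[Detection]]:
    """Run :func:`detect_spots` on every frame of a stack."""
    return [detect_spots(fr, expected_diameter, min_mass, frame_index=i)
            for i, fr in enumerate(stack)]


@dataclass
class _Track:
    track_id: int
    frames: list[int]
    xs: list[float]
    ys: list[float]
    last_frame: int


def link(detections_per_frame: list[list[Detection]],
         max_displacement: float, memory: int = 3
         ) -> list[pd.DataFrame]:
    """Link per-frame detections into tracks by minimum-cost assignment.

    Frame by frame, active tracks are matched to detections by solving the
    augmented assignment problem: matching track ``i`` to detection ``j``
    costs their squared displacement (forbidden beyond ``max_displacement``),
    while leaving a track or a detection unmatched costs
    ``max_displacement**2`` each.  Unmatched detections start new tracks, and
    tracks missing up to ``memory`` consecutive frames may resume (gaps are
    filled by linear interpolation).  Ties break deterministically (lowest
    track id, then detection order).

    Returns one tidy DataFrame per track with columns
    ``track_id, frame, x_px, y_px``.
    """
    tracks: list[_Track] = []
    next_id = 0
    gate2 = max_displacement ** 2
    big = 1e12
    for frame_idx, dets in enumerate(detections_per_frame):
        active = [tr for tr in tracks
                  if frame_idx - tr.last_frame <= memory + 1]
        matched_dets: set[int] = set()
        if active and dets:
            n, m = len(active), len(dets)
            # augmented square matrix: births/deaths cost gate2 each
            cost = np.full((n + m, m + n), big)
            for i, tr in enumerate(active):
                for j, d in enumerate(dets):
                    c = (tr.xs[-1] - d.x) ** 2 + (tr.ys[-1] - d.y) ** 2
                    if c <= gate2:
                        # tiny deterministic tie-break on (track id, det idx)
                        cost[i, j] = c + 1e-9 * (tr.track_id * m + j)
            for i in range(n):
                cost[i, m + i] = gate2          # track goes unmatched
            for j in range(m):
                cost[n + j, j] = gate2          # detection starts a track
            cost[n:, m:] = 0.0
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if i < n and j < m and cost[i, j] < big:
                    tr = active[i]
                    tr.frames.append(frame_idx)
                    tr.xs.append(dets[j].x)
                    tr.ys.append(dets[j].y)
                    tr.last_frame = frame_idx
                    matched_dets.add(j)
        for j, d in enumerate(dets):
            if j not in matched_dets:
                tracks.append(_Track(next_id, [frame_idx], [d.x], [d.y],
                                     frame_idx))
                next_id += 1
    out = []
    for tr in sorted(tracks, key=lambda t: t.track_id):
        frames = np.asarray(tr.frames)
        full = np.arange(frames[0], frames[-1] + 1)
        xs = np.interp(full, frames, tr.xs)
        ys = np.interp(full, frames, tr.ys)
        out.append(pd.DataFrame({"track_id": tr.track_id, "frame": full,
                                 "x_px": xs, "y_px": ys}))
    return out


def to_physical(track: pd.DataFrame, pixel_size: float,
                frame_rate: float, bubble_id: str | None = None) -> Trajectory:
    """Convert a pixel-space track to physical µm/seconds units.

    ``x_um = x_px * pixel_size``; ``t = frame / frame_rate``.  The mapping is
    invertible given the same calibration.
    """
    if pixel_size <= 0 or frame_rate <= 0:
        raise ValueError("pixel_size and frame_rate must be > 0")
    if bubble_id is None:
        bubble_id = str(track["track_id"].iloc[0])
    return Trajectory(
        bubble_id=bubble_id,
        t=track["frame"].to_numpy(dtype=float) / frame_rate,
        x=track["x_px"].to_numpy(dtype=float) * pixel_size,
        y=track["y_px"].to_numpy(dtype=float) * pixel_size)


def _gaussian_radial(r2: np.ndarray, amp: float, sigma: float, bg: float
                     ) -> np.ndarray:
    return bg + amp * np.exp(-r2 / (2.0 * sigma**2))


def radius_series(track: pd.DataFrame, stack: np.ndarray,
                  pixel_size: float = 0.33, window: int = 9,
                  smooth_window: int = 5,
                  sigma_per_radius_um: float = 0.5) -> pd.Series:
    """Per-frame bubble radius (µm) from Gaussian-width fits at each center.

    For every tracked frame a radially symmetric Gaussian (amplitude, width,
    background) is least-squares fitted to the pixel window around the
    tracked center; the radius is ``sigma_px * pixel_size /
    sigma_per_radius_um`` (the renderer draws spots with
    ``sigma = sigma_per_radius_um * R``).  Frames where the fit fails yield
    NaN; the series is median-smoothed over ``smooth_window`` frames.
    """
    radii = np.full(len(track), np.nan)
    ny, nx = stack.shape[1:]
    for k, (_, row) in enumerate(track.iterrows()):
        f = int(row["frame"])
        if f < 0 or f >= stack.shape[0]:
            continue
        cy, cx = row["y_px"], row["x_px"]
        r0, c0 = int(round(cy)) - window, int(round(cx)) - window
        r1, c1 = r0 + 2 * window + 1, c0 + 2 * window + 1
        if r0 < 0 or c0 < 0 or r1 > ny or c1 > nx:
            continue
        win = stack[f, r0:r1, c0:c1].astype(float)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        amp0 = win.max() - win.min()
        if amp0 <= 0:
            continue
        try:
            popt, _ = curve_fit(
                _gaussian_radial, r2.ravel(), win.ravel(),
                p0=[amp0, window / 3.0, win.min()],
                bounds=([0, 0.3, 0], [np.inf, 4.0 * window, np.inf]),
                maxfev=200)
            radii[k] = popt[1] * pixel_size / sigma_per_radius_um
        except RuntimeError:
            pass
    s = pd.Series(radii, index=track["frame"].to_numpy(), name="radius_um")
    if smooth_window > 1 and len(s) >= smooth_window:
        s = s.rolling(smooth_window, center=True, min_periods=1).median()
    return s
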