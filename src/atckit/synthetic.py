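"""Synthetic data generators: viscoelastic bubble trajectories, rendered
bubble image stacks, and two-channel nuclei images with ground truth.

Every generator is seeded and bit-reproducible, and every generated dataset
carries its ground truth, so the tracking, metrics, and image-quantification
modules can be validated end to end without any external data.

The mechanical model is a linear Kelvin–Voigt element (spring ``k`` and
dashpot ``eta`` in parallel) driven by the step force of each ultrasound
pulse: during a pulse the bubble creeps toward the creep limit
``x_inf = F/k`` with retardation time ``tau = eta/k``; when the pulse ends it
recovers exponentially toward its rest position with the same time constant.
Optional terms emulate the nonlinear creep stages seen at long pulses: a
linear secondary-creep rate ``beta`` and a per-pulse unrecovered (plastic)
fraction of the peak displacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acoustics import AcousticParams, BubbleGeom, PulseTrain, \
    net_force_direction, primary_radiation_force
from .trajectory import Trajectory

__all__ = [
    "KVParams",
    "SceneSpec",
    "NucleiSceneSpec",
    "NucleiScene",
    "FIVE_PULSE_MEANS",
    "kv_trajectory",
    "default_calibration",
    "peak_residual_recursion",
    "simulate_scene",
    "render_frames",
    "render_nuclei_image",
]


@dataclass(frozen=True)
class KVParams:
    """Kelvin–Voigt creep parameters.

    Attributes
    ----------
    tau : float
        Retardation time ``tau = eta/k`` in seconds (> 0).
    x_inf : float
        Creep limit ``x_inf = F/k`` in µm (>= 0) at the reference pressure.
    beta : float
        Secondary-creep rate in µm/s added during the on-phase (default 0,
        the pure linear model).
    plastic_fraction : float
        Fraction of each pulse's peak displacement that never recovers,
        in [0, 1) (default 0).
    """

    tau: float
    x_inf: float
    beta: float = 0.0
    plastic_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.x_inf < 0:
            raise ValueError("x_inf must be >= 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not (0 <= self.plastic_fraction < 1):
            raise ValueError("plastic_fraction must lie in [0, 1)")


# Five-pulse mean (peak, residual) displacements in µm for the supported duty
# cycles; measured inputs that the default calibration inverts.
FIVE_PULSE_MEANS: dict[float, tuple[float, float]] = {
    0.05: (1.45, 0.28),
    0.50: (4.74, 2.97),
}


def default_calibration(duty: float, prf: float = 1.0) -> KVParams:
    """Kelvin–Voigt parameters whose five-pulse means match the measured ones.

    Inverts the linear KV per-pulse recursion against the measured five-pulse
    mean peak ``P`` and mean residual ``R`` for the given duty cycle:
    ``b = R/P``; ``tau = t_off / (-ln b)``; ``a = exp(-t_on/tau)``;
    ``q = a*b``; first peak ``p1 = 5*P*(1-q) / sum_{n=1..5}(1-q^n)``;
    ``x_inf = p1/(1-a)``.

    Only duty cycles with a measured (peak, residual) pair are supported
    (0.05 and 0.50); others raise ``KeyError``.
    """
    try:
        peak_mean, resid_mean = FIVE_PULSE_MEANS[round(duty, 6)]
    except KeyError:
        raise KeyError(
            f"no displacement calibration for duty={duty}; "
            f"supported: {sorted(FIVE_PULSE_MEANS)}") from None
    t_on = duty / prf
    t_off = (1.0 - duty) / prf
    b = resid_mean / peak_mean
    tau = t_off / (-np.log(b))
    a = np.exp(-t_on / tau)
    q = a * b
    p1 = 5.0 * peak_mean * (1.0 - q) / np.sum(1.0 - q ** np.arange(1, 6))
    x_inf = p1 / (1.0 - a)
    return KVParams(tau=float(tau), x_inf=float(x_inf))


def peak_residual_recursion(params: KVParams, train: PulseTrain,
                            n_pulses: int | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form per-pulse peaks and residuals of the linear KV model.

    With ``a = exp(-t_on/tau)`` and ``b = exp(-t_off/tau)`` the peaks obey
    ``p_{n+1} = x_inf*(1-a) + a*b*p_n`` and residuals ``r_n = b*p_n``.
    Requires ``beta = 0`` and ``plastic_fraction = 0`` (the linear model).
    """
    if params.beta != 0 or params.plastic_fraction != 0:
        raise ValueError("closed-form recursion holds for the linear model only")
    n = train.n_pulses if n_pulses is None else n_pulses
    a = np.exp(-train.on_time / params.tau)
    b = np.exp(-train.off_time / params.tau)
    peaks = np.empty(n)
    residuals = np.empty(n)
    r = 0.0
    for k in range(n):
        p = params.x_inf + (r - params.x_inf) * a
        peaks[k] = p
        r = b * p
        residuals[k] = r
    return peaks, residuals


def _kv_segments(params: KVParams, train: PulseTrain, duration: float
                 ) -> list[tuple[float, float, float, float, float]]:
    """Piecewise-exponential segments of the KV response.

    Returns ``(t_start, x_target, x_start, tau, beta_seg)`` per segment,
    where the displacement over the segment is
    ``x(s) = x_target + (x_start - x_target)*exp(-s/tau) + beta_seg*s``
    with ``s`` the time since ``t_start``.
    """
    p_ref = train.pressure_segments[0][1]
    segments = []
    x = 0.0  # displacement at segment start
    beta_accum = 0.0  # locked-in secondary-creep displacement
    t = train.start_time
    k = 0
    while t < train.start_time + duration and k < train.n_pulses:
        # on-phase of pulse k
        p_a = train.pressure_at(t)
        scale = (p_a / p_ref) ** 2 if p_ref > 0 else 0.0
        x_inf_eff = params.x_inf * scale
        t_on = train.on_time
        segments.append((t, x_inf_eff, x, params.tau, params.beta))
        peak = (x_inf_eff + (x - x_inf_eff) * np.exp(-t_on / params.tau)
                + params.beta * t_on)
        beta_accum += params.beta * t_on
        # off-phase: exponential recovery toward the locked-in floor
        floor = min(params.plastic_fraction * peak + beta_accum, peak)
        t_off_start = t + t_on
        segments.append((t_off_start, floor, peak, params.tau, 0.0))
        x = (floor + (peak - floor) * np.exp(-train.off_time / params.tau))
        t += train.period
        k += 1
    if t < train.start_time + duration:
        # past the last pulse: free recovery toward the locked-in floor
        floor = min(beta_accum + params.plastic_fraction * x, x)
        segments.append((t, floor, x, params.tau, 0.0))
    return segments


def kv_trajectory(params: KVParams, train: PulseTrain, duration: float,
                  sample_rate: float = 1000.0,
                  bubble_id: str = "kv") -> Trajectory:
    """Simulate the 1-D KV displacement under a pulse train.

    Evaluates the exact piecewise closed form (no ODE stepping): during an
    on-phase starting from displacement ``r`` the response is
    ``x(s) = x_inf + (r - x_inf)*exp(-s/tau) + beta*s`` and during an
    off-phase starting from peak ``p`` it is
    ``x(s) = floor + (p - floor)*exp(-s/tau)`` with ``floor`` the locked-in
    (plastic + secondary-creep) displacement.  Pressure-segment changes scale
    the effective creep limit by ``(P/P_ref)^2`` (force quadratic in
    pressure), so a zero-pressure train yields an identically zero record.

    Samples are at ``start_time + n/sample_rate`` for ``n = 0 .. N-1`` with
    ``N = round(duration * sample_rate)``; exact at any admissible rate.
    """
    if duration < train.period:
        raise ValueError("duration must cover at least one full pulse period")
    min_rate = 2.0 * train.prf / train.duty
    if sample_rate < min_rate:
        raise ValueError(
            f"sample_rate {sample_rate} Hz undersamples the on-phase; "
            f"need >= {min_rate} Hz")
    n = int(round(duration * sample_rate))
    t = train.start_time + np.arange(n) / sample_rate
    segments = _kv_segments(params, train, duration)
    starts = np.array([s[0] for s in segments])
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, None)
    x = np.empty(n)
    for i, (t0, target, x0, tau, beta) in enumerate(segments):
        m = idx == i
        s = t[m] - t0
        x[m] = target + (x0 - target) * np.exp(-s / tau) + beta * s
    return Trajectory(bubble_id=bubble_id, t=t, x=x, y=np.zeros(n))


@dataclass
class SceneSpec:
    """A multi-bubble scene: geometry, mechanics, coupling, and imaging.

    ``kv_params`` maps bubble id to its Kelvin–Voigt parameters; a single
    ``KVParams`` applies to every bubble.  ``primary_direction`` is the
    in-plane unit vector of the incident-field push; ``bjerknes_coupling``
    is the signed bubble–bubble coupling (0 decouples); ``radius_decay_rate``
    is the exponential shrinkage rate of the bubble radius (gas leakage
    during insonation), default ≈0.2%/s so the radius drops ~1% over 5 s.
    """

    bubbles: list[BubbleGeom]
    kv_params: "KVParams | dict[str, KVParams]"
    primary_direction: tuple[float, float] = (1.0, 0.0)
    bjerknes_coupling: float = 0.0
    radius_decay_rate: float = 0.002
    noise_sd: float = 0.1          # µm, positional localization noise
    pixel_size: float = 0.33       # µm per pixel
    frame_rate: float = 1000.0     # Hz
    rng_seed: int = 0
    acoustic: AcousticParams = field(
        default_factory=lambda: AcousticParams(pressure_amplitude=0.035e6))
    # rendering
    fov_px: tuple[int, int] = (96, 96)   # (rows, cols)
    background_level: float = 100.0
    spot_peak: float = 1000.0
    image_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_rate <= 0:
            raise ValueError("pixel_size and frame_rate must be > 0")
        if self.noise_sd < 0 or self.image_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")

    def params_for(self, bubble_id: str) -> KVParams:
        if isinstance(self.kv_params, KVParams):
            return self.kv_params
        return self.kv_params[bubble_id]

    def noise_sd_for_snr(self, snr: float) -> float:
        """``image_noise_sd`` giving the requested SNR at the spot peak.

        The renderer's noise variance scales with the local signal, so the sd
        at a spot peak is ``image_noise_sd * sqrt((bg + peak)/bg)``; SNR is
        defined as spot peak amplitude over that sd.
        """
        if snr <= 0:
            raise ValueError("snr must be > 0")
        factor = np.sqrt(
            (self.background_level + self.spot_peak) / self.background_level)
        return self.spot_peak / (snr * factor)


def simulate_scene(spec: SceneSpec, train: PulseTrain, duration: float
                   ) -> tuple[list[Trajectory], pd.DataFrame]:
    """Simulate every bubble's 2-D trajectory under the pulse train.

    Each bubble's 1-D KV displacement is embedded along its net-force
    direction (primary push plus secondary Bjerknes coupling, evaluated at
    the rest geometry) and offset by its rest position.  Gaussian positional
    noise of sd ``noise_sd`` is added per frame, and the radius decays as
    ``R(t) = R0 * exp(-radius_decay_rate * t)``.

    Returns the noisy trajectories and a ground-truth table (noise-free
    positions) with columns bubble_id, frame, t_s, x_um, y_um, radius_um.
    """
    for i, bi in enumerate(spec.bubbles):
        for bj in spec.bubbles[i + 1:]:
            d = np.hypot(bi.position[0] - bj.position[0],
                         bi.position[1] - bj.position[1])
            if d < bi.radius + bj.radius:
                raise ValueError(
                    f"bubbles {bi.id!r} and {bj.id!r} overlap (d={d:.3g} µm)")
    forces = np.array([primary_radiation_force(spec.acoustic, b.radius)
                       for b in spec.bubbles])
    directions = net_force_direction(
        spec.bubbles, np.asarray(spec.primary_direction, dtype=float),
        forces, spec.bjerknes_coupling)
    rng = np.random.default_rng(spec.rng_seed)
    trajectories: list[Trajectory] = []
    truth_rows = []
    for b, direction in zip(spec.bubbles, directions):
        disp = kv_trajectory(spec.params_for(b.id), train, duration,
                             sample_rate=spec.frame_rate, bubble_id=b.id)
        true_x = b.position[0] + disp.x * direction[0]
        true_y = b.position[1] + disp.x * direction[1]
        radius = b.radius * np.exp(-spec.radius_decay_rate * disp.t)
        noisy_x = true_x + rng.normal(0.0, spec.noise_sd, size=true_x.size)
        noisy_y = true_y + rng.normal(0.0, spec.noise_sd, size=true_y.size)
        trajectories.append(Trajectory(
            bubble_id=b.id, t=disp.t, x=noisy_x, y=noisy_y, radius=radius))
        truth_rows.append(pd.DataFrame({
            "bubble_id": b.id, "frame": np.arange(disp.t.size),
            "t_s": disp.t, "x_um": true_x, "y_um": true_y,
            "radius_um": radius,
            "dir_x": direction[0], "dir_y": direction[1]}))
    return trajectories, pd.concat(truth_rows, ignore_index=True)


def render_frames(trajectories: list[Trajectory], spec: SceneSpec) -> np.ndarray:
    """Render trajectories as a 16-bit image stack of Gaussian spots.

    Pixel (0, 0) is top-left with physical position (0, 0) µm at its center;
    x runs rightward along columns, y downward along rows.  Each bubble is a
    Gaussian of peak ``spot_peak`` and width ``sigma_px = 0.5 * R/pixel_size``
    on a constant background; Poisson-like noise (Gaussian with variance
    proportional to the signal, sd ``image_noise_sd`` at background) is added
    when ``image_noise_sd > 0``.  Bubbles (partially) outside the field emit
    a warning and are clipped.
    """
    if not trajectories:
        raise ValueError("no trajectories to render")
    n_frames = len(trajectories[0])
    rows, cols = spec.fov_px
    stack = np.full((n_frames, rows, cols), spec.background_level, dtype=float)
    rng = np.random.default_rng(spec.rng_seed + 1)
    warned = set()
    for traj in trajectories:
        radius = (traj.radius if traj.radius is not None
                  else np.full(n_frames, 2.0))
        sigma = 0.5 * radius / spec.pixel_size
        col = traj.x / spec.pixel_size
        row = traj.y / spec.pixel_size
        out_of_fov = ((col < 0) | (col >= cols) | (row < 0) | (row >= rows))
        if np.any(out_of_fov) and traj.bubble_id not in warned:
            warnings.warn(f"bubble {traj.bubble_id!r} leaves the field of "
                          "view; clipped", stacklevel=2)
            warned.add(traj.bubble_id)
        for f in range(n_frames):
            half = max(int(np.ceil(4 * sigma[f])), 3)
            r0 = int(np.round(row[f])) - half
            c0 = int(np.round(col[f])) - half
            r1, c1 = r0 + 2 * half + 1, c0 + 2 * half + 1
            rr0, cc0 = max(r0, 0), max(c0, 0)
            rr1, cc1 = min(r1, rows), min(c1, cols)
            if rr0 >= rr1 or cc0 >= cc1:
                continue
            yy, xx = np.mgrid[rr0:rr1, cc0:cc1]
            spot = spec.spot_peak * np.exp(
                -((xx - col[f]) ** 2 + (yy - row[f]) ** 2)
                / (2.0 * sigma[f] ** 2))
            stack[f, rr0:rr1, cc0:cc1] += spot
    if spec.image_noise_sd > 0:
        sd = spec.image_noise_sd * np.sqrt(
            np.maximum(stack, 0.0) / spec.background_level)
        stack = stack + rng.normal(0.0, 1.0, size=stack.shape) * sd
    return np.clip(np.round(stack), 0, 65535).astype(np.uint16)


@dataclass
class NucleiSceneSpec:
    """Layout and intensity model for a synthetic two-channel nuclei image.

    Channel 1 emulates a DNA counterstain (nuclear ellipses of ``dapi_level``
    over ``background_level``); channel 2 a marker with level
    ``nuclear_marker_level`` inside nuclei, ``cytoplasmic_marker_level`` in a
    surrounding cytoplasmic ring, and background elsewhere.  A fraction
    ``fraction_yap_positive`` of cells is generated with nuclear marker at
    least 1.1x the cytoplasmic level; the rest at ``negative_ratio`` times
    the cytoplasmic level.  ``cell_level_cv`` applies a common multiplicative
    lognormal factor to both marker levels of a cell (staining variability
    that preserves the nuclear/cytoplasmic ratio).
    """

    n_nuclei: int = 50
    nucleus_axes_um: tuple[float, float] = (5.0, 3.5)   # semi-axes
    ring_width_um: float = 2.0
    nuclear_marker_level: float = 130.0
    cytoplasmic_marker_level: float = 100.0
    dapi_level: float = 200.0
    background_level: float = 20.0
    fraction_yap_positive: float = 1.0
    negative_ratio: float = 0.95
    cell_level_cv: float = 0.0
    noise_sd: float = 0.0
    pixel_size_um: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nuclear_marker_level", "cytoplasmic_marker_level",
                     "dapi_level", "background_level", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.fraction_yap_positive <= 1):
            raise ValueError("fraction_yap_positive must lie in [0, 1]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")


@dataclass
class NucleiScene:
    """A rendered nuclei image pair with its ground truth."""

    dapi: np.ndarray            # channel 1, float intensities
    marker: np.ndarray          # channel 2
    labels: np.ndarray          # ground-truth nucleus mask (0 = background)
    truth: pd.DataFrame         # per-nucleus ground-truth table

    @property
    def stack(self) -> np.ndarray:
        """(2, H, W) uint16 stack in channel order (DAPI, marker)."""
        return np.stack([
            np.clip(np.round(self.dapi), 0, 65535),
            np.clip(np.round(self.marker), 0, 65535),
        ]).astype(np.uint16)


def render_nuclei_image(spec: NucleiSceneSpec) -> NucleiScene:
    """Render a two-channel nuclei image with per-nucleus ground truth.

    Nuclei are non-overlapping ellipses placed on a jittered grid; an
    infeasible density (grid cannot host ``n_nuclei``) raises a layout
    error.  The ground-truth table records, per nucleus: centroid, the
    noise-free nuclear and cytoplasmic marker levels, their ratio, the
    positivity flag (ratio >= 1.1), and the true image-mean DAPI intensity
    used for normalization checks.
    """
    rng = np.random.default_rng(spec.rng_seed)
    a_px = spec.nucleus_axes_um[0] / spec.pixel_size_um
    b_px = spec.nucleus_axes_um[1] / spec.pixel_size_um
    ring_px = spec.ring_width_um / spec.pixel_size_um
    cell_px = 2.0 * (max(a_px, b_px) + ring_px) + 4.0
    n_side = int(np.ceil(np.sqrt(spec.n_nuclei))) if spec.n_nuclei else 1
    shape = (int(n_side * cell_px) + 8, int(n_side * cell_px) + 8)
    if n_side * n_side < spec.n_nuclei:
        raise ValueError("cannot lay out the requested number of nuclei")

    dapi = np.full(shape, spec.background_level, dtype=float)
    marker = np.full(shape, spec.background_level, dtype=float)
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]

    cells = [(i, j) for i in range(n_side) for j in range(n_side)]
    order = rng.permutation(len(cells))[:spec.n_nuclei]
    n_pos = int(round(spec.fraction_yap_positive * spec.n_nuclei))
    is_positive = np.zeros(spec.n_nuclei, dtype=bool)
    is_positive[rng.permutation(spec.n_nuclei)[:n_pos]] = True

    rows = []
    jitter = max(cell_px / 2.0 - max(a_px, b_px) - ring_px - 2.0, 0.0)
    for label, (k, positive) in enumerate(zip(order, is_positive), start=1):
        i, j = cells[k]
        cy = (i + 0.5) * cell_px + 4 + rng.uniform(-jitter, jitter)
        cx = (j + 0.5) * cell_px + 4 + rng.uniform(-jitter, jitter)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        nucleus = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
        ring = (((u / (a_px + ring_px)) ** 2 + (v / (b_px + ring_px)) ** 2
                 <= 1.0) & ~nucleus)
        gain = (rng.lognormal(0.0, spec.cell_level_cv)
                if spec.cell_level_cv > 0 else 1.0)
        cyto_level = spec.cytoplasmic_marker_level * gain
        if positive:
            nuc_level = max(spec.nuclear_marker_level,
                            1.1 * spec.cytoplasmic_marker_level) * gain
        else:
            nuc_level = spec.negative_ratio * spec.cytoplasmic_marker_level * gain
        dapi[nucleus] = spec.dapi_level
        marker[nucleus] = nuc_level
        marker[ring] = cyto_level
        labels[nucleus] = label
        rows.append({
            "label": label, "centroid_y": cy, "centroid_x": cx,
            "area_px": int(nucleus.sum()),
            "nuclear_marker_level": nuc_level,
            "cytoplasmic_marker_level": cyto_level,
            "nuclear_cyto_ratio": nuc_level / cyto_level if cyto_level else np.inf,
            "yap_positive": bool(nuc_level >= 1.1 * cyto_level),
        })
    if spec.noise_sd > 0:
        dapi = dapi + rng.normal(0.0, spec.noise_sd, size=shape)
        marker = marker + rng.normal(0.0, spec.noise_sd, size=shape)
        dapi = np.maximum(dapi, 0.0)
        marker = np.maximum(marker, 0.0)
    truth = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["label", "centroid_y", "centroid_x", "area_px",
                 "nuclear_marker_level", "cytoplasmic_marker_level",
                 "nuclear_cyto_ratio", "yap_positive"])
    if len(truth):
        truth["image_mean_dapi"] = dapi.mean()
        truth["normalized_marker_truth"] = (
            truth["nuclear_marker_level"] / dapi.mean())
    return NucleiScene(dapi=dapi, marker=marker, labels=labels, truth=truth)
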