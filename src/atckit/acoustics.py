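"""Acoustic force models and ultrasound pulse scheduling.

Acoustic tweezing cytometry (ATC) displaces receptor-bound microbubbles with
the acoustic radiation force of a pulsed ultrasound field.  This module holds
the two force models used throughout the package — the first-order primary
radiation force on a single bubble and the secondary Bjerknes bubble–bubble
coupling — together with the :class:`PulseTrain` schedule that synchronizes
simulation, metric extraction, and windowing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcousticParams",
    "PulseTrain",
    "BubbleGeom",
    "primary_radiation_force",
    "secondary_bjerknes_force",
    "net_force_direction",
    "pulse_envelope",
]


@dataclass(frozen=True)
class AcousticParams:
    """Parameters of the incident ultrasound field and medium.

    Attributes
    ----------
    pressure_amplitude : float
        Peak acoustic pressure ``P_A`` in pascals (>= 0).
    center_frequency : float
        Transducer center frequency ``f0`` in hertz; the angular frequency
        ``omega0 = 2*pi*f0`` is derived.
    damping_constant : float
        Total (dimensionless) damping constant of the bubble oscillation,
        default 0.16.
    medium_density : float
        Medium density ``rho0`` in kg/m^3, default 1000 (water-like medium).
    sound_speed : float
        Speed of sound ``c`` in m/s, default 1500.
    """

    pressure_amplitude: float
    center_frequency: float = 1.25e6
    damping_constant: float = 0.16
    medium_density: float = 1000.0
    sound_speed: float = 1500.0

    def __post_init__(self) -> None:
        if self.pressure_amplitude < 0:
            raise ValueError("pressure_amplitude must be >= 0")
        for name in ("center_frequency", "damping_constant",
                     "medium_density", "sound_speed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def angular_frequency(self) -> float:
        """Angular frequency ``omega0 = 2*pi*f0`` in rad/s."""
        return 2.0 * np.pi * self.center_frequency


@dataclass(frozen=True)
class PulseTrain:
    """An ultrasound pulse schedule: PRF, duty cycle, and pressure segments.

    Pulse ``k`` (0-based) is on over the half-open interval
    ``[start_time + k*T, start_time + k*T + on_time)`` with ``T = 1/prf`` and
    ``on_time = duty*T``.  The acoustic pressure is piecewise constant over
    ``pressure_segments``, a sequence of ``(duration_s, P_A_pascals)`` pairs
    (a ramped protocol uses several segments).
    """

    prf: float = 1.0
    duty: float = 0.5
    n_pulses: int = 5
    pressure_segments: tuple[tuple[float, float], ...] = ((float("inf"), 0.035e6),)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.prf <= 0:
            raise ValueError("prf must be > 0")
        if not (0 < self.duty <= 1):
            raise ValueError("duty must lie in (0, 1]")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        segs = tuple((float(d), float(p)) for d, p in self.pressure_segments)
        for d, p in segs:
            if d < self.period:
                raise ValueError("segment durations must cover >= one period")
            if p < 0:
                raise ValueError("segment pressures must be >= 0")
        object.__setattr__(self, "pressure_segments", segs)

    @property
    def period(self) -> float:
        return 1.0 / self.prf

    @property
    def on_time(self) -> float:
        return self.duty / self.prf

    @property
    def off_time(self) -> float:
        return (1.0 - self.duty) / self.prf

    @property
    def total_duration(self) -> float:
        return self.n_pulses * self.period

    def pressure_at(self, t: float) -> float:
        """Pressure of the segment active at time ``t`` (seconds, absolute)."""
        if t < self.start_time:
            raise ValueError(f"t={t} precedes start_time={self.start_time}")
        elapsed = t - self.start_time
        for duration, p_a in self.pressure_segments:
            if elapsed < duration:
                return p_a
            elapsed -= duration
        return 0.0

    @classmethod
    def constant(cls, prf: float, duty: float, n_pulses: int,
                 pressure: float = 0.035e6, start_time: float = 0.0) -> "PulseTrain":
        """Single-pressure train covering all ``n_pulses`` periods."""
        return cls(prf=prf, duty=duty, n_pulses=n_pulses,
                   pressure_segments=((float("inf"), pressure),),
                   start_time=start_time)


@dataclass(frozen=True)
class BubbleGeom:
    """A bubble's label, 2-D rest position (µm) and radius (µm)."""

    id: str
    position: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position must be finite")
        object.__setattr__(self, "position",
                           (float(self.position[0]), float(self.position[1])))


def primary_radiation_force(acoustic: AcousticParams, radius_um: float) -> float:
    """First-order primary acoustic radiation force on a bubble, in newtons.

    F = 2*pi*P_A^2*R0 / (delta_tot*rho0*c*omega0), with R0 the bubble radius.
    Linear in radius, quadratic in pressure amplitude.

    Parameters
    ----------
    acoustic : AcousticParams
        Field and medium parameters (SI units).
    radius_um : float
        Bubble radius in micrometres (> 0).
    """
    if radius_um <= 0:
        raise ValueError("radius must be > 0")
    r0_m = radius_um * 1e-6
    p = acoustic
    return (2.0 * np.pi * p.pressure_amplitude**2 * r0_m
            / (p.damping_constant * p.medium_density * p.sound_speed
               * p.angular_frequency))


def secondary_bjerknes_force(b1: BubbleGeom, b2: BubbleGeom,
                             coupling: float) -> np.ndarray:
    """Secondary Bjerknes force on ``b1`` due to ``b2``, as a 2-D vector (N).

    Magnitude ``|coupling| * R1^3 * R2^3 / d^2`` with ``d`` the center
    distance; directed along the line of centers.  Negative ``coupling`` is
    attractive (force on b1 points toward b2), positive repulsive.  The pair
    forces obey action–reaction: F(b1<-b2) = -F(b2<-b1).

    Radii enter in µm and distance in µm, so ``coupling`` absorbs all unit
    conversion; only relative magnitudes matter downstream.
    """
    r1 = np.asarray(b1.position, dtype=float)
    r2 = np.asarray(b2.position, dtype=float)
    sep = r2 - r1
    d = float(np.hypot(*sep))
    if d == 0.0:
        raise ValueError(f"bubbles {b1.id!r} and {b2.id!r} have coincident centers")
    unit_toward_b2 = sep / d
    magnitude = abs(coupling) * b1.radius**3 * b2.radius**3 / d**2
    # attractive (coupling < 0): force on b1 points toward b2
    sign = -1.0 if coupling > 0 else 1.0
    return sign * magnitude * unit_toward_b2


def net_force_direction(bubbles: list[BubbleGeom],
                        primary_direction: np.ndarray,
                        primary_forces: float | np.ndarray,
                        coupling: float = 0.0) -> np.ndarray:
    """Unit direction of the net acoustic force on each bubble.

    Each bubble's net force is its primary radiation force along
    ``primary_direction`` plus the sum of secondary Bjerknes forces from every
    other bubble.  Returns an ``(n, 2)`` array of unit vectors.  A single
    isolated bubble (or ``coupling == 0``) returns ``primary_direction``
    exactly.

    Parameters
    ----------
    bubbles : list of BubbleGeom
    primary_direction : array-like, shape (2,)
        Unit vector of the incident-field propagation direction in the image
        plane.
    primary_forces : float or array, newtons
        Primary radiation force magnitude per bubble (scalar broadcasts).
    coupling : float
        Signed Bjerknes coupling constant (see
        :func:`secondary_bjerknes_force`); 0 decouples the bubbles.
    """
    if len(bubbles) == 0:
        raise ValueError("need at least one bubble")
    e = np.asarray(primary_direction, dtype=float)
    e = e / np.linalg.norm(e)
    fp = np.broadcast_to(np.asarray(primary_forces, dtype=float), (len(bubbles),))

    out = np.empty((len(bubbles), 2))
    for i, bi in enumerate(bubbles):
        net = fp[i] * e
        if coupling != 0.0:
            for j, bj in enumerate(bubbles):
                if j != i:
                    net = net + secondary_bjerknes_force(bi, bj, coupling)
        norm = np.linalg.norm(net)
        if norm == 0.0:
            raise ValueError(f"net force on bubble {bi.id!r} is the zero vector")
        out[i] = net / norm
    return out


def pulse_envelope(train: PulseTrain, t: float) -> tuple[bool, float]:
    """On/off state and acoustic pressure of ``train`` at time ``t`` (s).

    Pulse ``k`` is on over ``[k*T, k*T + on_time)`` relative to
    ``start_time``; after ``n_pulses`` periods the train is permanently off.
    The returned pressure is that of the active pressure segment (also during
    the off-phase; the boolean carries the gating).
    """
    if t < train.start_time:
        raise ValueError(f"t={t} precedes train start_time={train.start_time}")
    rel = t - train.start_time
    k = int(np.floor(rel * train.prf))
    if k >= train.n_pulses:
        return False, 0.0
    phase = rel - k * train.period
    is_on = phase < train.on_time
    return is_on, train.pressure_at(t)
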