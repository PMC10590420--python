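"""Per-pulse displacement metrics synchronized to an ultrasound pulse train.

For each pulse period ``[kT, (k+1)T)`` the peak displacement is the maximum
of the displacement-magnitude series over the period, the residual is the
unrecovered displacement at the last sample before the next pulse, and the
relative displacement is their difference.  The displacement integral (AUC)
is the trapezoidal integral of the series over an observation window
(first five periods by default), and the cumulative displacement is the path
length of the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acoustics import PulseTrain
from .trajectory import Trajectory

__all__ = [
    "PulseMetricSet",
    "displacement_magnitude",
    "per_pulse_metrics",
    "auc",
    "cumulative_displacement",
    "summarize",
]

DEFAULT_N_PULSES = 5


@dataclass
class PulseMetricSet:
    """Per-pulse metrics of one bubble plus record-level scalars (µm, µm·s)."""

    bubble_id: str
    peak: np.ndarray           # µm, per pulse
    residual: np.ndarray       # µm, per pulse
    auc: float                 # µm·s over the default window
    cumulative: float          # µm path length

    @property
    def relative(self) -> np.ndarray:
        """Relative displacement per pulse: peak - residual (µm)."""
        return self.peak - self.residual

    @property
    def n_pulses(self) -> int:
        return self.peak.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bubble_id": self.bubble_id,
            "pulse_idx": np.arange(self.n_pulses),
            "peak_um": self.peak,
            "residual_um": self.residual,
            "relative_um": self.relative,
        })


def displacement_magnitude(traj: Trajectory,
                           origin_window: int = 1) -> np.ndarray:
    """Euclidean distance (µm) from the pre-actuation origin at each sample.

    The origin is the mean position over the first ``origin_window`` frames,
    which must precede the first pulse.
    """
    if origin_window < 1 or origin_window > len(traj):
        raise ValueError("origin_window must be >= 1 and within the record")
    origin = traj.positions[:origin_window].mean(axis=0)
    return np.hypot(traj.x - origin[0], traj.y - origin[1])


def per_pulse_metrics(series: np.ndarray, t: np.ndarray, train: PulseTrain,
                      n_pulses: int | None = None,
                      bubble_id: str = "bubble") -> PulseMetricSet:
    """Per-pulse peak and residual displacement of a magnitude series.

    For pulse ``k`` covering ``[kT, (k+1)T)`` relative to the train start:
    the peak is the maximum over the whole period (robust to response lag)
    and the residual the value at the last sample before ``(k+1)T``.
    """
    series = np.asarray(series, dtype=float)
    t = np.asarray(t, dtype=float)
    if series.size != t.size:
        raise ValueError("series and t must have equal length")
    n = train.n_pulses if n_pulses is None else n_pulses
    rel = t - train.start_time
    end = n * train.period
    if rel[-1] + (rel[1] - rel[0] if t.size > 1 else 0.0) < end - 1e-9:
        raise ValueError(
            f"series covers {rel[-1]:.4g}s but {n} pulses need {end:.4g}s")
    peaks = np.empty(n)
    residuals = np.empty(n)
    for k in range(n):
        lo, hi = k * train.period, (k + 1) * train.period
        in_period = (rel >= lo - 1e-12) & (rel < hi - 1e-12)
        if not np.any(in_period):
            raise ValueError(f"no samples in pulse period {k}")
        vals = series[in_period]
        peaks[k] = vals.max()
        residuals[k] = vals[-1]
    window = (0.0, min(DEFAULT_N_PULSES, n) * train.period)
    return PulseMetricSet(
        bubble_id=bubble_id, peak=peaks, residual=residuals,
        auc=auc(series, t, (train.start_time + window[0],
                            train.start_time + window[1])),
        cumulative=float(np.sum(np.abs(np.diff(series)))))


def metrics_for_trajectory(traj: Trajectory, train: PulseTrain,
                           origin_window: int = 1,
                           n_pulses: int | None = None) -> PulseMetricSet:
    """Convenience: displacement magnitude then per-pulse metrics, with the
    cumulative displacement taken as the 2-D path length of the trajectory."""
    series = displacement_magnitude(traj, origin_window)
    ms = per_pulse_metrics(series, traj.t, train, n_pulses,
                           bubble_id=traj.bubble_id)
    ms.cumulative = cumulative_displacement(traj)
    return ms


def auc(series: np.ndarray, t: np.ndarray,
        window: tuple[float, float] | None = None) -> float:
    """Trapezoidal integral of the displacement series (µm·s) over a window.

    ``window`` is ``(t_start, t_end)`` in the series' time units; the whole
    record when None.
    """
    series = np.asarray(series, dtype=float)
    t = np.asarray(t, dtype=float)
    if window is not None:
        lo, hi = window
        if hi < lo:
            raise ValueError("window end precedes start")
        m = (t >= lo - 1e-12) & (t <= hi + 1e-12)
        series, t = series[m], t[m]
    if t.size < 2:
        return 0.0
    return float(np.trapezoid(series, t))


def cumulative_displacement(traj: Trajectory) -> float:
    """Total path length of the trajectory (µm): sum of sample-to-sample
    Euclidean steps.  (Displacement-from-origin at the final sample is
    available via :func:`displacement_magnitude`.)"""
    if len(traj) < 2:
        raise ValueError("need >= 2 samples")
    steps = np.hypot(np.diff(traj.x), np.diff(traj.y))
    return float(steps.sum())


def summarize(metric_sets: list[PulseMetricSet],
              n: int = DEFAULT_N_PULSES) -> pd.DataFrame:
    """Across-pulse then across-bubble summary of the first ``n`` pulses.

    Each bubble's per-pulse peaks/residuals/relatives are first averaged over
    pulses 1..n; the table then reports mean, median, sd, sem, and the
    box-plot summary (q25, q75, p1, p99) of those per-bubble values, one row
    per metric.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for ms in metric_sets:
        if ms.n_pulses < n:
            raise ValueError(
                f"bubble {ms.bubble_id!r} has {ms.n_pulses} pulses < n={n}")
    per_bubble = pd.DataFrame({
        "bubble_id": [ms.bubble_id for ms in metric_sets],
        "peak_um": [ms.peak[:n].mean() for ms in metric_sets],
        "residual_um": [ms.residual[:n].mean() for ms in metric_sets],
        "relative_um": [ms.relative[:n].mean() for ms in metric_sets],
        "auc_um_s": [ms.auc for ms in metric_sets],
        "cumulative_um": [ms.cumulative for ms in metric_sets],
    })
    rows = []
    for col in ("peak_um", "residual_um", "relative_um", "auc_um_s",
                "cumulative_um"):
        v = per_bubble[col].to_numpy()
        rows.append({
            "metric": col, "n_bubbles": v.size, "n_pulses_used": n,
            "mean": v.mean(), "median": float(np.median(v)),
            "sd": v.std(ddof=1) if v.size > 1 else 0.0,
            "sem": (v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0,
            "q25": float(np.percentile(v, 25)),
            "q75": float(np.percentile(v, 75)),
            "p1": float(np.percentile(v, 1)),
            "p99": float(np.percentile(v, 99)),
        })
    return pd.DataFrame(rows)
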