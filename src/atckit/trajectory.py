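"""Uniformly sampled bubble trajectories in physical units (µm, seconds)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory"]

_SPACING_RTOL = 1e-6


@dataclass
class Trajectory:
    """One bubble's time series of 2-D position (and optionally radius).

    Times are in seconds and strictly increasing with uniform spacing;
    positions and radii are in micrometres.  A 1-D displacement record (e.g. a
    simulated creep curve along the force axis) is stored with ``y = 0``.
    """

    bubble_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    radius: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.radius is not None:
            self.radius = np.asarray(self.radius, dtype=float)
        n = self.t.size
        if self.x.size != n or self.y.size != n:
            raise ValueError("t, x, y must have equal length")
        if self.radius is not None and self.radius.size != n:
            raise ValueError("radius must match t in length")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("t must be strictly increasing")
            if np.ptp(dt) > _SPACING_RTOL * max(dt.mean(), 1e-30) + 1e-12:
                raise ValueError("t must be uniformly spaced")
        for arr in (self.t, self.x, self.y):
            if not np.all(np.isfinite(arr)):
                raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return self.t.size

    @property
    def sample_interval(self) -> float:
        """Spacing between consecutive samples, seconds."""
        if len(self) < 2:
            raise ValueError("need >= 2 samples for a sample interval")
        return float(np.mean(np.diff(self.t)))

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) in µm."""
        return np.column_stack([self.x, self.y])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: bubble_id, frame, t_s, x_um, y_um[, radius_um]."""
        out = pd.DataFrame({
            "bubble_id": self.bubble_id,
            "frame": np.arange(len(self)),
            "t_s": self.t,
            "x_um": self.x,
            "y_um": self.y,
        })
        if self.radius is not None:
            out["radius_um"] = self.radius
        return out

    @staticmethod
    def from_frame(df: pd.DataFrame, bubble_id: str | None = None) -> "Trajectory":
        """Inverse of :meth:`to_frame` for a single bubble's rows."""
        if bubble_id is not None:
            df = df[df["bubble_id"] == bubble_id]
        elif df["bubble_id"].nunique() > 1:
            raise ValueError("frame holds multiple bubbles; pass bubble_id")
        df = df.sort_values("t_s")
        radius = df["radius_um"].to_numpy() if "radius_um" in df else None
        return Trajectory(
            bubble_id=str(df["bubble_id"].iloc[0]),
            t=df["t_s"].to_numpy(), x=df["x_um"].to_numpy(),
            y=df["y_um"].to_numpy(), radius=radius)
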