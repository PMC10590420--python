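"""Kelvin–Voigt creep/recovery model: closed-form response, least-squares
parameter fitting, and creep-stage classification.

The bubble–integrin–cytoskeleton linkage is modelled as a Kelvin–Voigt
element (spring ``k`` parallel to dashpot ``eta``) under the step force of
each ultrasound pulse: ``k*x + eta*dx/dt = F(t)``.  During a pulse the
displacement creeps as ``x(t) = x_inf*(1 - exp(-t/tau))`` from rest and
recovers exponentially with the same retardation time ``tau = eta/k`` when
the pulse ends; ``x_inf = F/k`` is the creep limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .acoustics import PulseTrain
from .synthetic import KVParams, _kv_segments

__all__ = ["FitResult", "CreepStage", "kv_response", "fit_kv",
           "classify_creep_stage"]


@dataclass
class FitResult:
    """Outcome of a Kelvin–Voigt least-squares fit."""

    params: KVParams
    residual_norm: float                    # RMS misfit, µm
    conf_halfwidth: tuple[float, float]     # ~1-sigma half-widths (tau, x_inf)
    converged: bool


@dataclass
class CreepStage:
    """Creep-stage call for one pulse's on-phase window.

    ``stage`` is 'primary' (decelerating creep), 'secondary' (near-constant
    positive creep rate), or 'tertiary' (accelerating creep); ``slope`` and
    ``curvature`` are the late-window first and second displacement
    derivatives used for the call.
    """

    pulse_index: int
    stage: str
    slope: float        # µm/s over the late half-window
    curvature: float    # µm/s² over the late half-window


def kv_response(params: KVParams, train: PulseTrain,
                t: np.ndarray | float) -> np.ndarray | float:
    """Exact piecewise-exponential KV displacement at time(s) ``t`` (µm).

    Pure function of (params, train, t); identical to the generator's
    closed-form trajectory model evaluated pointwise.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < train.start_time):
        raise ValueError("t must be >= train.start_time")
    duration = float(t_arr.max() - train.start_time) + train.period
    segments = _kv_segments(params, train, duration)
    starts = np.array([s[0] for s in segments])
    idx = np.clip(np.searchsorted(starts, t_arr, side="right") - 1, 0, None)
    x = np.empty_like(t_arr)
    for i, (t0, target, x0, tau, beta) in enumerate(segments):
        m = idx == i
        if np.any(m):
            s = t_arr[m] - t0
            x[m] = target + (x0 - target) * np.exp(-s / tau) + beta * s
    return x if np.ndim(t) else float(x[0])


_TAU_STARTS = np.geomspace(0.01, 10.0, 8)


def fit_kv(series: np.ndarray, t: np.ndarray, train: PulseTrain,
           fit_nonlinear: bool = False) -> FitResult:
    """Fit (tau, x_inf) of the linear KV model to a displacement series.

    Unweighted least squares with multi-start initialization (8 log-spaced
    retardation times over [0.01, 10] s); ``fit_nonlinear=True`` additionally
    fits the secondary-creep rate ``beta`` and ``plastic_fraction``.
    A degenerate series (no signal) yields a non-converged result.  The
    confidence half-widths are 1-sigma values from the Gauss–Newton
    covariance at the optimum.
    """
    series = np.asarray(series, dtype=float)
    t = np.asarray(t, dtype=float)
    if t.size < 2 or float(t.max() - train.start_time) < train.period:
        raise ValueError("need at least one full pulse period of data")
    scale = float(np.max(np.abs(series)))
    if not np.isfinite(scale) or scale <= 0:
        return FitResult(KVParams(tau=1.0, x_inf=0.0), 0.0,
                         (np.inf, np.inf), converged=False)

    def residuals(theta: np.ndarray) -> np.ndarray:
        if fit_nonlinear:
            p = KVParams(tau=theta[0], x_inf=theta[1], beta=theta[2],
                         plastic_fraction=theta[3])
        else:
            p = KVParams(tau=theta[0], x_inf=theta[1])
        return kv_response(p, train, t) - series

    lo = [1e-4, 0.0] + ([0.0, 0.0] if fit_nonlinear else [])
    hi = [1e3, np.inf] + ([np.inf, 0.999] if fit_nonlinear else [])
    best = None
    for tau0 in _TAU_STARTS:
        x0 = [tau0, scale] + ([0.0, 0.0] if fit_nonlinear else [])
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi),
                                xtol=1e-10, ftol=1e-10)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return FitResult(KVParams(tau=1.0, x_inf=scale), np.inf,
                         (np.inf, np.inf), converged=False)
    theta = best.x
    params = (KVParams(tau=theta[0], x_inf=theta[1], beta=theta[2],
                       plastic_fraction=theta[3]) if fit_nonlinear
              else KVParams(tau=theta[0], x_inf=theta[1]))
    rms = float(np.sqrt(2.0 * best.cost / t.size))
    # Gauss-Newton covariance for rough 1-sigma half-widths
    dof = max(t.size - theta.size, 1)
    s2 = 2.0 * best.cost / dof
    try:
        jtj = best.jac.T @ best.jac
        cov = s2 * np.linalg.pinv(jtj)
        half = tuple(float(np.sqrt(max(cov[i, i], 0.0))) for i in range(2))
    except Exception:
        half = (np.inf, np.inf)
    at_bounds = bool(np.any(np.isclose(theta[:2], lo[:2]))
                     or theta[0] >= hi[0] * 0.999)
    # misfit larger than half the signal means the KV shape does not apply
    poor_fit = rms > 0.5 * scale
    return FitResult(params, rms, half,
                     converged=bool(best.success) and not at_bounds
                     and not poor_fit)


def classify_creep_stage(series: np.ndarray, t: np.ndarray,
                         pulse_index: int = 0,
                         rel_tol: float = 0.05) -> CreepStage:
    """Classify the creep stage of one on-phase displacement window.

    A quadratic is fitted to the late half of the window; its curvature,
    compared against ``rel_tol`` times the largest curvature magnitude seen
    anywhere in the window, decides the stage: decelerating (curvature below
    ``-tol``) is primary creep, near-zero curvature with positive slope is
    secondary, and accelerating (above ``+tol``) is tertiary.  The call is
    invariant to amplitude scaling of the window.
    """
    series = np.asarray(series, dtype=float)
    t = np.asarray(t, dtype=float)
    if series.size < 5:
        raise ValueError("need >= 5 samples in the on-phase window")
    half = series.size // 2
    t_late, x_late = t[half:], series[half:]
    c_late = np.polyfit(t_late - t_late[0], x_late, 2)
    curv_late = 2.0 * c_late[0]
    slope_late = float(np.polyval(np.polyder(c_late),
                                  t_late[-1] - t_late[0]))
    c_early = np.polyfit(t[:half + 1] - t[0], series[:half + 1], 2)
    curv_ref = max(abs(2.0 * c_early[0]), abs(curv_late))
    tol = rel_tol * curv_ref
    if curv_late < -tol:
        stage = "primary"
    elif curv_late > tol:
        stage = "tertiary"
    elif slope_late > 0:
        stage = "secondary"
    else:
        stage = "primary"   # flat and non-increasing: saturated primary creep
    return CreepStage(pulse_index=pulse_index, stage=stage,
                      slope=slope_late, curvature=float(curv_late))
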