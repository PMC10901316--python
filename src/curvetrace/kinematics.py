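"""Discrete tracing traces: resampling, finite-difference kinematics,
speed/curvature series, preprocessing filters and Euclidean
reparameterization of a whole trace.

A :class:`Trace` is a uniformly sampled planar movement (positions in
meters, 100 Hz by convention).  The instantaneous unsigned curvature is
evaluated per sample as ``kappa = |x' y'' - x'' y'| / (x'^2 + y'^2)^{3/2}``
and the speed as the norm of the velocity; samples where the tracer is
(nearly) stationary have undefined curvature and are flagged rather than
raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .curves import ParametricCurve, Projection, project_to_curve

__all__ = [
    "Trace",
    "KinematicSeries",
    "EmptySelectionError",
    "differentiate",
    "speed_curvature",
    "preprocess",
    "reparameterize_trace",
    "resample",
    "read_trace_csv",
    "write_trace_csv",
    "PREPROCESS_PROFILES",
]

#: Default zero-speed threshold [m/s]: one position quantum per 100 Hz sample.
DEFAULT_V_ZERO = 0.005

#: Curvature threshold [1/m] removing near-straight segments where the
#: log-log power-law regression degenerates.
CURVATURE_THRESHOLD = 1.0

PREPROCESS_PROFILES = ("human_demo", "elm_eight", "elm_new_curves")


class EmptySelectionError(ValueError):
    """All samples were removed by the preprocessing filters."""


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled planar tracing.

    ``positions`` has shape (m, 2) in meters; ``velocities`` (same shape,
    m/s) is optional — synthetic traces carry analytic velocities, recorded
    ones are differentiated numerically.
    """

    dt: float
    positions: np.ndarray
    velocities: np.ndarray | None = None
    accelerations: np.ndarray | None = None
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        if self.velocities is not None:
            object.__setattr__(self, "velocities", np.asarray(self.velocities, dtype=float))
        if self.accelerations is not None:
            object.__setattr__(
                self, "accelerations", np.asarray(self.accelerations, dtype=float)
            )
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (m, 2)")

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.dt


@dataclass(frozen=True)
class KinematicSeries:
    """Per-sample speed [m/s], unsigned curvature [1/m] and acceleration.

    ``kappa_defined`` marks samples where the speed is large enough for the
    curvature quotient to be meaningful; elsewhere ``kappa`` is NaN.
    """

    v: np.ndarray
    kappa: np.ndarray
    accel: np.ndarray
    kappa_defined: np.ndarray


def _gradient(y: np.ndarray, dt: float) -> np.ndarray:
    """Second-order finite differences (central interior, one-sided ends)."""
    return np.gradient(y, dt, axis=0, edge_order=2)


def differentiate(trace: Trace) -> Trace:
    """Attach finite-difference velocities and accelerations.

    Measured velocities, when present, are preserved; accelerations are
    always obtained by differentiating the velocity series.
    """
    if len(trace) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    vel = trace.velocities
    if vel is None:
        vel = _gradient(trace.positions, trace.dt)
    acc = trace.accelerations
    if acc is None:
        acc = _gradient(vel, trace.dt)
    return replace(trace, velocities=vel, accelerations=acc)


def speed_curvature(trace: Trace, v_zero: float = 1e-9) -> KinematicSeries:
    """Per-sample speed and unsigned curvature of a trace.

    ``kappa = |x' y'' - x'' y'| / v^3`` with the numerator from the
    velocity/acceleration cross product.  Samples with ``v <= v_zero`` get
    ``kappa = NaN`` and ``kappa_defined = False``.
    """
    trace = differentiate(trace)
    vel, acc = trace.velocities, trace.accelerations
    v = np.linalg.norm(vel, axis=1)
    cross = vel[:, 0] * acc[:, 1] - acc[:, 0] * vel[:, 1]
    defined = v > v_zero
    kappa = np.full_like(v, np.nan)
    kappa[defined] = np.abs(cross[defined]) / v[defined] ** 3
    return KinematicSeries(v=v, kappa=kappa, accel=acc, kappa_defined=defined)


def preprocess(
    series: KinematicSeries,
    profile: str = "human_demo",
    v_zero: float = DEFAULT_V_ZERO,
) -> np.ndarray:
    """Boolean sample mask implementing the power-law preprocessing filters.

    All profiles drop stationary samples (``v <= v_zero``) and
    near-straight samples (``kappa <= 1 /m``).  ``elm_eight`` additionally
    trims curvature outliers above the 85th percentile of the eligible
    samples; ``elm_new_curves`` further keeps only speeds inside the
    [10th, 90th] interpercentile band.  Percentiles are linear-interpolation
    empirical quantiles of the threshold-eligible samples.
    """
    if profile not in PREPROCESS_PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {PREPROCESS_PROFILES}")
    mask = series.kappa_defined & (series.v > v_zero)
    mask &= np.where(np.isnan(series.kappa), False, series.kappa > CURVATURE_THRESHOLD)
    if profile in ("elm_eight", "elm_new_curves") and mask.any():
        k85 = np.percentile(series.kappa[mask], 85.0)
        mask &= np.where(np.isnan(series.kappa), False, series.kappa <= k85)
    if profile == "elm_new_curves" and mask.any():
        v10, v90 = np.percentile(series.v[mask], [10.0, 90.0])
        mask &= (series.v >= v10) & (series.v <= v90)
    if not mask.any():
        raise EmptySelectionError(f"profile {profile!r} removed every sample")
    return mask


def reparameterize_trace(
    trace: Trace,
    curve: ParametricCurve,
    p_init: float,
    half_width: float = np.pi / 4,
) -> list[Projection]:
    """Sequential closest-point projection ``t -> p*`` of a whole trace.

    The projection for sample ``t`` searches ±``half_width`` around the
    previous sample's ``p*`` so the recovered parameter is continuous and
    stays on the branch selected by ``p_init``.  ``p_init`` must be chosen
    by the caller to reflect the direction of travel — at self-crossings
    (e.g. the center of a figure of eight) projections from different
    branches coincide spatially and only the initialization disambiguates
    them.
    """
    projections: list[Projection] = []
    p_prev = float(p_init)
    for r in trace.positions:
        proj = project_to_curve(curve, r, p_prev, half_width=half_width)
        projections.append(proj)
        p_prev = proj.p_star
    return projections


def resample(trace: Trace, rate: float = 100.0) -> Trace:
    """Resample to a uniform ``rate`` [Hz] by linear interpolation.

    Downsampling an integer factor hits the original samples exactly.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    new_dt = 1.0 / rate
    if np.isclose(new_dt, trace.dt, rtol=0, atol=1e-12):
        return trace
    t_old = trace.times
    t_new = np.arange(0.0, t_old[-1] + 1e-12, new_dt)
    cols = [np.interp(t_new, t_old, trace.positions[:, k]) for k in range(2)]
    positions = np.stack(cols, axis=1)
    velocities = None
    if trace.velocities is not None:
        vcols = [np.interp(t_new, t_old, trace.velocities[:, k]) for k in range(2)]
        velocities = np.stack(vcols, axis=1)
    return Trace(dt=new_dt, positions=positions, velocities=velocities, meta=dict(trace.meta))


# ---------------------------------------------------------------------------
# CSV interchange: header t,x,y[,vx,vy]; seconds and meters, '.' decimal.
# ---------------------------------------------------------------------------


def read_trace_csv(path_or_buffer, t_tol: float = 1e-6) -> Trace:
    """Read a trace from CSV with columns ``t,x,y`` and optional ``vx,vy``.

    Rejects non-uniform time stamps (deviation from the median step larger
    than ``t_tol`` seconds).
    """
    df = pd.read_csv(path_or_buffer)
    required = {"t", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace CSV must contain columns {sorted(required)}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("trace CSV needs at least 2 samples")
    steps = np.diff(t)
    dt = float(np.median(steps))
    if np.any(np.abs(steps - dt) > t_tol):
        raise ValueError("non-uniform time stamps in trace CSV")
    positions = df[["x", "y"]].to_numpy(dtype=float)
    velocities = None
    if {"vx", "vy"}.issubset(df.columns):
        velocities = df[["vx", "vy"]].to_numpy(dtype=float)
    return Trace(dt=dt, positions=positions, velocities=velocities)


def write_trace_csv(trace: Trace, path_or_buffer) -> None:
    """Write a trace as CSV (``t,x,y`` plus ``vx,vy`` when available)."""
    data = {"t": trace.times, "x": trace.positions[:, 0], "y": trace.positions[:, 1]}
    if trace.velocities is not None:
        data["vx"] = trace.velocities[:, 0]
        data["vy"] = trace.velocities[:, 1]
    pd.DataFrame(data).to_csv(path_or_buffer, index=False)
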