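"""Extreme learning machine with closed-form ridge readout.

The ELM is a single-layer random-feature network: a fixed random input
matrix ``C`` (scaled by ``c``) and bias ``zeta`` feed a tanh layer,

    x_t = tanh(c C z_t + zeta),        y_t = W x_t + b,

and only the affine readout ``(W, b)`` is trained, by ridge-regularized
least squares with an exact closed-form solution.  One reservoir instance
(one draw of ``C``) is shared across all demonstrators so that differences
between trained models reflect only tracing style, carried by the
subject-specific scaling ``c``, ridge strength ``lambda_rdg`` and readout.

Inputs are the rigid-motion invariants of a tracing sample — signed lateral
error, moving-frame curvature scaled by ``mu_0 = 50 /m`` and the wrapped
curve parameter scaled by ``p_0 = 10 rad`` — standardized with training-set
statistics; targets are the moving-frame velocities, likewise standardized.
The scale factors keep the raw inputs inside the active range of tanh.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .curves import (
    ParametricCurve,
    Projection,
    frame_at,
    wrap_parameter,
)
from .kinematics import Trace

__all__ = [
    "Reservoir",
    "Readout",
    "Normalizer",
    "TrainingSet",
    "ELMModel",
    "make_reservoir",
    "raw_observation",
    "build_training_set",
    "compute_states",
    "train_readout",
    "train_model",
    "tune_hyperparameters",
    "predict",
    "save_model",
    "load_model",
    "MU_0",
    "P_0",
    "DEFAULT_C_GRID",
    "DEFAULT_LAMBDA_GRID",
]

MU_0 = 50.0   # curvature normalization [1/m]
P_0 = 10.0    # parameter normalization [rad]
N_X_DEFAULT = 100
N_Z = 3
N_Y = 2

DEFAULT_C_GRID = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0)
DEFAULT_LAMBDA_GRID = tuple(float(x) for x in np.logspace(-8, -1, 8))

CURVATURE_MODES = ("arc_length", "parameter")


@dataclass(frozen=True)
class Reservoir:
    """Fixed random first layer: connectivity ``C`` (N_x x 3), bias ``zeta``."""

    C: np.ndarray
    zeta: np.ndarray
    seed: int
    law: str = "uniform"

    @property
    def n_x(self) -> int:
        return self.C.shape[0]


@dataclass(frozen=True)
class Readout:
    """Trained affine readout with its hyperparameters."""

    W: np.ndarray
    b: np.ndarray
    scaling_c: float
    lambda_ridge: float
    training_mse: float = float("nan")


@dataclass(frozen=True)
class Normalizer:
    """Training-set standardization statistics plus the fixed scale factors."""

    z_mean: np.ndarray
    z_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    mu0: float = MU_0
    p0: float = P_0

    def standardize_z(self, z_raw: np.ndarray) -> np.ndarray:
        return (z_raw - self.z_mean[:, None]) / self.z_std[:, None]

    def destandardize_y(self, y: np.ndarray) -> np.ndarray:
        return y * self.y_std[:, None] + self.y_mean[:, None]


@dataclass(frozen=True)
class TrainingSet:
    """Standardized invariant observations ``Z`` (3 x m) and moving-frame
    velocity targets ``Y`` (2 x m), with the raw versions kept for window
    re-fitting during hyperparameter tuning."""

    Z: np.ndarray
    Y: np.ndarray
    Z_raw: np.ndarray
    Y_raw: np.ndarray
    normalizer: Normalizer
    meta: Mapping = field(default_factory=dict)

    @property
    def m(self) -> int:
        return self.Z.shape[1]


@dataclass(frozen=True)
class ELMModel:
    """A trained tracing model: reservoir + readout + normalizer."""

    reservoir: Reservoir
    readout: Readout
    normalizer: Normalizer
    curvature_mode: str = "arc_length"
    meta: Mapping = field(default_factory=dict)


def make_reservoir(
    seed: int = 0, n_x: int = N_X_DEFAULT, n_z: int = N_Z, law: str = "uniform"
) -> Reservoir:
    """Draw the fixed random layer; ``law`` is ``'uniform'`` (continuous on
    [-1, 1]) or ``'sign'`` (discrete ±1).  The bias is zero."""
    rng = np.random.default_rng(seed)
    if law == "uniform":
        C = rng.uniform(-1.0, 1.0, size=(n_x, n_z))
    elif law == "sign":
        C = rng.choice([-1.0, 1.0], size=(n_x, n_z))
    else:
        raise ValueError("law must be 'uniform' or 'sign'")
    return Reservoir(C=C, zeta=np.zeros(n_x), seed=seed, law=law)


def raw_observation(
    curve: ParametricCurve,
    proj: Projection,
    curvature_mode: str = "arc_length",
) -> np.ndarray:
    """Raw (unstandardized) input vector ``(e, mu/mu0, wrap(p*)/p0)``.

    ``arc_length`` mode uses the Euclidean (arc-length) curvature — a true
    rigid-motion invariant.  ``parameter`` mode uses the parameter-space
    second derivative projected on the normal, ``<c_pp, n> = mu ||c_p||^2``,
    which depends on the curve's parameterization speed; it exists to
    demonstrate how a non-invariant input breaks generalization across
    re-parameterizations.
    """
    if curvature_mode not in CURVATURE_MODES:
        raise ValueError(f"curvature_mode must be one of {CURVATURE_MODES}")
    frame = frame_at(curve, proj.p_star)
    if curvature_mode == "arc_length":
        mu = frame.mu
    else:
        cpp = curve.second_derivative(proj.p_star)
        mu = float(frame.n @ cpp)
    period = curve.period if (curve.periodic and curve.period) else 2.0 * np.pi
    p_wrapped = float(wrap_parameter(proj.p_star, period))
    return np.array([proj.e, mu / MU_0, p_wrapped / P_0])


def build_training_set(
    trace: Trace,
    curve: ParametricCurve,
    projections: Sequence[Projection],
    curvature_mode: str = "arc_length",
    mask: np.ndarray | None = None,
) -> TrainingSet:
    """Invariant training set from a demonstration and its projections.

    Per sample the raw input is ``(e, mu/mu0, wrap(p*)/p0)`` and the raw
    target the moving-frame velocity ``M^T rdot``; both are demeaned and
    standardized with statistics stored in the returned normalizer.
    ``mask`` optionally restricts to non-stationary samples.
    """
    if trace.velocities is None:
        raise ValueError("trace must carry velocities (differentiate first)")
    if len(projections) != len(trace):
        raise ValueError("one projection per trace sample required")
    idx = np.arange(len(trace)) if mask is None else np.flatnonzero(mask)
    Z_raw = np.empty((N_Z, idx.size))
    Y_raw = np.empty((N_Y, idx.size))
    for j, i in enumerate(idx):
        proj = projections[i]
        Z_raw[:, j] = raw_observation(curve, proj, curvature_mode)
        frame = frame_at(curve, proj.p_star)
        Y_raw[:, j] = frame.M.T @ trace.velocities[i]
    z_mean, z_std = Z_raw.mean(axis=1), Z_raw.std(axis=1)
    y_mean, y_std = Y_raw.mean(axis=1), Y_raw.std(axis=1)
    z_std = np.where(z_std > 1e-12, z_std, 1.0)
    y_std = np.where(y_std > 1e-12, y_std, 1.0)
    norm = Normalizer(z_mean=z_mean, z_std=z_std, y_mean=y_mean, y_std=y_std)
    Z = (Z_raw - z_mean[:, None]) / z_std[:, None]
    Y = (Y_raw - y_mean[:, None]) / y_std[:, None]
    meta = {"curve": curve.name, "curvature_mode": curvature_mode, "m": int(idx.size)}
    return TrainingSet(Z=Z, Y=Y, Z_raw=Z_raw, Y_raw=Y_raw, normalizer=norm, meta=meta)


def compute_states(res: Reservoir, scaling_c: float, Z: np.ndarray) -> np.ndarray:
    """Reservoir states ``X = tanh(c C Z + zeta)``, column per sample."""
    if scaling_c <= 0:
        raise ValueError("scaling_c must be positive")
    Z = np.atleast_2d(Z)
    if Z.shape[0] != res.C.shape[1]:
        raise ValueError(
            f"input dimension {Z.shape[0]} does not match reservoir ({res.C.shape[1]})"
        )
    return np.tanh(scaling_c * (res.C @ Z) + res.zeta[:, None])


def train_readout(
    X: np.ndarray, Y: np.ndarray, lambda_ridge: float,
    scaling_c: float = float("nan"),
) -> Readout:
    """Exact minimizer of ``||Y - W X - b 1^T||_F^2 + lambda ||W||_F^2``.

    The stationarity condition in ``b`` centers the problem, so the closed
    form is the centered ridge solution ``W = Y_c X_c^T (X_c X_c^T +
    lambda I)^{-1}`` with ``b = y_mean - W x_mean``; solved via a symmetric
    positive-definite factorization, never an explicit inverse.
    """
    if lambda_ridge < 0:
        raise ValueError("lambda_ridge must be >= 0")
    X = np.atleast_2d(X)
    Y = np.atleast_2d(Y)
    x_mean = X.mean(axis=1)
    y_mean = Y.mean(axis=1)
    Xc = X - x_mean[:, None]
    Yc = Y - y_mean[:, None]
    G = Xc @ Xc.T + lambda_ridge * np.eye(X.shape[0])
    try:
        Cf = np.linalg.cholesky(G)
        W = np.linalg.solve(Cf.T, np.linalg.solve(Cf, Xc @ Yc.T)).T
    except np.linalg.LinAlgError as exc:
        if lambda_ridge == 0:
            raise np.linalg.LinAlgError(
                "singular state covariance at lambda_ridge = 0"
            ) from exc
        raise
    b = y_mean - W @ x_mean
    resid = Y - W @ X - b[:, None]
    mse = float(np.mean(np.sum(resid**2, axis=0)))
    return Readout(W=W, b=b, scaling_c=scaling_c, lambda_ridge=lambda_ridge,
                   training_mse=mse)


def train_model(
    reservoir: Reservoir,
    training: TrainingSet,
    scaling_c: float,
    lambda_ridge: float,
    curvature_mode: str = "arc_length",
    meta: Mapping | None = None,
) -> ELMModel:
    """Fit the readout on a full training set and assemble a model."""
    X = compute_states(reservoir, scaling_c, training.Z)
    readout = train_readout(X, training.Y, lambda_ridge, scaling_c=scaling_c)
    return ELMModel(
        reservoir=reservoir,
        readout=readout,
        normalizer=training.normalizer,
        curvature_mode=curvature_mode,
        meta=dict(meta or {}),
    )


def predict(model: ELMModel, z_raw: np.ndarray) -> np.ndarray:
    """Moving-frame velocity [m/s] predicted for raw invariant input(s).

    ``z_raw`` is a 3-vector or a (3, k) matrix; standardization and
    de-standardization use the model's stored training statistics.
    """
    z = np.asarray(z_raw, dtype=float)
    single = z.ndim == 1
    if single:
        z = z[:, None]
    zs = model.normalizer.standardize_z(z)
    X = compute_states(model.reservoir, model.readout.scaling_c, zs)
    Y = model.readout.W @ X + model.readout.b[:, None]
    out = model.normalizer.destandardize_y(Y)
    return out[:, 0] if single else out


def tune_hyperparameters(
    reservoir: Reservoir,
    trace: Trace,
    curve: ParametricCurve,
    projections: Sequence[Projection],
    curvature_mode: str = "arc_length",
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    l: int = 100,
    alpha: float = 0.05,
    mask: np.ndarray | None = None,
    metric: str = "velocity",
):
    """Sliding-window validation of ``(scaling_c, lambda_ridge)``.

    Validation windows start at the indices ``S = {10, 20, ..,
    floor((m - l)/4)}``; each window of length ``floor(3(m - l)/4) -
    floor(l/2)`` trains a candidate readout, which is then run self-looped
    for ``l`` autonomous steps from the window's end and scored by the mean
    squared error against the next ``l`` recorded samples.  The candidate
    pair minimizing the mean validation error wins; the caller refits on
    the full sample afterwards (see :func:`train_model`).

    ``metric`` selects the space the autonomous run is scored in:
    ``"velocity"`` (default) compares the predicted velocities with the
    recorded ones — this directly discriminates models that flatten the
    speed profile, which time-aligned position error largely forgives
    because phase errors partially integrate out; ``"position"`` compares
    integrated positions.

    Returns ``(c_star, lambda_star, error_surface)`` where the error
    surface is indexed ``[i_c, i_lambda]``.
    """
    from .selfloop import SelfLoopConfig, autonomous_trace  # local: avoid cycle

    if metric not in ("velocity", "position"):
        raise ValueError("metric must be 'velocity' or 'position'")
    training = build_training_set(trace, curve, projections, curvature_mode, mask)
    idx = np.arange(len(trace)) if mask is None else np.flatnonzero(mask)
    m = training.m
    if len(c_grid) == 0 or len(lambda_grid) == 0:
        raise ValueError("hyperparameter grids must be non-empty")
    s_max = (m - l) // 4
    S = list(range(10, s_max + 1, 10))
    if not S:
        raise ValueError(f"training sample too short for validation windows (m={m})")
    L = (3 * (m - l)) // 4 - l // 2
    if L < 1:
        raise ValueError(
            f"training sample too short: window length {L} for m={m}, l={l}"
        )

    errors = np.zeros((len(c_grid), len(lambda_grid)))
    for ic, c in enumerate(c_grid):
        X_all = compute_states(reservoir, c, training.Z)
        for il, lam in enumerate(lambda_grid):
            total = 0.0
            for i in S:
                sl = slice(i, min(i + L, m))
                readout = train_readout(X_all[:, sl], training.Y[:, sl], lam,
                                        scaling_c=c)
                cand = ELMModel(
                    reservoir=reservoir,
                    readout=readout,
                    normalizer=training.normalizer,
                    curvature_mode=curvature_mode,
                )
                start = sl.stop - 1
                val = idx[start + 1 : start + 1 + l]
                if val.size == 0:
                    continue
                cfg = SelfLoopConfig(
                    dt=trace.dt,
                    duration=val.size * trace.dt,
                    alpha=alpha,
                    r0=trace.positions[idx[start]],
                    p_init=projections[idx[start]].p_star,
                    max_error=np.inf,
                )
                result = autonomous_trace(cand, curve, cfg)
                if metric == "velocity":
                    pred = result.trace.velocities[1 : val.size + 1]
                    ref = trace.velocities[val]
                else:
                    pred = result.trace.positions[1 : val.size + 1]
                    ref = trace.positions[val]
                n_cmp = min(len(pred), len(ref))
                total += float(
                    np.mean(np.sum((pred[:n_cmp] - ref[:n_cmp]) ** 2, axis=1))
                )
            errors[ic, il] = total / len(S)
    ic, il = np.unravel_index(int(np.argmin(errors)), errors.shape)
    return float(c_grid[ic]), float(lambda_grid[il]), errors


# ---------------------------------------------------------------------------
# Serialization: single .npz archive, bit-exact round trip.
# ---------------------------------------------------------------------------


def save_model(model: ELMModel, path) -> None:
    """Serialize a model to a single ``.npz`` archive (bit-exact)."""
    np.savez(
        path,
        C=model.reservoir.C,
        zeta=model.reservoir.zeta,
        reservoir_seed=np.int64(model.reservoir.seed),
        law=np.str_(model.reservoir.law),
        W=model.readout.W,
        b=model.readout.b,
        scaling_c=np.float64(model.readout.scaling_c),
        lambda_ridge=np.float64(model.readout.lambda_ridge),
        training_mse=np.float64(model.readout.training_mse),
        z_mean=model.normalizer.z_mean,
        z_std=model.normalizer.z_std,
        y_mean=model.normalizer.y_mean,
        y_std=model.normalizer.y_std,
        mu0=np.float64(model.normalizer.mu0),
        p0=np.float64(model.normalizer.p0),
        curvature_mode=np.str_(model.curvature_mode),
    )


def load_model(path) -> ELMModel:
    """Load a model saved by :func:`save_model`."""
    with np.load(path, allow_pickle=False) as d:
        reservoir = Reservoir(
            C=d["C"], zeta=d["zeta"], seed=int(d["reservoir_seed"]), law=str(d["law"])
        )
        readout = Readout(
            W=d["W"], b=d["b"],
            scaling_c=float(d["scaling_c"]),
            lambda_ridge=float(d["lambda_ridge"]),
            training_mse=float(d["training_mse"]),
        )
        normalizer = Normalizer(
            z_mean=d["z_mean"], z_std=d["z_std"],
            y_mean=d["y_mean"], y_std=d["y_std"],
            mu0=float(d["mu0"]), p0=float(d["p0"]),
        )
        return ELMModel(
            reservoir=reservoir,
            readout=readout,
            normalizer=normalizer,
            curvature_mode=str(d["curvature_mode"]),
        )
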