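"""Two-regime (piecewise) speed–curvature power law.

The model: speed is constant at the critical speed ``v_c`` wherever the
path curvature is below the critical curvature ``kappa_c``, and decays as a
power law above it::

    v(kappa) = v_c                          if kappa <  kappa_c
             = v_c (kappa/kappa_c)^(-beta)  otherwise

with the slope fixed at ``beta = 1/3``.  In log space this is a continuous
piecewise-linear model with a single breakpoint,

    log v = log v_c + beta (log kappa_c - log kappa) (1 + sign(kappa - kappa_c)) / 2,

fitted by least squares over ``(log v_c, log kappa_c)``.  Because the
critical speed enters linearly it is profiled out exactly for any candidate
breakpoint, leaving a one-dimensional, piecewise-smooth objective in
``log kappa_c`` which is minimized on a dense candidate grid (midpoints of
the sorted unique curvatures) followed by bounded local refinement.

Breakpoint estimates from self-looped machine tracings are biased upward
when the high-curvature tail is thin; :func:`fit_piecewise_penalized`
counteracts this with a ridge penalty ``lambda_pen * (log kappa_c)^2`` whose
strength is selected on a held-out 20% split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "PowerLawFit",
    "predict_speed",
    "fit_piecewise",
    "fit_piecewise_penalized",
    "loglog_slope",
    "DEFAULT_PENALTY_GRID",
]

DEFAULT_BETA = 1.0 / 3.0

#: Penalty strengths searched by the cross-validated breakpoint estimator.
DEFAULT_PENALTY_GRID = tuple(float(x) for x in np.logspace(-4, -1, 7)) + (0.0,)

MIN_SAMPLES = 20


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted two-regime power law.

    ``beta`` is stored positive; the model uses ``-beta`` as the exponent.
    ``kappa_c_censored`` is set when the data never leaves the constant-speed
    plateau, in which case ``kappa_c`` is only a lower bound (the largest
    observed curvature).
    """

    v_c: float
    kappa_c: float
    beta: float
    rss: float
    n_used: int
    kappa_c_censored: bool = False
    penalty: float = 0.0
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @staticmethod
    def from_json(s: str) -> "PowerLawFit":
        return PowerLawFit(**json.loads(s))


def predict_speed(fit: PowerLawFit, kappa):
    """Model speed at curvature ``kappa`` (> 0); scalar or array."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa <= 0):
        raise ValueError("kappa must be positive")
    out = np.where(
        kappa < fit.kappa_c,
        fit.v_c,
        fit.v_c * (kappa / fit.kappa_c) ** (-fit.beta),
    )
    return float(out) if out.ndim == 0 else out


def _check_inputs(v, kappa):
    v = np.asarray(v, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    if v.shape != kappa.shape or v.ndim != 1:
        raise ValueError("v and kappa must be 1-D arrays of equal length")
    if np.any(v <= 0) or np.any(kappa <= 0) or not np.all(np.isfinite(v * kappa)):
        raise ValueError("v and kappa must be positive and finite (preprocess first)")
    return v, kappa


def _profiled_rss(x, y, t, beta, penalty):
    """RSS at breakpoint ``t = log kappa_c`` with log v_c profiled out.

    ``x = log kappa``, ``y = log v``.  Returns (objective, log v_c, rss):
    objective = rss + penalty * t**2.
    """
    shifted = y + beta * np.maximum(x - t, 0.0)  # = log v_c + residual
    u = float(np.mean(shifted))
    rss = float(np.sum((shifted - u) ** 2))
    return rss + penalty * t * t, u, rss


_MAX_BREAK_CANDIDATES = 512


def _fit_breakpoint(x, y, beta, penalty):
    """Minimize the profiled objective over t on grid + local refinement."""
    xs = np.unique(x)
    plateau_obj, plateau_u, plateau_rss = _profiled_rss(
        x, y, xs[-1] + 1.0, beta, 0.0
    )  # breakpoint above all data: pure plateau, penalty not meaningful there
    if xs.size < 2:
        return xs[-1], plateau_u, plateau_rss, True

    if xs.size > _MAX_BREAK_CANDIDATES + 1:
        # quantile-thin the candidate anchors; exactness is restored by the
        # bounded refinement between neighboring anchors
        q = np.linspace(0.0, 1.0, _MAX_BREAK_CANDIDATES + 1)
        xs = np.unique(np.quantile(xs, q))
    candidates = 0.5 * (xs[:-1] + xs[1:])
    objs = np.array([_profiled_rss(x, y, t, beta, penalty)[0] for t in candidates])
    k = int(np.argmin(objs))
    lo = xs[max(k, 0)]
    hi = xs[min(k + 1, xs.size - 1)]
    res = minimize_scalar(
        lambda t: _profiled_rss(x, y, t, beta, penalty)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    t_best, obj_best = float(res.x), float(res.fun)
    if objs[k] < obj_best:
        t_best, obj_best = float(candidates[k]), float(objs[k])
    # censored plateau: the all-plateau model fits at least as well (within
    # numerical slack) as any interior breakpoint
    if penalty == 0.0 and plateau_obj <= obj_best + 1e-12:
        return xs[-1], plateau_u, plateau_rss, True
    _, u, rss = _profiled_rss(x, y, t_best, beta, penalty)
    return t_best, u, rss, False


def fit_piecewise(v, kappa, beta: float = DEFAULT_BETA) -> PowerLawFit:
    """Least-squares fit of the two-regime power law with fixed slope.

    Requires preprocessed data (positive finite speeds and curvatures,
    ``>= 20`` samples).  Deterministic given the data.  When every sample
    lies on the plateau the critical curvature is unidentified: ``v_c`` is
    still estimated and ``kappa_c_censored`` is set.
    """
    v, kappa = _check_inputs(v, kappa)
    if v.size < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, got {v.size}")
    x, y = np.log(kappa), np.log(v)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate fit: all curvatures identical")
    t, u, rss, censored = _fit_breakpoint(x, y, beta, penalty=0.0)
    return PowerLawFit(
        v_c=float(np.exp(u)),
        kappa_c=float(np.exp(t)),
        beta=beta,
        rss=rss,
        n_used=int(v.size),
        kappa_c_censored=censored,
    )


def fit_piecewise_penalized(
    v,
    kappa,
    beta: float = DEFAULT_BETA,
    penalty_grid=DEFAULT_PENALTY_GRID,
    holdout_frac: float = 0.2,
    seed: int | None = 0,
) -> PowerLawFit:
    """Breakpoint fit with ridge penalty on ``log kappa_c``, CV-selected.

    For each penalty strength the model is fitted on a random 80% of the
    samples (seeded split) and scored by prediction RSS on the held-out
    20%; the strength with the smallest validation error wins (ties go to
    the smallest penalty) and the model is refitted on all samples with it.
    A grid of ``{0}`` reduces exactly to :func:`fit_piecewise`.
    """
    v, kappa = _check_inputs(v, kappa)
    penalty_grid = sorted(float(p) for p in penalty_grid)
    if len(penalty_grid) == 0 or penalty_grid[0] < 0:
        raise ValueError("penalty_grid must be non-empty with values >= 0")
    if not 0.0 < holdout_frac < 1.0:
        raise ValueError("holdout_frac must be in (0, 1)")
    n = v.size
    n_hold = int(round(holdout_frac * n))
    n_train = n - n_hold
    if n_train < MIN_SAMPLES or n_hold < 1:
        raise ValueError("insufficient training data after holdout split")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    hold, train = perm[:n_hold], perm[n_hold:]
    x, y = np.log(kappa), np.log(v)

    best = None
    for pen in penalty_grid:
        t, u, _, _ = _fit_breakpoint(x[train], y[train], beta, pen)
        pred = u - beta * np.maximum(x[hold] - t, 0.0)
        val = float(np.sum((y[hold] - pred) ** 2))
        if best is None or val < best[0] - 1e-15:
            best = (val, pen)
    pen_star = best[1]

    t, u, rss, censored = _fit_breakpoint(x, y, beta, pen_star)
    return PowerLawFit(
        v_c=float(np.exp(u)),
        kappa_c=float(np.exp(t)),
        beta=beta,
        rss=rss,
        n_used=int(n),
        kappa_c_censored=censored,
        penalty=pen_star,
        seed=seed,
    )


def loglog_slope(v, kappa) -> float:
    """Unconstrained OLS slope of ``log v`` on ``log kappa``.

    Diagnostic for the classical one-third law (slope ≈ −1/3 for
    power-law-compliant movement).
    """
    v, kappa = _check_inputs(v, kappa)
    if v.size < 3:
        raise ValueError("need at least 3 samples")
    x, y = np.log(kappa), np.log(v)
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in log kappa; slope undefined")
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)
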