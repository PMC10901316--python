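"""Planar parametric curves and their Euclidean invariants.

A reference curve is a smooth map ``p -> c(p)`` into the plane.  Everything
the learning machinery consumes is expressed in the *moving frame* attached
to the closest point of the reference curve: the unit tangent ``t``, the
unit normal ``n = J t`` (``J`` the fixed 90-degree counter-clockwise
rotation), the rotation matrix ``M = [t n]`` and the signed Euclidean
curvature ``mu``.  Quantities expressed in this frame are invariant under
rigid motions of the workspace, which is what makes tracing styles learned
on one placement of a curve transfer to any other placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "ParametricCurve",
    "MovingFrame",
    "Projection",
    "InvariantObservation",
    "SingularPointError",
    "J",
    "frame_at",
    "project_to_curve",
    "to_moving_frame",
    "make_named_curve",
    "affine_transform",
    "curve_from_config",
    "wrap_parameter",
    "NAMED_CURVES",
]

#: Fixed 90-degree counter-clockwise rotation mapping tangent to normal.
J = np.array([[0.0, -1.0], [1.0, 0.0]])

_REGULARITY_TOL = 1e-12


class SingularPointError(ValueError):
    """Raised where ``‖c_p(p)‖`` vanishes (cusp / degenerate parameterization)."""


@dataclass(frozen=True)
class ParametricCurve:
    """Smooth planar curve ``p -> c(p)`` with derivative access.

    Parameters
    ----------
    position_fn, first_derivative_fn, second_derivative_fn
        Vectorized callables mapping a parameter array of shape ``(...)`` to
        points of shape ``(..., 2)`` in meters.  Built-in curves attach
        analytic derivatives; :func:`ParametricCurve.from_position` builds
        central finite-difference fallbacks.
    domain
        Closed parameter interval the curve is defined on.
    periodic, period
        Whether ``c(p + period) == c(p)``; ``period`` is required when
        periodic.
    name
        Identifier used in serialized configurations and provenance.
    """

    position_fn: Callable[[np.ndarray], np.ndarray]
    first_derivative_fn: Callable[[np.ndarray], np.ndarray]
    second_derivative_fn: Callable[[np.ndarray], np.ndarray]
    domain: tuple[float, float] = (0.0, 2.0 * np.pi)
    periodic: bool = True
    period: float | None = 2.0 * np.pi
    name: str = "custom"
    meta: Mapping = field(default_factory=dict)

    def position(self, p) -> np.ndarray:
        return np.asarray(self.position_fn(np.asarray(p, dtype=float)))

    def first_derivative(self, p) -> np.ndarray:
        return np.asarray(self.first_derivative_fn(np.asarray(p, dtype=float)))

    def second_derivative(self, p) -> np.ndarray:
        return np.asarray(self.second_derivative_fn(np.asarray(p, dtype=float)))

    @staticmethod
    def from_position(position_fn, *, step: float = 1e-5, **kwargs) -> "ParametricCurve":
        """Build a curve from a position map alone, with central
        finite-difference first and second derivatives at ``step``."""

        def d1(p):
            return (position_fn(p + step) - position_fn(p - step)) / (2.0 * step)

        def d2(p):
            return (
                position_fn(p + step) - 2.0 * position_fn(p) + position_fn(p - step)
            ) / step**2

        return ParametricCurve(position_fn, d1, d2, **kwargs)


@dataclass(frozen=True)
class MovingFrame:
    """Orthonormal frame at a curve point: tangent, normal, ``M = [t n]``
    and the signed Euclidean curvature ``mu`` [1/m]."""

    t: np.ndarray
    n: np.ndarray
    M: np.ndarray
    mu: float


@dataclass(frozen=True)
class Projection:
    """Closest-point projection of a query point onto the reference curve.

    ``e`` is the signed lateral error ``<n(p*), r - c(p*)>`` [m]; positive
    means the tracer sits to the left of the direction of travel.
    ``interior`` is False when the minimizer landed on the boundary of the
    local search interval, in which case the orthogonality of ``r - c(p*)``
    to the tangent is not guaranteed.
    """

    p_star: float
    e: float
    distance: float
    interior: bool


@dataclass(frozen=True)
class InvariantObservation:
    """Moving-frame observation triple plus moving-frame velocity.

    Fields: signed error ``e`` [m], signed curvature ``mu`` [1/m] at the
    closest point, curve parameter ``p_star`` [rad], and the velocity
    rotated into the moving frame ``rdot_moving = M^T rdot`` [m/s].
    """

    e: float
    mu: float
    p_star: float
    rdot_moving: np.ndarray


def wrap_parameter(p, period: float, tol: float = 1e-9) -> np.ndarray:
    """Wrap an (unwrapped) parameter to the fundamental interval [0, period).

    Values within ``tol`` of the upper boundary snap to 0 so that a
    parameter sitting numerically *on* a period boundary wraps identically
    from either side (the wrapped value feeds the learned model, and a
    solver-tolerance sign flip there would otherwise move the input by a
    full period).
    """
    w = np.mod(p, period)
    return np.where(w > period - tol, 0.0, w)


def frame_at(curve: ParametricCurve, p: float) -> MovingFrame:
    """Moving frame and signed curvature of ``curve`` at parameter ``p``.

    The curvature is evaluated directly from parameter derivatives,
    ``mu = <c_pp, J c_p> / ‖c_p‖³``, which is algebraically identical to the
    arc-length definition ``<c_ss, n>`` (the ``s_pp`` term is orthogonal to
    the normal) and avoids inverting ``s(p)`` numerically.
    """
    cp = curve.first_derivative(p)
    cpp = curve.second_derivative(p)
    speed = float(np.linalg.norm(cp))
    if speed <= _REGULARITY_TOL:
        raise SingularPointError(f"curve '{curve.name}' is singular at p={p!r}")
    t = cp / speed
    n = J @ t
    mu = float(cpp @ (J @ cp)) / speed**3
    M = np.column_stack([t, n])
    return MovingFrame(t=t, n=n, M=M, mu=mu)


def _clip_interval(curve: ParametricCurve, lo: float, hi: float) -> tuple[float, float]:
    """Restrict a search interval to the curve's domain for non-periodic
    curves; periodic curves extend over the whole real line."""
    if curve.periodic:
        return lo, hi
    dlo, dhi = curve.domain
    return max(lo, dlo), min(hi, dhi)


def project_to_curve(
    curve: ParametricCurve,
    r: np.ndarray,
    p_prev: float,
    half_width: float = np.pi / 4,
    n_grid: int = 64,
) -> Projection:
    """Locally-closest point on ``curve`` to ``r`` near parameter ``p_prev``.

    Minimizes ``‖r - c(p)‖²`` over ``I = [p_prev - half_width,
    p_prev + half_width]`` with a coarse grid seed followed by bounded
    scalar minimization.  The deliberately local interval (default ±π/4)
    excludes competing minima on curves with adjoining loops; the caller
    chains ``p_prev`` from sample to sample so the recovered parameter stays
    on the intended branch.  Parameters are kept unwrapped.
    """
    r = np.asarray(r, dtype=float)
    lo, hi = _clip_interval(curve, p_prev - half_width, p_prev + half_width)
    if not hi > lo:
        raise ValueError("empty projection search interval (outside curve domain)")

    grid = np.linspace(lo, hi, n_grid)
    d2 = np.sum((curve.position(grid) - r) ** 2, axis=-1)
    k = int(np.argmin(d2))
    blo = grid[max(k - 1, 0)]
    bhi = grid[min(k + 1, n_grid - 1)]

    def objective(p):
        return float(np.sum((curve.position(p) - r) ** 2))

    res = minimize_scalar(
        objective, bounds=(blo, bhi), method="bounded", options={"xatol": 1e-12}
    )
    p_star = float(res.x)
    if objective(p_star) > d2[k]:  # guard: refinement must not lose to the grid
        p_star = float(grid[k])

    # Newton polish on the orthogonality residual g(p) = <c_p, r - c(p)>;
    # bounded minimization alone leaves g at ~sqrt(eps) of the local scale.
    for _ in range(3):
        cp = curve.first_derivative(p_star)
        delta = r - curve.position(p_star)
        g = float(cp @ delta)
        gp = float(curve.second_derivative(p_star) @ delta) - float(cp @ cp)
        if gp >= 0 or not np.isfinite(gp):
            break
        step = g / gp
        cand = p_star - step
        if not lo <= cand <= hi:
            break
        p_star = cand
        if abs(step) < 1e-14:
            break

    edge = 1e-9 * max(1.0, hi - lo)
    interior = (p_star > lo + edge) and (p_star < hi - edge)
    frame = frame_at(curve, p_star)
    delta = r - curve.position(p_star)
    e = float(frame.n @ delta)
    return Projection(
        p_star=p_star,
        e=e,
        distance=float(np.linalg.norm(delta)),
        interior=interior,
    )


def to_moving_frame(
    curve: ParametricCurve,
    r: np.ndarray,
    rdot: np.ndarray,
    proj: Projection,
) -> InvariantObservation:
    """Express a sample in the moving frame at its projection.

    Returns the rigid-motion invariants ``(e, mu, p_star)`` together with
    the moving-frame velocity ``M^T rdot``.  For interior projections the
    tangential component of ``r - c(p*)`` vanishes by the optimality of
    ``p*``; it is asserted here rather than returned.
    """
    frame = frame_at(curve, proj.p_star)
    delta = np.asarray(r, dtype=float) - curve.position(proj.p_star)
    if proj.interior:
        tang = abs(float(frame.t @ delta))
        assert tang <= 1e-6 * np.linalg.norm(delta) + 1e-9, (
            f"non-orthogonal interior projection (tangential residual {tang:g})"
        )
    rdot_moving = frame.M.T @ np.asarray(rdot, dtype=float)
    return InvariantObservation(
        e=proj.e, mu=frame.mu, p_star=proj.p_star, rdot_moving=rdot_moving
    )


# ---------------------------------------------------------------------------
# Built-in curve library
# ---------------------------------------------------------------------------


def _stack(x, y):
    return np.stack([np.asarray(x, dtype=float), np.asarray(y, dtype=float)], axis=-1)


def _figure_eight_fns(n: float = 1.0):
    def pos(p):
        return _stack(0.05 * np.sin(2 * n * p), 0.1 * np.sin(n * p))

    def d1(p):
        return _stack(0.1 * n * np.cos(2 * n * p), 0.1 * n * np.cos(n * p))

    def d2(p):
        return _stack(-0.2 * n**2 * np.sin(2 * n * p), -0.1 * n**2 * np.sin(n * p))

    return pos, d1, d2


def _make_figure_eight() -> ParametricCurve:
    pos, d1, d2 = _figure_eight_fns(1.0)
    return ParametricCurve(pos, d1, d2, name="figure_eight")


def _make_speed_scaled_eight(n: float = 2.0) -> ParametricCurve:
    if n <= 0:
        raise ValueError("speed factor n must be positive")
    pos, d1, d2 = _figure_eight_fns(n)
    return ParametricCurve(
        pos, d1, d2,
        domain=(0.0, 2.0 * np.pi / n),
        period=2.0 * np.pi / n,
        name="speed_scaled_eight",
        meta={"n": n},
    )


def _make_affine_eight_c1() -> ParametricCurve:
    A = np.array([[2.1, -0.7], [3.5, 2.1]])
    return affine_transform(_make_figure_eight(), A, np.zeros(2), name="affine_eight_c1")


def _make_quadrifolium_c2() -> ParametricCurve:
    # x = 0.4 sin(2p) cos(p), y = 0.7 sin(p) sin(2p)
    def pos(p):
        return _stack(0.4 * np.sin(2 * p) * np.cos(p), 0.7 * np.sin(p) * np.sin(2 * p))

    def d1(p):
        return _stack(
            0.8 * np.cos(2 * p) * np.cos(p) - 0.4 * np.sin(2 * p) * np.sin(p),
            0.7 * np.cos(p) * np.sin(2 * p) + 1.4 * np.sin(p) * np.cos(2 * p),
        )

    def d2(p):
        return _stack(
            -2.0 * np.sin(2 * p) * np.cos(p) - 1.6 * np.cos(2 * p) * np.sin(p),
            -3.5 * np.sin(p) * np.sin(2 * p) + 2.8 * np.cos(p) * np.cos(2 * p),
        )

    return ParametricCurve(pos, d1, d2, name="quadrifolium_c2")


def _make_ellipse_c3() -> ParametricCurve:
    def pos(p):
        return _stack(0.6 * np.sin(p), 0.2 * np.cos(p))

    def d1(p):
        return _stack(0.6 * np.cos(p), -0.2 * np.sin(p))

    def d2(p):
        return _stack(-0.6 * np.sin(p), -0.2 * np.cos(p))

    return ParametricCurve(pos, d1, d2, name="ellipse_c3")


def _make_spiral_c4(domain: tuple[float, float] = (0.0, 3.0 * np.pi)) -> ParametricCurve:
    # c4(p) = 0.05 (p + pi/4) (cos 5p, sin 5p); radius stays positive for
    # p > -pi/4, hence the default domain starting at 0.
    def pos(p):
        rad = 0.05 * (p + np.pi / 4)
        return _stack(rad * np.cos(5 * p), rad * np.sin(5 * p))

    def d1(p):
        rad = 0.05 * (p + np.pi / 4)
        return _stack(
            0.05 * np.cos(5 * p) - 5 * rad * np.sin(5 * p),
            0.05 * np.sin(5 * p) + 5 * rad * np.cos(5 * p),
        )

    def d2(p):
        rad = 0.05 * (p + np.pi / 4)
        return _stack(
            -0.5 * np.sin(5 * p) - 25 * rad * np.cos(5 * p),
            0.5 * np.cos(5 * p) - 25 * rad * np.sin(5 * p),
        )

    return ParametricCurve(
        pos, d1, d2, domain=tuple(domain), periodic=False, period=None, name="spiral_c4"
    )


NAMED_CURVES = (
    "figure_eight",
    "affine_eight_c1",
    "quadrifolium_c2",
    "ellipse_c3",
    "spiral_c4",
    "speed_scaled_eight",
)


def make_named_curve(name: str, **options) -> ParametricCurve:
    """Construct one of the built-in reference curves by name.

    ``figure_eight`` is the demonstration curve; ``affine_eight_c1``,
    ``quadrifolium_c2``, ``ellipse_c3`` and ``spiral_c4`` are the
    generalization targets; ``speed_scaled_eight`` re-parameterizes the
    figure of eight at ``n`` times the parameter speed (``options['n']``,
    default 2) while traversing the identical point set.
    """
    if name == "figure_eight":
        return _make_figure_eight()
    if name == "affine_eight_c1":
        return _make_affine_eight_c1()
    if name == "quadrifolium_c2":
        return _make_quadrifolium_c2()
    if name == "ellipse_c3":
        return _make_ellipse_c3()
    if name == "spiral_c4":
        if "domain" in options and options["domain"] is not None:
            return _make_spiral_c4(tuple(options["domain"]))
        return _make_spiral_c4()
    if name == "speed_scaled_eight":
        return _make_speed_scaled_eight(float(options.get("n", 2.0)))
    raise ValueError(f"unknown curve name {name!r}; choose from {NAMED_CURVES}")


def affine_transform(
    curve: ParametricCurve,
    A: np.ndarray,
    d: np.ndarray | Sequence[float] = (0.0, 0.0),
    name: str | None = None,
) -> ParametricCurve:
    """Curve ``p -> A c(p) + d`` with derivatives transformed accordingly."""
    A = np.asarray(A, dtype=float)
    d = np.asarray(d, dtype=float)
    if A.shape != (2, 2) or abs(np.linalg.det(A)) < 1e-15:
        raise ValueError("A must be a non-singular 2x2 matrix")

    def pos(p):
        return curve.position(p) @ A.T + d

    def d1(p):
        return curve.first_derivative(p) @ A.T

    def d2(p):
        return curve.second_derivative(p) @ A.T

    return ParametricCurve(
        pos, d1, d2,
        domain=curve.domain,
        periodic=curve.periodic,
        period=curve.period,
        name=name or f"affine({curve.name})",
        meta={"base": curve.name},
    )


def curve_from_config(config: Mapping) -> ParametricCurve:
    """Build a curve from a plain config mapping.

    Schema: ``{name, params: {n, A, d, domain}}``.  ``A``/``d`` apply an
    affine transform on top of the named base curve.
    """
    name = config["name"]
    params = dict(config.get("params", {}) or {})
    A = params.pop("A", None)
    d = params.pop("d", None)
    curve = make_named_curve(name, **params)
    if A is not None or d is not None:
        curve = affine_transform(
            curve,
            np.eye(2) if A is None else np.asarray(A, dtype=float),
            np.zeros(2) if d is None else np.asarray(d, dtype=float),
        )
    return curve
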