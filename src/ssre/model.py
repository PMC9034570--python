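"""Closed-form solutions of the Zeisel two-stage model of RNA kinetics.

The model describes premature (unspliced) RNA ``p`` and mature RNA ``m`` of
one transcript with constant synthesis rate ``alpha``, processing rate
``beta`` and degradation rate ``gamma``::

    dp/dt = alpha - beta * p
    dm/dt = beta * p - gamma * m

In a metabolic-labeling pulse of duration ``T`` the RNA splits into two
pools: the *unlabeled* (pre-existing) pool, which starts at steady state and
receives no new premature RNA, and the *labeled* (newly synthesized) pool,
which starts empty.  Both pools follow the same linear system and admit the
closed-form solutions implemented here.

The observable the inference works with is the intron-to-exon abundance
ratio ``p / (p + m)`` of each pool at the single time point ``T``.  After
the reparametrization ``k = beta/gamma``, ``x = gamma*T`` these two ratios
``(a, b)`` depend on ``(k, x)`` only — they are independent of ``alpha`` —
which is what makes single-sample inference possible.

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "RateTriplet",
    "ReducedParams",
    "PoolState",
    "K_DEGENERATE_TOL",
    "unlabeled_solution",
    "labeled_solution",
    "ratio_unlabeled",
    "ratio_labeled",
    "trajectory",
    "ode_oracle",
]

#: below this |k - 1| the closed forms are evaluated by their analytic
#: limit (the printed formulas divide by gamma - beta)
K_DEGENERATE_TOL = 1e-6


@dataclass(frozen=True)
class RateTriplet:
    """Kinetic parameters of one transcript, per unit of labeling time.

    alpha is in transcript-abundance units per time unit; beta and gamma
    are first-order rate constants (1/time).  The library never converts
    units: rates come out per whatever unit ``T`` is supplied in.
    """

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0 and self.gamma > 0):
            raise ValueError(
                f"rates must be positive, got alpha={self.alpha}, "
                f"beta={self.beta}, gamma={self.gamma}"
            )

    @property
    def k(self) -> float:
        """Dimensionless processing-to-degradation ratio beta/gamma."""
        return self.beta / self.gamma


@dataclass(frozen=True)
class ReducedParams:
    """Dimensionless parametrization (k = beta/gamma, x = gamma*T)."""

    k: float
    x: float

    def __post_init__(self) -> None:
        if not (self.k > 0 and self.x > 0):
            raise ValueError(f"k and x must be positive, got k={self.k}, x={self.x}")


@dataclass(frozen=True)
class PoolState:
    """Premature and mature RNA abundance of one pool at one time."""

    p: float
    m: float


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t


def unlabeled_solution(rates: RateTriplet, t) -> PoolState:
    """Pre-existing pool: starts at steady state, no new premature input.

    p_u(t) = (alpha/beta) e^(-beta t)
    m_u(t) = alpha/(gamma-beta) e^(-beta t) - beta*alpha/(gamma(gamma-beta)) e^(-gamma t)

    At t=0 this is the steady state (alpha/beta, alpha/gamma); both
    components decay to zero.  The beta == gamma degeneracy is evaluated by
    the analytic limit m_u = alpha e^(-gamma t) (1/gamma + t).
    """
    t = _check_time(t)
    a, b, g = rates.alpha, rates.beta, rates.gamma
    p = (a / b) * np.exp(-b * t)
    if abs(b - g) <= K_DEGENERATE_TOL * g:
        m = a * np.exp(-g * t) * (1.0 / g + t)
    else:
        m = (a / (g - b)) * np.exp(-b * t) - (b * a / (g * (g - b))) * np.exp(-g * t)
    return PoolState(p=p if p.ndim else float(p), m=m if m.ndim else float(m))


def labeled_solution(rates: RateTriplet, t) -> PoolState:
    """Newly synthesized pool: empty at t=0, approaches steady state.

    p_l(t) = (alpha/beta)(1 - e^(-beta t))
    m_l(t) = (alpha/gamma)(1 + beta/(gamma-beta) e^(-gamma t)) - alpha/(gamma-beta) e^(-beta t)

    The unlabeled and labeled pools sum to the steady state at every t.
    """
    t = _check_time(t)
    a, b, g = rates.alpha, rates.beta, rates.gamma
    p = (a / b) * (-np.expm1(-b * t))
    if abs(b - g) <= K_DEGENERATE_TOL * g:
        m = a / g - a * np.exp(-g * t) * (1.0 / g + t)
    else:
        m = (a / g) * (1.0 + (b / (g - b)) * np.exp(-g * t)) - (a / (g - b)) * np.exp(
            -b * t
        )
    return PoolState(p=p if p.ndim else float(p), m=m if m.ndim else float(m))


def _as_kx(k, x):
    k = np.asarray(k, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(k <= 0) or np.any(x <= 0):
        raise ValueError("k and x must be positive")
    return k, x


def ratio_unlabeled(params) -> float | np.ndarray:
    """Intron-to-exon ratio ``a`` of the unlabeled pool.

    a(k, x) = (1-k) e^(-kx) / (e^(-kx) - k^2 e^(-x)),  k = beta/gamma, x = gamma*T.

    Independent of alpha; lies in (0, 1).  Evaluated in the exponential
    form appropriate to the sign of 1-k so that no intermediate overflows
    even when (k-1)*x exceeds several hundred nats; the removable k=1
    singularity uses the limit a = 1/(2+x).

    Accepts a ``ReducedParams`` or a ``(k, x)`` pair of scalars/arrays.
    """
    if isinstance(params, ReducedParams):
        k, x = params.k, params.x
    else:
        k, x = params
    k, x = _as_kx(k, x)
    scalar = k.ndim == 0 and x.ndim == 0
    k, x = np.atleast_1d(k), np.atleast_1d(x)
    k, x = np.broadcast_arrays(k, x)
    a = np.empty_like(k, dtype=float)

    deg = np.abs(k - 1.0) < K_DEGENERATE_TOL
    lo = (k < 1.0) & ~deg
    hi = (k > 1.0) & ~deg
    # k<1: divide through by e^(-kx); the remaining exponential decays
    with np.errstate(over="ignore"):
        a[lo] = (1.0 - k[lo]) / (1.0 - k[lo] ** 2 * np.exp((k[lo] - 1.0) * x[lo]))
    # k>1: divide through by e^(-x) instead
    e = np.exp((1.0 - k[hi]) * x[hi])
    a[hi] = (k[hi] - 1.0) * e / (k[hi] ** 2 - e)
    a[deg] = 1.0 / (2.0 + x[deg])
    return float(a[0]) if scalar else a.reshape(np.broadcast_shapes(k.shape, x.shape))


def ratio_labeled(params) -> float | np.ndarray:
    """Intron-to-exon ratio ``b`` of the labeled pool.

    b(k, x) = (1-k)(1 - e^(-kx)) / ((1 - e^(-kx)) - k^2 (1 - e^(-x)))

    Same form as the unlabeled ratio with each exponential replaced by its
    complement to one.  Starts at 1 for x -> 0 and decreases to 1/(1+k).
    Uses expm1 throughout; the k=1 limit is
    b = (1-e^(-x)) / (2(1-e^(-x)) - x e^(-x)).
    """
    if isinstance(params, ReducedParams):
        k, x = params.k, params.x
    else:
        k, x = params
    k, x = _as_kx(k, x)
    scalar = k.ndim == 0 and x.ndim == 0
    k, x = np.atleast_1d(k), np.atleast_1d(x)
    k, x = np.broadcast_arrays(k, x)
    b = np.empty_like(k, dtype=float)

    deg = np.abs(k - 1.0) < K_DEGENERATE_TOL
    nd = ~deg
    ekx = -np.expm1(-k[nd] * x[nd])  # 1 - e^(-kx)
    ex = -np.expm1(-x[nd])  # 1 - e^(-x)
    b[nd] = (1.0 - k[nd]) * ekx / (ekx - k[nd] ** 2 * ex)
    exd = -np.expm1(-x[deg])
    b[deg] = exd / (2.0 * exd - x[deg] * np.exp(-x[deg]))
    return float(b[0]) if scalar else b.reshape(np.broadcast_shapes(k.shape, x.shape))


def trajectory(k: float, x_grid) -> np.ndarray:
    """Path of the observable pair (a, b) as the dimensionless time gamma*T grows.

    Returns an (n, 2) array of (a, b) at each point of ``x_grid`` (strictly
    positive, ascending).  The path depends on k only: it starts near
    (1/(1+k), 1) and converges to (1-k, 1/(1+k)) for k<1 or to
    (0, 1/(1+k)) for k>=1, with b decreasing monotonically.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    if x_grid.ndim != 1 or x_grid.size == 0:
        raise ValueError("x_grid must be a non-empty 1-d array")
    if np.any(x_grid <= 0) or np.any(np.diff(x_grid) <= 0):
        raise ValueError("x_grid must be strictly positive and ascending")
    a = ratio_unlabeled((k, x_grid))
    b = ratio_labeled((k, x_grid))
    return np.column_stack([a, b])


def ode_oracle(
    rates: RateTriplet,
    t: float,
    initial: PoolState,
    *,
    synthesis_on: bool = True,
    rtol: float = 1e-12,
    atol: float = 1e-14,
) -> PoolState:
    """Numerically integrate the kinetic ODEs from an arbitrary initial state.

    Exists to verify the closed forms independently: with
    ``synthesis_on=False`` (alpha forced to 0) and the steady state as
    initial condition it must reproduce ``unlabeled_solution``; with
    synthesis on and an empty initial state it must reproduce
    ``labeled_solution``.

    Raises ``RuntimeError`` if the integrator fails — never returns NaN
    silently.
    """
    t = float(t)
    if t < 0:
        raise ValueError("time must be non-negative")
    if t == 0.0:
        return PoolState(p=initial.p, m=initial.m)
    alpha = rates.alpha if synthesis_on else 0.0
    beta, gamma = rates.beta, rates.gamma

    def rhs(_t, y):
        p, m = y
        return [alpha - beta * p, beta * p - gamma * m]

    sol = solve_ivp(
        rhs,
        (0.0, t),
        [initial.p, initial.m],
        method="LSODA",
        rtol=rtol,
        atol=atol,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    p, m = sol.y[:, -1]
    if not (np.isfinite(p) and np.isfinite(m)):
        raise RuntimeError("ODE integration produced non-finite values")
    return PoolState(p=float(p), m=float(m))
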