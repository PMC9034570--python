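"""Invert observed intron/exon ratios to per-transcript kinetic rates.

Given the pair of intron-to-exon abundance ratios ``(r_u, r_l)`` of the
unlabeled and labeled pools of one sample and the pulse duration ``T``, the
processing-to-degradation ratio ``k = beta/gamma`` satisfies a single
transcendental equation

    g(k) = k/(k-1) * log((k + a - 1) / (k^2 a)) - log((b - a) / (a (b k + b - 1)))

on the bounded open domain

    max(1/b - 1, 1 - a)  <  k  <  1/a - 1 .

Above the separating curve ``b = 1/(2-a)`` this equation has exactly one
root; at or below it there may be two roots (two genuinely distinct rate
pairs produce the same observables) or none, in which case the rates are
obtained by minimizing the squared log-distance between observed and
model ratios.  Once k is known,

    gamma = log((b-a)/(a(bk+b-1))) / (k T),    beta = k gamma,

and the synthesis rate follows from the mature unlabeled abundance
(approximated by exon minus intron abundance, the more precisely
quantified pool) through the closed-form solution.

Observed ratios that are incompatible with the model (r_l >= 1, or
r_l <= r_u) are rejected; rejection is data, not an error — rejected
transcripts are returned with a status and NaN rates, because the
rejected fraction is itself a result of interest.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import gaussian_kde

from .model import K_DEGENERATE_TOL, ratio_labeled, ratio_unlabeled

__all__ = [
    "Region",
    "Status",
    "ObservableRatios",
    "AdmissibleDomain",
    "EstimationResult",
    "admissible_domain",
    "classify_region",
    "reduced_equation",
    "solve_k",
    "gamma_from_k",
    "objective_f",
    "objective_reduced",
    "alpha_from_unlabeled",
    "alpha_from_labeled",
    "resolve_ambiguity",
    "estimate_transcript",
    "estimate_all",
]

#: relative shrink applied to the admissible domain before evaluating the
#: reduced equation (its log arguments vanish at the endpoints)
DOMAIN_MARGIN = 1e-9

#: |k-1| below which the removable singularity in the reduced equation is
#: evaluated by its series expansion
K_SERIES_TOL = 1e-4

#: a root of the reduced equation is kept only if the (k, x) pair it implies
#: reproduces the observed ratios this closely in log space.  The reduced
#: equation's residual also vanishes identically at the upper domain
#: endpoint (where the implied x is 0), so floating-point noise there
#: produces spurious sign changes; genuine roots reproduce the observables
#: to near machine precision, spurious ones miss by orders of magnitude.
ROOT_CONSISTENCY_TOL = 1e-8

DEFAULT_GRID_POINTS = 1000


class Region(str, enum.Enum):
    """Partition of the observable plane (see the separating curve b = 1/(2-a))."""

    UNIQUE = "UNIQUE"  # b > 1/(2-a) and b < 1: single root, direct solve
    FALLBACK = "FALLBACK"  # a < b <= 1/(2-a): zero, one or two roots
    REJECT_RL_GE_1 = "REJECT_RL_GE_1"  # labeled ratio >= 1
    REJECT_B_LE_A = "REJECT_B_LE_A"  # labeled ratio <= unlabeled ratio


class Status(str, enum.Enum):
    """Which inference path produced (or rejected) a transcript's estimate."""

    UNIQUE_ROOT = "unique_root"
    AMBIGUOUS_RESOLVED = "ambiguous_resolved"
    FALLBACK_OPTIMIZED = "fallback_optimized"
    REJECTED_RATIO_GE_1 = "rejected_ratio_ge_1"
    REJECTED_B_LE_A = "rejected_b_le_a"
    REJECTED_EMPTY_DOMAIN = "rejected_empty_domain"
    REJECTED_NO_SOLUTION = "rejected_no_solution"

    @property
    def rejected(self) -> bool:
        return self.value.startswith("rejected")


@dataclass(frozen=True)
class ObservableRatios:
    """The observable pair: unlabeled ratio ``a`` = r_u, labeled ratio ``b`` = r_l."""

    a: float
    b: float


@dataclass(frozen=True)
class AdmissibleDomain:
    """Open interval of k values on which the reduced equation is defined."""

    lower: float
    upper: float

    @property
    def empty(self) -> bool:
        return not (self.lower < self.upper)


@dataclass
class EstimationResult:
    """Outcome of rate inference for one transcript.

    For rejected statuses the rate fields are NaN.  ``k_candidates`` holds
    both roots when the observables admit two rate pairs; after resolution
    ``k`` is the retained one and the status is ``ambiguous_resolved``.
    """

    status: Status
    k: float = math.nan
    alpha: float = math.nan
    beta: float = math.nan
    gamma: float = math.nan
    r_u: float = math.nan
    r_l: float = math.nan
    n_roots: int = 0
    objective_value: float = math.nan
    transcript_id: str | None = None
    gene_id: str | None = None
    k_candidates: tuple[float, ...] = field(default_factory=tuple)


def admissible_domain(obs: ObservableRatios) -> AdmissibleDomain:
    """Domain of k on which all logarithms in the reduced equation are defined.

    lower = max(1/b - 1, 1 - a); upper = 1/a - 1.  The upper bound also
    guarantees gamma > 0.  An empty interval is returned as such, never
    silently clamped.
    """
    a, b = obs.a, obs.b
    if not (0 < a and 0 < b <= 1):
        raise ValueError(f"ratios must be in (0, 1], got a={a}, b={b}")
    lower = max(1.0 / b - 1.0, 1.0 - a)
    upper = 1.0 / a - 1.0
    return AdmissibleDomain(lower=lower, upper=upper)


def classify_region(obs: ObservableRatios) -> Region:
    """Place an observable pair in the partition of the (a, b) plane."""
    a, b = obs.a, obs.b
    if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
        raise ValueError(f"ratios must be finite and positive, got a={a}, b={b}")
    if b >= 1.0:
        return Region.REJECT_RL_GE_1
    if b <= a:
        return Region.REJECT_B_LE_A
    if b > 1.0 / (2.0 - a):
        return Region.UNIQUE
    return Region.FALLBACK


def _residual_terms(k, a, b):
    """Vectorized residual of the reduced equation; k must lie inside the domain."""
    k = np.asarray(k, dtype=float)
    out = np.empty_like(k)
    h = k - 1.0
    ser = np.abs(h) < K_SERIES_TOL
    gen = ~ser
    kg = k[gen]
    out[gen] = (kg / (kg - 1.0)) * np.log((kg + a - 1.0) / (kg**2 * a))
    # removable 0/0 at k=1: (k/(k-1)) L(k) with L(1)=0, L'(1)=1/a-2,
    # L''(1)=2-1/a^2; second-order series keeps continuity through the grid
    hs = h[ser]
    inva = np.divide(1.0, a)  # np scalar: overflows to inf instead of raising
    lp = inva - 2.0
    lpp = 2.0 - inva * inva
    out[ser] = (1.0 + hs) * (lp + 0.5 * hs * lpp)
    out -= np.log((b - a) / (a * (b * k + b - 1.0)))
    return out


def reduced_equation(k, obs: ObservableRatios):
    """Residual g(k) whose roots inside the admissible domain give beta/gamma.

    Continuous across the removable singularity at k=1 (series expansion
    for |k-1| < 1e-4).  Raises for k outside the open domain, where the
    log arguments are non-positive.
    """
    dom = admissible_domain(obs)
    karr = np.asarray(k, dtype=float)
    if np.any(karr <= dom.lower) or np.any(karr >= dom.upper):
        raise ValueError(
            f"k must lie strictly inside the admissible domain "
            f"({dom.lower}, {dom.upper})"
        )
    out = _residual_terms(karr, obs.a, obs.b)
    return float(out) if np.ndim(k) == 0 else out


def _shrunk_bounds(dom: AdmissibleDomain) -> tuple[float, float]:
    lo = dom.lower * (1.0 + DOMAIN_MARGIN)
    hi = dom.upper * (1.0 - DOMAIN_MARGIN)
    return lo, hi


def solve_k(
    obs: ObservableRatios, *, grid_points: int = DEFAULT_GRID_POINTS
) -> list[float]:
    """All roots of the reduced equation in the admissible domain.

    Dense log-spaced sign scan (default 1000 points, domain shrunk by a
    relative 1e-9 at the endpoints) followed by bracketed Brent refinement
    to 1e-10 relative tolerance.  The equation has at most two roots; above
    the b = 1/(2-a) curve exactly one.  An empty list means the caller
    should fall back to objective minimization.
    """
    dom = admissible_domain(obs)
    if dom.empty:
        return []
    lo, hi = _shrunk_bounds(dom)
    if not (lo < hi):
        return []
    grid = np.exp(np.linspace(math.log(lo), math.log(hi), grid_points))
    res = _residual_terms(grid, obs.a, obs.b)
    finite = np.isfinite(res)
    roots: list[float] = []
    a, b = obs.a, obs.b

    def g(k: float) -> float:
        return float(_residual_terms(np.asarray([k]), a, b)[0])

    sign = np.sign(res)
    for i in np.nonzero((sign[:-1] * sign[1:] < 0) & finite[:-1] & finite[1:])[0]:
        roots.append(float(brentq(g, grid[i], grid[i + 1], rtol=1e-10, xtol=1e-300)))
    for i in np.nonzero((res == 0.0) & finite)[0]:
        roots.append(float(grid[i]))
    roots = sorted(r for r in roots if _root_is_consistent(r, a, b))
    # collapse duplicates from a root landing exactly on a grid point
    dedup: list[float] = []
    for r in roots:
        if not dedup or abs(r - dedup[-1]) > 1e-9 * max(1.0, abs(r)):
            dedup.append(r)
    return dedup


def _root_is_consistent(k: float, a: float, b: float) -> bool:
    """True when (k, x implied by k) reproduces the observed (a, b).

    A genuine root of the reduced equation solves both observable
    equations exactly, so the forward maps at (k, x = log(Q)/k) must return
    the observed pair to near machine precision.  Spurious roots — sign
    changes manufactured by rounding noise where the residual degenerates
    near the upper domain endpoint — fail this by orders of magnitude.
    """
    q = (b - a) / (a * (b * k + b - 1.0))
    if not (q > 1.0):
        return False
    x = math.log(q) / k
    am = ratio_unlabeled((k, x))
    bm = ratio_labeled((k, x))
    if not (am > 0 and bm > 0):
        return False
    return (
        abs(math.log(am) - math.log(a)) + abs(math.log(bm) - math.log(b))
        < ROOT_CONSISTENCY_TOL
    )


def gamma_from_k(k: float, obs: ObservableRatios, T: float) -> float:
    """Degradation rate from k and the observables: gamma = log(Q)/(k T).

    Q = (b-a)/(a(bk+b-1)) exceeds 1 everywhere on the admissible domain,
    so gamma is positive; beta follows as k*gamma.
    """
    if T <= 0:
        raise ValueError("labeling time T must be positive")
    a, b = obs.a, obs.b
    q = (b - a) / (a * (b * k + b - 1.0))
    if q <= 0:
        raise ValueError("k outside the admissible domain")
    return math.log(q) / (k * T)


def objective_f(k: float, x: float, r_u: float, r_l: float) -> float:
    """Squared log-distance between observed and model ratios at (k, x=gamma*T)."""
    if k <= 0 or x <= 0:
        raise ValueError("k and x must be positive")
    am = ratio_unlabeled((k, x))
    bm = ratio_labeled((k, x))
    return (math.log(r_u) - math.log(am)) ** 2 + (math.log(r_l) - math.log(bm)) ** 2


def _x_of_k(k: float, r_u: float, r_l: float) -> float:
    """gamma*T implied by k and the observed ratios (the Q relation)."""
    return math.log((r_l - r_u) / (r_u * (r_l * k + r_l - 1.0))) / k


def objective_reduced(k: float, r_u: float, r_l: float) -> float:
    """Univariate objective: the bivariate log-distance with x eliminated via Q."""
    return objective_f(k, _x_of_k(k, r_u, r_l), r_u, r_l)


def _minimize_reduced(
    obs: ObservableRatios, *, n_starts: int = 10
) -> tuple[float, float] | None:
    """Global minimum of the reduced objective over the admissible domain.

    Bounded scalar minimization (1e-10 tolerance) restarted on the
    subintervals between ``n_starts`` log-spaced probe points, so that both
    local minima possible below the separating curve are found.
    """
    dom = admissible_domain(obs)
    if dom.empty:
        return None
    lo, hi = _shrunk_bounds(dom)
    if not (lo < hi):
        return None
    r_u, r_l = obs.a, obs.b
    probes = np.exp(np.linspace(math.log(lo), math.log(hi), n_starts))
    best_k, best_f = None, math.inf
    for kp in probes:
        f = objective_reduced(float(kp), r_u, r_l)
        if f < best_f:
            best_k, best_f = float(kp), f
    for left, right in zip(probes[:-1], probes[1:]):
        res = minimize_scalar(
            objective_reduced,
            args=(r_u, r_l),
            bounds=(float(left), float(right)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if res.fun < best_f:
            best_k, best_f = float(res.x), float(res.fun)
    if best_k is None:
        return None
    return best_k, best_f


def alpha_from_unlabeled(
    k: float, gamma: float, T: float, chi_u: float, iota_u: float
) -> float:
    """Synthesis rate from the unlabeled pool's mature abundance.

    The mature unlabeled abundance m_u(T) is approximated by chi_u - iota_u
    and the closed form is inverted:

        alpha = gamma (gamma - beta) (chi_u - iota_u) / (gamma E_beta - beta E_gamma)

    with E_beta = e^(-beta T), E_gamma = e^(-gamma T).  The beta == gamma
    degeneracy uses the limit alpha = gamma e^(gamma T) m_u / (1 + gamma T).
    """
    if chi_u <= iota_u:
        raise ValueError("chi_u must exceed iota_u (unlabeled ratio below 1)")
    if gamma <= 0 or T <= 0 or k <= 0:
        raise ValueError("k, gamma and T must be positive")
    m_u = chi_u - iota_u
    beta = k * gamma
    if abs(k - 1.0) < K_DEGENERATE_TOL:
        return gamma * math.exp(gamma * T) * m_u / (1.0 + gamma * T)
    denom = gamma * math.exp(-beta * T) - beta * math.exp(-gamma * T)
    return gamma * (gamma - beta) * m_u / denom


def alpha_from_labeled(
    k: float, gamma: float, T: float, chi_l: float, iota_l: float
) -> float:
    """Synthesis rate from the labeled pool's mature abundance (m_l = chi_l - iota_l).

    Inverts the labeled closed form:

        alpha = gamma (gamma - beta) m_l / (gamma - beta + beta E_gamma - gamma E_beta)

    As T grows m_l approaches alpha/gamma, so alpha -> gamma (chi_l - iota_l).
    """
    if chi_l <= iota_l:
        raise ValueError("chi_l must exceed iota_l (labeled ratio below 1)")
    if gamma <= 0 or T <= 0 or k <= 0:
        raise ValueError("k, gamma and T must be positive")
    m_l = chi_l - iota_l
    beta = k * gamma
    if abs(k - 1.0) < K_DEGENERATE_TOL:
        return gamma * m_l / (-math.expm1(-gamma * T) - gamma * T * math.exp(-gamma * T))
    denom = (
        gamma - beta + beta * math.exp(-gamma * T) - gamma * math.exp(-beta * T)
    )
    return gamma * (gamma - beta) * m_l / denom


#: fewer unambiguous transcripts than this and the density estimate is not
#: trusted; resolution falls back to distance from the population median
MIN_KDE_POPULATION = 10

#: population subsample size used to fit the resolution density (the KDE
#: cost is linear in it; a few thousand points pin the density well)
KDE_MAX_POINTS = 4000


def _population_log_rates(population) -> np.ndarray:
    """(log beta, log gamma) of the population's uniquely determined transcripts."""
    pts = [
        (math.log(r.beta), math.log(r.gamma))
        for r in population
        if r.status is Status.UNIQUE_ROOT
        and np.isfinite(r.beta)
        and np.isfinite(r.gamma)
    ]
    return np.asarray(pts, dtype=float)


def _fit_resolution_kde(pop_pts: np.ndarray) -> gaussian_kde | None:
    if len(pop_pts) < MIN_KDE_POPULATION:
        return None
    if len(pop_pts) > KDE_MAX_POINTS:
        # deterministic thinning; order carries no information
        step = len(pop_pts) // KDE_MAX_POINTS + 1
        pop_pts = pop_pts[::step]
    try:
        return gaussian_kde(pop_pts.T)
    except np.linalg.LinAlgError:  # degenerate population
        return None


def resolve_ambiguity(
    candidate_results: list[EstimationResult],
    population: list[EstimationResult],
) -> EstimationResult:
    """Pick one of two rate sets consistent with the same observables.

    Concretizes "the rates most consistent with the other transcripts":
    the retained candidate is the one whose (log beta, log gamma) falls in
    the denser part of the population's distribution, estimated by a
    Gaussian KDE over the uniquely determined transcripts.  Small
    populations fall back to the nearest candidate to the population
    median in the same plane; with no population at all, the candidate
    with the smaller objective value is kept (ties: the first).
    """
    if len(candidate_results) != 2:
        raise ValueError("exactly two candidates required")
    pop_pts = _population_log_rates(population)
    cand_pts = np.array(
        [(math.log(r.beta), math.log(r.gamma)) for r in candidate_results]
    )
    kde = _fit_resolution_kde(pop_pts)
    if kde is not None:
        dens = kde(cand_pts.T)
        chosen = candidate_results[int(np.argmax(dens))]
    elif len(pop_pts):
        ref = np.median(pop_pts, axis=0)
        d = np.linalg.norm(cand_pts - ref, axis=1)
        chosen = candidate_results[int(np.argmin(d))]
    else:
        chosen = min(
            candidate_results,
            key=lambda r: (r.objective_value if np.isfinite(r.objective_value) else 0.0),
        )
    chosen.status = Status.AMBIGUOUS_RESOLVED
    return chosen


def _result_from_k(
    k: float,
    obs: ObservableRatios,
    T: float,
    record,
    status: Status,
    n_roots: int,
    alpha_source: str,
    objective_value: float = math.nan,
) -> EstimationResult:
    gamma = gamma_from_k(k, obs, T)
    beta = k * gamma
    if alpha_source == "labeled":
        alpha = alpha_from_labeled(k, gamma, T, record.chi_l, record.iota_l)
    else:
        alpha = alpha_from_unlabeled(k, gamma, T, record.chi_u, record.iota_u)
    return EstimationResult(
        status=status,
        k=k,
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        r_u=obs.a,
        r_l=obs.b,
        n_roots=n_roots,
        objective_value=objective_value,
        transcript_id=getattr(record, "transcript_id", None),
        gene_id=getattr(record, "gene_id", None),
    )


def _rejection(record, status: Status, r_u=math.nan, r_l=math.nan) -> EstimationResult:
    return EstimationResult(
        status=status,
        r_u=r_u,
        r_l=r_l,
        transcript_id=getattr(record, "transcript_id", None),
        gene_id=getattr(record, "gene_id", None),
    )


def estimate_transcript(
    record,
    T: float,
    *,
    alpha_source: str = "unlabeled",
    grid_points: int = DEFAULT_GRID_POINTS,
) -> EstimationResult:
    """Full single-transcript inference: classify, solve or optimize, reconstruct.

    Never raises on incompatible data — the result carries a rejection
    status instead.  When the observables admit two rate sets, the result
    keeps both candidates in ``k_candidates`` (rates filled from the first)
    so that a later population pass can resolve them; use
    :func:`estimate_all` for that.
    """
    if T <= 0:
        raise ValueError("labeling time T must be positive")
    if alpha_source not in ("unlabeled", "labeled"):
        raise ValueError("alpha_source must be 'unlabeled' or 'labeled'")
    chi_u, iota_u = record.chi_u, record.iota_u
    chi_l, iota_l = record.chi_l, record.iota_l
    if chi_u <= 0 or chi_l <= 0 or iota_u < 0 or iota_l < 0:
        return _rejection(record, Status.REJECTED_EMPTY_DOMAIN)
    r_u = iota_u / chi_u
    r_l = iota_l / chi_l
    if r_l >= 1.0:
        return _rejection(record, Status.REJECTED_RATIO_GE_1, r_u, r_l)
    if r_l <= r_u:
        return _rejection(record, Status.REJECTED_B_LE_A, r_u, r_l)
    if r_u <= 0.0 or r_u >= 1.0:
        return _rejection(record, Status.REJECTED_EMPTY_DOMAIN, r_u, r_l)
    obs = ObservableRatios(a=r_u, b=r_l)
    dom = admissible_domain(obs)
    if dom.empty:
        return _rejection(record, Status.REJECTED_EMPTY_DOMAIN, r_u, r_l)

    roots = solve_k(obs, grid_points=grid_points)
    if len(roots) == 1:
        return _result_from_k(
            roots[0], obs, T, record, Status.UNIQUE_ROOT, 1, alpha_source
        )
    if len(roots) >= 2:
        # keep the two extreme roots should numerics ever report more
        ks = (roots[0], roots[-1])
        res = _result_from_k(
            ks[0], obs, T, record, Status.AMBIGUOUS_RESOLVED, len(roots), alpha_source
        )
        res.k_candidates = ks
        return res
    # no root: minimize the log-distance objective over the domain
    opt = _minimize_reduced(obs)
    if opt is None:
        return _rejection(record, Status.REJECTED_NO_SOLUTION, r_u, r_l)
    k_opt, f_opt = opt
    # an optimum pinned to the evaluation margin means no admissible
    # interior rate pair fits; the implied gamma there reflects the margin,
    # not the data, so the transcript is reported unsolvable
    lo, hi = _shrunk_bounds(dom)
    if (k_opt - lo) < 1e-6 * (hi - lo) or (hi - k_opt) < 1e-6 * (hi - lo):
        return _rejection(record, Status.REJECTED_NO_SOLUTION, r_u, r_l)
    return _result_from_k(
        k_opt,
        obs,
        T,
        record,
        Status.FALLBACK_OPTIMIZED,
        0,
        alpha_source,
        objective_value=f_opt,
    )


def estimate_all(
    records,
    T: float,
    *,
    alpha_source: str = "unlabeled",
    grid_points: int = DEFAULT_GRID_POINTS,
) -> list[EstimationResult]:
    """Estimate every transcript, then resolve two-solution ambiguities.

    A first pass estimates each transcript independently (embarrassingly
    parallel by construction); a second pass resolves each ambiguous case
    against the median log k of the run's own uniquely determined
    transcripts, so results do not depend on processing order.
    """
    results = [
        estimate_transcript(
            rec, T, alpha_source=alpha_source, grid_points=grid_points
        )
        for rec in records
    ]
    uniques = [r for r in results if r.status is Status.UNIQUE_ROOT]
    kde = _fit_resolution_kde(_population_log_rates(uniques))

    pending: list[tuple[int, list[EstimationResult]]] = []
    for i, (res, rec) in enumerate(zip(results, records)):
        if len(res.k_candidates) == 2:
            obs = ObservableRatios(a=res.r_u, b=res.r_l)
            cands = [
                _result_from_k(
                    kc, obs, T, rec, Status.AMBIGUOUS_RESOLVED, res.n_roots,
                    alpha_source,
                )
                for kc in res.k_candidates
            ]
            for c, kc in zip(cands, res.k_candidates):
                c.k_candidates = res.k_candidates
                c.objective_value = objective_reduced(kc, res.r_u, res.r_l)
            pending.append((i, cands))
    if not pending:
        return results
    if kde is not None:
        # one batched density evaluation for all candidates of all transcripts
        pts = np.array(
            [
                (math.log(c.beta), math.log(c.gamma))
                for _, cands in pending
                for c in cands
            ]
        )
        dens = kde(pts.T).reshape(-1, 2)
        for (i, cands), d in zip(pending, dens):
            chosen = cands[int(np.argmax(d))]
            chosen.status = Status.AMBIGUOUS_RESOLVED
            results[i] = chosen
    else:
        for i, cands in pending:
            results[i] = resolve_ambiguity(cands, uniques)
    return results
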