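"""Maximal AUC over all risk distributions with given prevalence and PVE.

The average risk ``k`` fixes the first moment of the risk distribution and
the PVE fixes its second moment (``E[risk^2] = k(1-k) PVE + k^2``).  Over
all histograms on the ``i/b`` grid satisfying these two moment constraints,
the AUC of the ideal risk-ranking predictor is maximized.  After eliminating
``p_0 = 1 - sum(p_1..p_b)`` the AUC numerator becomes the quadratic form
``p^T Q p + b^2 k`` with ``Q[i, j] = -j(b + i)/2`` for ``i >= j`` (1-based).
``Q`` is negative definite for every bin count we use, so the maximization
is a concave quadratic program with a guaranteed global optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, minimize

from .risk_model import (
    DiseaseParams,
    RiskDistribution,
    auc_oracle,
    mean_risk,
    pve_of_distribution,
)

__all__ = [
    "AUCBoundResult",
    "FeasibilityReport",
    "build_q_matrix",
    "is_negative_definite",
    "second_moment",
    "check_feasibility",
    "feasible_start",
    "max_auc",
]

#: Required accuracy on the moment constraints at the solution.
CONSTRAINT_TOL = 1e-8


@lru_cache(maxsize=32)
def _q_matrix_cached(b: int) -> np.ndarray:
    i = np.arange(1, b + 1)
    lo = np.minimum.outer(i, i)
    hi = np.maximum.outer(i, i)
    q = -lo * (b + hi) / 2.0
    q.setflags(write=False)
    return q


def build_q_matrix(b: int) -> np.ndarray:
    """The symmetric b x b matrix of the AUC quadratic form.

    Rows/columns index bins ``1..b`` (bin 0 is eliminated via
    ``p_0 = 1 - sum p_i``); the entry at (i, j) with ``i >= j`` is
    ``-j(b + i)/2``, mirrored above the diagonal.  For a distribution with
    mean ``k``, ``(p^T Q p + b^2 k) / (b^2 k (1-k))`` equals the AUC.
    """
    if b < 2:
        raise ValueError(f"b must be >= 2, got {b}")
    return _q_matrix_cached(int(b))


@lru_cache(maxsize=32)
def is_negative_definite(b: int) -> bool:
    """Whether Q(b) is negative definite (checked once per b, by Cholesky)."""
    try:
        np.linalg.cholesky(-build_q_matrix(b))
        return True
    except np.linalg.LinAlgError:
        return False


def second_moment(params: DiseaseParams) -> float:
    """Second moment of risk implied by (k, PVE): ``k(1-k) PVE + k^2``."""
    k = params.k
    return k * (1.0 - k) * params.pve + k * k


@dataclass(frozen=True)
class FeasibilityReport:
    """Whether (k, PVE) is attainable by a histogram on the ``i/b`` grid."""

    feasible: bool
    m2: float
    m2_min: float
    m2_max: float
    pve_min: float
    message: str


def check_feasibility(params: DiseaseParams, b: int) -> FeasibilityReport:
    """Grid feasibility of the two moment constraints.

    For mean ``k``, the smallest second moment attainable on the grid puts
    all mass on the two bins adjacent to ``k b`` (equal to ``k^2`` only when
    ``k b`` is an integer); the largest, ``k``, puts mass on bins 0 and b.
    The pair (k, PVE) is feasible iff its implied second moment lies between
    these extremes.
    """
    k = params.k
    m2 = second_moment(params)
    kb = k * b
    lo = np.floor(kb)
    w_hi = kb - lo  # mass on bin lo+1 in the minimum-variance distribution
    m2_min = ((1.0 - w_hi) * lo**2 + w_hi * (lo + 1.0) ** 2) / b**2
    m2_max = k
    pve_min = (m2_min - k * k) / (k * (1.0 - k))
    tol = 1e-12
    if m2 < m2_min - tol:
        msg = (
            f"PVE={params.pve:g} below the grid minimum {pve_min:.6g} for "
            f"k={k:g}, b={b} (k*b is not an integer, so zero variance is "
            "unattainable on the grid)"
        )
        return FeasibilityReport(False, m2, m2_min, m2_max, pve_min, msg)
    if m2 > m2_max + tol:
        return FeasibilityReport(
            False, m2, m2_min, m2_max, pve_min, "second moment exceeds k"
        )
    return FeasibilityReport(True, m2, m2_min, m2_max, pve_min, "feasible")


def _min_variance_distribution(k: float, b: int) -> np.ndarray:
    """Mass on the two bins adjacent to k*b; the grid minimum of variance."""
    p = np.zeros(b + 1)
    kb = k * b
    lo = int(np.floor(kb))
    w_hi = kb - lo
    p[lo] = 1.0 - w_hi
    if w_hi > 0:
        p[lo + 1] = w_hi
    return p


def feasible_start(params: DiseaseParams, b: int) -> np.ndarray:
    """A distribution satisfying both moment constraints exactly.

    Mixes the minimum-variance (adjacent-bin) distribution with the
    maximum-variance one (mass on risks 0 and 1) in the unique ratio that
    hits the target second moment.  Raises if (k, PVE) is grid-infeasible.
    """
    rep = check_feasibility(params, b)
    if not rep.feasible:
        raise ValueError(rep.message)
    k = params.k
    p_lo = _min_variance_distribution(k, b)
    p_hi = np.zeros(b + 1)
    p_hi[0], p_hi[b] = 1.0 - k, k
    denom = rep.m2_max - rep.m2_min
    lam = 0.0 if denom <= 0 else np.clip((rep.m2 - rep.m2_min) / denom, 0.0, 1.0)
    return (1.0 - lam) * p_lo + lam * p_hi


def _full_m_matrix(b: int) -> np.ndarray:
    """Full (b+1)x(b+1) form of the AUC numerator: N(p) = p^T M p / 2.

    ``M[i, j] = (b - min(i, j)) * max(i, j)``; equivalent to the reduced
    ``p^T Q p + b^2 k`` form after eliminating ``p_0``, but keeps all bins
    as variables, which is what the active-set solver works with.
    """
    i = np.arange(b + 1)
    mn = np.minimum.outer(i, i)
    mx = np.maximum.outer(i, i)
    return ((b - mn) * mx).astype(float)


def _interval_qp(
    b: int, k: float, m2: float, lo: int, hi: int, max_iter: int | None = None
) -> np.ndarray | None:
    """Exact solution of the max-AUC program via interval active sets.

    Maximizes ``p^T M p / 2`` subject to the three equalities (total mass,
    mean, second moment) and ``p >= 0``.  The maximizer's support is a
    contiguous run of bins, so the working set is an interval ``[lo, hi]``:
    solve the equality-constrained KKT system on it, shrink ends whose
    probabilities go negative, extend ends whose zero bins have positive
    Lagrangian gradient (i.e. would improve the objective).  The final
    iterate satisfies the full KKT conditions, which certifies the global
    optimum of the concave program.  Returns None if the support is not an
    interval (never observed) or the iteration cap is hit.
    """
    M = _full_m_matrix(b)
    i = np.arange(b + 1, dtype=float)
    A = np.vstack([np.ones(b + 1), i, i * i])
    c = np.array([1.0, b * k, b * b * m2])
    if max_iter is None:
        max_iter = 2 * b + 50
    g_tol = 1e-9 * b * b  # gradient entries scale like b^2
    for _ in range(max_iter):
        S = np.arange(lo, hi + 1)
        ns = len(S)
        kkt = np.zeros((ns + 3, ns + 3))
        kkt[:ns, :ns] = M[np.ix_(S, S)]
        kkt[:ns, ns:] = A[:, S].T
        kkt[ns:, :ns] = A[:, S]
        rhs = np.zeros(ns + 3)
        rhs[ns:] = c
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            return None
        p_s, lam = sol[:ns], sol[ns:]
        neg = p_s < -1e-12
        if neg.any():
            # negative mass must sit at the ends of the interval
            if neg.all():
                return None
            head = int(np.argmax(~neg)) if neg[0] else 0
            tail = int(np.argmax(~neg[::-1])) if neg[-1] else 0
            if neg.sum() != head + tail or ns - head - tail < 3:
                return None
            lo, hi = lo + head, hi - tail
            continue
        p = np.zeros(b + 1)
        p[S] = np.clip(p_s, 0.0, None)
        # stationarity on the support reads M p + A^T lam = 0; a zero bin
        # can only improve the objective if this gradient is positive there
        grad = M @ p + A.T @ lam
        viol = np.nonzero(grad > g_tol)[0]
        viol = viol[(viol < lo) | (viol > hi)]
        if viol.size == 0:
            return p
        new_lo = min(lo, int(viol.min()))
        new_hi = max(hi, int(viol.max()))
        if (new_lo, new_hi) == (lo, hi):  # pragma: no cover - safety
            return None
        lo, hi = new_lo, new_hi
    return None


@dataclass(frozen=True)
class AUCBoundResult:
    """Outcome of the max-AUC program for one (k, PVE, b)."""

    max_auc: float
    optimizer: RiskDistribution | None
    k: float
    pve: float
    bins: int
    solver_status: str  # optimal | infeasible | numerical_failure
    message: str = ""

    def __repr__(self) -> str:  # compact: the distribution is b+1 numbers
        return (
            f"AUCBoundResult(max_auc={self.max_auc:.6f}, k={self.k}, "
            f"pve={self.pve}, bins={self.bins}, status={self.solver_status!r})"
        )


def quadratic_form_auc(q: np.ndarray, b: int, k: float) -> float:
    """AUC from the reduced vector ``q = (p_1..p_b)`` via the Q matrix."""
    Q = build_q_matrix(b)
    return float((q @ Q @ q + b * b * k) / (b * b * k * (1.0 - k)))


def max_auc(
    params: DiseaseParams,
    b: int = 100,
    relax_pve: bool = False,
    tol: float = 1e-9,
) -> AUCBoundResult:
    """Globally maximal AUC for the given average risk and PVE.

    Solves the concave quadratic program: maximize
    ``(p^T Q p + b^2 k) / (b^2 k(1-k))`` over ``p = (p_1..p_b)`` with
    ``0 <= p_i <= 1``, ``sum p_i <= 1`` and the two moment equalities.
    Negative definiteness of Q is verified (once per ``b``), so the optimum
    is global.

    With ``relax_pve=True`` the second-moment constraint is imposed as
    ">= target" instead of equality, answering "PVE at least this large";
    the bound can only increase.
    """
    k, pve = params.k, params.pve
    rep = check_feasibility(params, b)
    if not rep.feasible:
        return AUCBoundResult(np.nan, None, k, pve, b, "infeasible", rep.message)
    if not is_negative_definite(b):
        return AUCBoundResult(
            np.nan, None, k, pve, b, "numerical_failure",
            f"Q is not negative definite for b={b}",
        )

    span = rep.m2_max - rep.m2_min
    if rep.m2 >= rep.m2_max - 1e-14:
        # maximal variance: support {0, 1} is the unique feasible
        # distribution, and it separates cases from controls perfectly
        p = np.zeros(b + 1)
        p[0], p[b] = 1.0 - k, k
        d = RiskDistribution(bins=b, probs=p)
        return AUCBoundResult(auc_oracle(d), d, k, pve, b, "optimal")
    if span <= 1e-14 or (rep.m2 <= rep.m2_min + 1e-14 and not relax_pve):
        # minimal grid variance: the adjacent-bin distribution is unique
        d = RiskDistribution(bins=b, probs=_min_variance_distribution(k, b))
        return AUCBoundResult(auc_oracle(d), d, k, pve, b, "optimal")

    p = None
    if not relax_pve:
        p = _interval_active_set(b, k, rep.m2)
    if p is None:
        p = _trust_constr_qp(params, b, rep.m2, relax_pve, tol)
        if p is None:
            return AUCBoundResult(
                np.nan, None, k, pve, b, "numerical_failure",
                "both the active-set and trust-region solvers failed",
            )
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    d = RiskDistribution(bins=b, probs=p)
    auc = auc_oracle(d)
    mean_err = abs(mean_risk(d) - k)
    pve_err = pve_of_distribution(d) - pve
    ok = mean_err < CONSTRAINT_TOL and (
        pve_err > -CONSTRAINT_TOL if relax_pve else abs(pve_err) < CONSTRAINT_TOL
    )
    if not ok:
        return AUCBoundResult(
            auc, d, k, pve, b, "numerical_failure",
            f"moment constraints not met: mean error {mean_err:.3g}, "
            f"pve error {pve_err:.3g}",
        )
    return AUCBoundResult(auc, d, k, pve, b, "optimal")


_COARSE_B = 128  # bin count at which the support interval is first located


def _interval_active_set(b: int, k: float, m2: float) -> np.ndarray | None:
    """Interval active-set solve, warm-started from a coarse grid.

    For large ``b`` the support interval is located on a ~100-bin grid first
    (the support endpoints, as risk fractions, are stable across bin
    counts), then refined at full resolution; this keeps the number of
    dense KKT solves at size ``b`` to a handful.
    """
    if b <= _COARSE_B:
        return _interval_qp(b, k, m2, 0, b)
    coarse = _interval_qp(_COARSE_B, k, m2, 0, _COARSE_B)
    if coarse is None:
        return _interval_qp(b, k, m2, 0, b)
    nz = np.nonzero(coarse > 1e-12)[0]
    margin = max(2, b // 50)
    lo = max(0, int(np.floor(nz[0] / _COARSE_B * b)) - margin)
    hi = min(b, int(np.ceil(nz[-1] / _COARSE_B * b)) + margin)
    p = _interval_qp(b, k, m2, lo, hi)
    if p is None:
        p = _interval_qp(b, k, m2, 0, b)
    return p


def _trust_constr_qp(
    params: DiseaseParams, b: int, m2: float, relax_pve: bool, tol: float
) -> np.ndarray | None:
    """Fallback/general solver on the reduced (p_0-eliminated) program."""
    k = params.k
    Q = build_q_matrix(b)
    i = np.arange(1, b + 1, dtype=float)
    constraints = [
        LinearConstraint(i / b, k, k),
        LinearConstraint((i / b) ** 2, m2, np.inf if relax_pve else m2),
        LinearConstraint(np.ones(b), -np.inf, 1.0),
    ]
    x0 = feasible_start(params, b)[1:]
    res = minimize(
        lambda q: -(q @ Q @ q),
        x0,
        method="trust-constr",
        jac=lambda q: -2.0 * (Q @ q),
        hess=lambda q: -2.0 * Q,
        bounds=Bounds(0.0, 1.0),
        constraints=constraints,
        options={"gtol": tol, "xtol": 1e-12, "maxiter": 1000},
    )
    if res.status not in (1, 2):
        return None
    q = np.clip(res.x, 0.0, None)
    p0 = 1.0 - q.sum()
    if p0 < -CONSTRAINT_TOL:
        return None
    return np.concatenate([[max(p0, 0.0)], q])
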