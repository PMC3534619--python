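"""Maximal ROC curve: best sensitivity/specificity pairs via linear programs.

For a fixed decision threshold ``t/b`` ("declare positive iff risk >= t/b")
both sensitivity and specificity are linear in the bin probabilities, so the
largest sensitivity compatible with a specificity target — over all risk
distributions matching the prevalence/PVE moment constraints — is a linear
program.  Maximizing over all thresholds gives one point of the maximal ROC
curve.  Each point of that curve may be achieved by a *different* risk
distribution, so the curve is an envelope: no single trait need realize all
of its points, and its area can exceed the (single-distribution) AUC bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .auc_bound import check_feasibility, second_moment
from .risk_model import DiseaseParams, RiskDistribution

__all__ = [
    "ROCBoundPoint",
    "max_sens_at_threshold",
    "max_roc_point",
    "max_spec_at_sensitivity",
    "max_roc_curve",
]

_TIE_TOL = 1e-9


@dataclass(frozen=True)
class ROCBoundPoint:
    """One point of the maximal ROC curve.

    ``target`` is the constrained coordinate (specificity for the
    sensitivity-maximizing direction, sensitivity for the reverse),
    ``value`` the optimized one; ``threshold`` is the smallest threshold bin
    achieving it and ``optimizer`` the achieving distribution.
    """

    target: float
    value: float
    threshold: int | None
    optimizer: RiskDistribution | None
    solver_status: str  # optimal | infeasible
    direction: str = "sensitivity"  # quantity being maximized


def _moment_rows(b: int, k: float, m2: float):
    i = np.arange(b + 1, dtype=float)
    a_eq = np.vstack([np.ones(b + 1), i / b, (i / b) ** 2])
    b_eq = np.array([1.0, k, m2])
    return i, a_eq, b_eq


def _solve_lp(c, a_eq, b_eq, a_ub, b_ub, b):
    res = linprog(
        c,
        A_ub=a_ub,
        b_ub=b_ub,
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=(0.0, 1.0),
        method="highs",
    )
    if res.status != 0:
        return None, None
    p = np.clip(res.x, 0.0, 1.0)
    p /= p.sum()
    return -res.fun, RiskDistribution(bins=b, probs=p)


def max_sens_at_threshold(
    params: DiseaseParams, spec_target: float, t: int, b: int = 1000
) -> tuple[float, RiskDistribution | None, str]:
    """Largest sensitivity at threshold ``t`` with specificity >= target.

    Maximizes ``Se = (1/(b k)) sum_{i>=t} i p_i`` over distributions ``p``
    subject to the specificity constraint, the two moment equalities and the
    simplex bounds.  Returns ``(sensitivity, optimizer, status)``.
    """
    if not 0 <= t <= b + 1:
        raise ValueError(f"threshold bin t must be in 0..{b + 1}, got {t}")
    if not 0.0 <= spec_target <= 1.0:
        raise ValueError("spec_target must be in [0, 1]")
    k = params.k
    i, a_eq, b_eq = _moment_rows(b, k, second_moment(params))
    c = np.where(i >= t, -i / (b * k), 0.0)
    a_ub = np.where(i < t, -(b - i), 0.0)[None, :]
    b_ub = np.array([-b * (1.0 - k) * spec_target])
    val, dist = _solve_lp(c, a_eq, b_eq, a_ub, b_ub, b)
    if val is None:
        return np.nan, None, "infeasible"
    return float(val), dist, "optimal"


def _sweep(params, target, b, direction):
    """Maximize Se (or Sp) over all thresholds; smallest t wins ties."""
    k = params.k
    rep = check_feasibility(params, b)
    if not rep.feasible:
        return ROCBoundPoint(target, np.nan, None, None, "infeasible", direction)
    i, a_eq, b_eq = _moment_rows(b, k, rep.m2)
    best = ROCBoundPoint(target, np.nan, None, None, "infeasible", direction)
    for t in range(b + 2):
        if direction == "sensitivity":
            c = np.where(i >= t, -i / (b * k), 0.0)
            a_ub = np.where(i < t, -(b - i), 0.0)[None, :]
            b_ub = np.array([-b * (1.0 - k) * target])
        else:
            c = np.where(i < t, -(b - i) / (b * (1.0 - k)), 0.0)
            a_ub = np.where(i >= t, -i, 0.0)[None, :]
            b_ub = np.array([-b * k * target])
        val, dist = _solve_lp(c, a_eq, b_eq, a_ub, b_ub, b)
        if val is None:
            continue
        if best.solver_status != "optimal" or val > best.value + _TIE_TOL:
            best = ROCBoundPoint(target, float(val), t, dist, "optimal", direction)
        if best.solver_status == "optimal" and best.value >= 1.0 - _TIE_TOL:
            break  # cannot improve on a perfect score; smallest t already kept
    return best


def max_roc_point(
    params: DiseaseParams, spec_target: float, b: int = 1000
) -> ROCBoundPoint:
    """Maximal sensitivity at a specificity target, over all thresholds."""
    if not 0.0 <= spec_target <= 1.0:
        raise ValueError("spec_target must be in [0, 1]")
    return _sweep(params, spec_target, b, "sensitivity")


def max_spec_at_sensitivity(
    params: DiseaseParams, sens_target: float, b: int = 1000
) -> ROCBoundPoint:
    """Maximal specificity at a sensitivity target, over all thresholds.

    Formulated as its own linear program (not by inverting the
    sensitivity-direction curve numerically).
    """
    if not 0.0 <= sens_target <= 1.0:
        raise ValueError("sens_target must be in [0, 1]")
    return _sweep(params, sens_target, b, "specificity")


def max_roc_curve(
    params: DiseaseParams, spec_grid: Sequence[float], b: int = 1000
) -> list[ROCBoundPoint]:
    """Maximal ROC envelope: one point per specificity target.

    ``spec_grid`` must be sorted ascending.  Each point may be realized by a
    different distribution; the envelope is nonincreasing in the specificity
    target.
    """
    grid = np.asarray(spec_grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) < 0):
        raise ValueError("spec_grid must be a 1-D ascending sequence")
    return [max_roc_point(params, s, b) for s in grid]
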