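"""Synthetic risk distributions and sampled cohorts for validation.

Property tests need arbitrary feasible risk distributions with prescribed
(k, PVE).  :func:`random_feasible_distribution` builds them by moment
matching through convex mixtures: a seeded Dirichlet draw is first brought
to mean ``k`` by mixing with a point mass at risk 0 or 1, then to the
target second moment by mixing with the minimum-variance (adjacent-bin) or
maximum-variance (risks 0 and 1) distribution of the same mean.  Every
stage mixes nonnegative vectors, so the result is a valid distribution with
both moments exact, for any feasible (k, PVE).  :func:`empirical_auc`
simulates a finite cohort from a distribution — risks drawn from the
histogram, diseases drawn from the risks — and computes the rank-based AUC
of risk as a predictor, which converges to the exact enumeration value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .auc_bound import _min_variance_distribution, check_feasibility, feasible_start
from .risk_model import DiseaseParams, RiskDistribution

__all__ = ["FixtureSpec", "random_feasible_distribution", "empirical_auc"]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one random feasible distribution.

    ``n_support`` bounds how many bins receive random mass before the moment
    projection (the projection may spread mass slightly); ``None`` uses all
    bins.  The moment contract is exact; the shape is otherwise arbitrary.
    """

    k: float
    pve: float
    bins: int = 100
    n_support: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pve > 0 and self.n_support is not None and self.n_support < 2:
            raise ValueError("n_support must be >= 2 when pve > 0")


def random_feasible_distribution(spec: FixtureSpec) -> RiskDistribution:
    """Seeded random distribution with mean ``k`` and PVE ``pve`` exactly.

    Deterministic for a given spec.  Raises for grid-infeasible (k, pve).
    The contract is on the moments, not on the shape: the result is a
    convex mixture of a Dirichlet draw (on ``n_support`` random bins if
    given) with the extreme-variance anchor distributions.
    """
    params = DiseaseParams(k=spec.k, pve=spec.pve)
    b, k, m2 = spec.bins, spec.k, None
    rep = check_feasibility(params, b)
    if not rep.feasible:
        raise ValueError(rep.message)
    m2 = rep.m2
    base = feasible_start(params, b)
    # Degenerate corners admit a unique distribution: return it directly.
    span = rep.m2_max - rep.m2_min
    if spec.pve >= 1.0 or span <= 1e-14 or m2 <= rep.m2_min + 1e-14:
        return RiskDistribution(bins=b, probs=base)

    rng = np.random.default_rng(spec.seed)
    support = np.arange(b + 1)
    if spec.n_support is not None and spec.n_support < b + 1:
        support = rng.choice(b + 1, size=spec.n_support, replace=False)
    r = np.zeros(b + 1)
    r[support] = rng.dirichlet(np.ones(len(support)))

    levels = np.arange(b + 1) / b
    mu = float(levels @ r)
    # stage 1: fix the mean by mixing with a point mass at risk 0 or 1
    if mu > k:
        w = k / mu
        r = w * r
        r[0] += 1.0 - w
    elif mu < k:
        w = (1.0 - k) / (1.0 - mu)
        r = w * r
        r[b] += 1.0 - w
    # stage 2: fix the second moment by mixing with the same-mean anchor
    m2_r = float(levels**2 @ r)
    if m2_r < m2:
        anchor = np.zeros(b + 1)
        anchor[0], anchor[b] = 1.0 - k, k  # maximal variance, mean k
        lam = (m2 - m2_r) / (k - m2_r)
    else:
        anchor = _min_variance_distribution(k, b)  # minimal variance, mean k
        lam = (m2_r - m2) / max(m2_r - rep.m2_min, 1e-300)
    p = (1.0 - lam) * r + lam * anchor
    return RiskDistribution(bins=b, probs=p / p.sum())


def empirical_auc(
    d: RiskDistribution, n: int, seed: int = 0
) -> float:
    """Rank-based AUC of true risk in a simulated cohort of size ``n``.

    Each individual's risk is drawn from ``d`` and their binary outcome from
    that risk; the AUC is the Mann-Whitney statistic of risk against
    outcome, ties counted half.  Returns NaN (flagged undefined) if the
    sample contains only cases or only controls.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    risks = d.levels[rng.choice(d.bins + 1, size=n, p=d.probs)]
    sick = rng.random(n) < risks
    n1 = int(sick.sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = stats.rankdata(risks)
    u = ranks[sick].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
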