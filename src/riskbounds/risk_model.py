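"""Binned genetic risk distributions and their exact accuracy measures.

A population's genetic risk distribution is modelled as a histogram over
``b + 1`` equally spaced risk levels ``0, 1/b, 2/b, ..., 1``: ``probs[i]`` is
the probability that a random individual's conditional disease risk (the
probability of disease given their genetic profile) equals ``i/b``.  Two
scalar summaries of such a distribution drive everything in this package:

* the *average risk* ``k`` (prevalence or lifetime risk) — the mean of the
  risk distribution, by the law of total probability; and
* the *proportion of variance explained* (PVE) — the fraction of the
  phenotypic (Bernoulli) variance ``k(1-k)`` attributable to variation in
  risk; broad-sense heritability on the observed binary scale is the special
  case where the risk distribution is the genetic one.

Everything here is exact arithmetic on the histogram: case/control risk
densities via Bayes' rule, the Mann-Whitney AUC of the ideal risk-ranking
predictor, and sensitivity/specificity at every threshold.  These serve as
the brute-force oracle against which the optimization modules are verified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd  # delimited-text I/O only

__all__ = [
    "PROB_TOL",
    "RiskDistribution",
    "DiseaseParams",
    "CaseControlDensities",
    "mean_risk",
    "pve_of_distribution",
    "case_control_densities",
    "auc_oracle",
    "sens_spec_at_threshold",
    "roc_points",
    "read_distribution",
    "write_distribution",
]

#: Tolerance for probability-sum and moment identities (accumulated float
#: error over at most 1001 bins is orders of magnitude below this).
PROB_TOL = 1e-9


@dataclass(frozen=True)
class RiskDistribution:
    """Categorical distribution of conditional risk on the grid ``i/b``.

    Parameters
    ----------
    bins : int
        Number of equal subdivisions ``b >= 1``; there are ``b + 1`` risk
        levels ``0, 1/b, ..., 1``.
    probs : array-like of shape (b + 1,)
        ``probs[i]`` is the probability of having conditional risk ``i/b``.
        Must be nonnegative and sum to one within ``PROB_TOL``.
    """

    bins: int
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        b = self.bins
        if not (isinstance(b, (int, np.integer)) and b >= 1):
            raise ValueError(f"bins must be an integer >= 1, got {b!r}")
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (b + 1,):
            raise ValueError(
                f"probs must have length bins + 1 = {b + 1}, got shape {p.shape}"
            )
        if np.any(p < -PROB_TOL) or np.any(p > 1 + PROB_TOL):
            raise ValueError("probabilities must lie in [0, 1]")
        total = p.sum()
        if abs(total - 1.0) > PROB_TOL:
            raise ValueError(f"probabilities must sum to 1 (got {total!r})")
        p = np.clip(p, 0.0, 1.0)
        p.setflags(write=False)
        object.__setattr__(self, "bins", int(b))
        object.__setattr__(self, "probs", p)

    @property
    def levels(self) -> np.ndarray:
        """Risk levels ``i/b`` for ``i = 0..b``."""
        return np.arange(self.bins + 1) / self.bins

    def mean_risk(self) -> float:
        return mean_risk(self)

    def pve(self) -> float:
        return pve_of_distribution(self)

    def auc(self) -> float:
        return auc_oracle(self)


@dataclass(frozen=True)
class DiseaseParams:
    """Average risk ``k`` and proportion of variance explained.

    ``k`` is the unconditional probability of the binary trait (prevalence,
    or lifetime risk for lifetime prediction).  ``pve`` is the proportion of
    the phenotypic variance ``k(1-k)`` explained by the predictive factors;
    with all genetic factors it is broad-sense heritability H^2 on the
    observed binary scale.
    """

    k: float
    pve: float

    def __post_init__(self) -> None:
        if not 0.0 < self.k < 1.0:
            raise ValueError(f"average risk k must be in (0, 1), got {self.k}")
        if not 0.0 <= self.pve <= 1.0:
            raise ValueError(f"pve must be in [0, 1], got {self.pve}")


@dataclass(frozen=True)
class CaseControlDensities:
    """Risk densities among future non-cases (X) and cases (Y).

    ``p_x[i] = P(X = i/b)`` is the probability that an individual who will
    *not* develop the trait has risk ``i/b``; ``p_y`` the same for those who
    will.  Both follow from the population distribution by Bayes' rule.
    """

    p_x: np.ndarray
    p_y: np.ndarray


def mean_risk(d: RiskDistribution) -> float:
    """Mean of the risk distribution = unconditional probability of disease."""
    return float(d.levels @ d.probs)


def pve_of_distribution(d: RiskDistribution) -> float:
    """Proportion of phenotypic variance explained by the risk distribution.

    Computed as ``1 - E[risk(1-risk)] / (k(1-k))`` with ``k`` the mean risk:
    the residual Bernoulli variance within risk groups, relative to the total
    phenotypic variance.  Equals ``Var(risk)/(k(1-k))``.
    """
    k = mean_risk(d)
    if not 0.0 < k < 1.0:
        raise ValueError("PVE undefined: mean risk is 0 or 1")
    r = d.levels
    residual = float(d.probs @ (r * (1.0 - r)))
    return 1.0 - residual / (k * (1.0 - k))


def case_control_densities(d: RiskDistribution) -> CaseControlDensities:
    """Bayes-rule risk densities of non-cases (X) and cases (Y).

    ``P(X=i/b) = (b-i) p_i / (b(1-k))`` and ``P(Y=i/b) = i p_i / (b k)``.
    """
    k = mean_risk(d)
    if not 0.0 < k < 1.0:
        raise ValueError("densities undefined: mean risk is 0 or 1")
    b = d.bins
    i = np.arange(b + 1)
    p_x = (b - i) * d.probs / (b * (1.0 - k))
    p_y = i * d.probs / (b * k)
    return CaseControlDensities(p_x=p_x, p_y=p_y)


def auc_oracle(d: RiskDistribution) -> float:
    """AUC of the ideal risk-ranking predictor, by direct enumeration.

    Uses the Mann-Whitney identity ``AUC = P(X < Y) + P(X = Y)/2`` where X
    and Y are the risks of a random non-case and case.  Brute force over the
    grid; no optimization.
    """
    dens = case_control_densities(d)
    cdf_x = np.cumsum(dens.p_x)
    # P(X < i/b) + P(X = i/b)/2, summed against P(Y = i/b)
    below = cdf_x - dens.p_x / 2.0
    return float(dens.p_y @ below)


def sens_spec_at_threshold(d: RiskDistribution, t: int) -> tuple[float, float]:
    """Sensitivity and specificity of "declare positive iff risk >= t/b".

    ``t`` ranges over ``0..b+1``; ``t = 0`` declares everyone positive and
    ``t = b+1`` nobody, giving the trivial ROC endpoints.
    """
    b = d.bins
    if not 0 <= t <= b + 1:
        raise ValueError(f"threshold bin t must be in 0..{b + 1}, got {t}")
    k = mean_risk(d)
    if not 0.0 < k < 1.0:
        raise ValueError("sensitivity/specificity undefined: mean risk is 0 or 1")
    i = np.arange(b + 1)
    pos = i >= t
    se = float((i[pos] * d.probs[pos]).sum() / (b * k))
    sp = float(((b - i[~pos]) * d.probs[~pos]).sum() / (b * (1.0 - k)))
    return se, sp


def roc_points(d: RiskDistribution) -> np.ndarray:
    """Threshold-swept ROC of ``d``: array of (1 - Sp, Se) rows, t = b+1..0.

    Ordered so the false-positive rate increases; the trapezoidal area under
    this polyline equals :func:`auc_oracle` (ties contribute the half term).
    """
    pts = [sens_spec_at_threshold(d, t) for t in range(d.bins + 1, -1, -1)]
    se = np.array([p[0] for p in pts])
    sp = np.array([p[1] for p in pts])
    return np.column_stack([1.0 - sp, se])


def write_distribution(d: RiskDistribution, path_or_buf) -> None:
    """Write a risk distribution as two-column CSV (risk, probability)."""
    df = pd.DataFrame({"risk": d.levels, "probability": d.probs})
    df.to_csv(path_or_buf, index=False)


def read_distribution(path_or_buf, bins: int | None = None) -> RiskDistribution:
    """Read a risk distribution from two-column delimited text.

    The file must have columns ``risk`` and ``probability`` (comma or tab
    separated).  Risk levels must match the grid ``i/b`` exactly for the
    declared (or inferred) bin count ``b``; files on a different grid are
    rejected rather than silently re-binned, because the bounds are defined
    on the exact grid.
    """
    df = pd.read_csv(path_or_buf, sep=None, engine="python", comment="#")
    cols = {c.strip().lower(): c for c in df.columns}
    if "risk" not in cols or "probability" not in cols:
        raise ValueError("expected columns 'risk' and 'probability'")
    risk = df[cols["risk"]].to_numpy(dtype=float)
    prob = df[cols["probability"]].to_numpy(dtype=float)
    if bins is None:
        bins = len(risk) - 1
    grid = np.arange(bins + 1) / bins
    if len(risk) != bins + 1 or not np.allclose(risk, grid, atol=1e-12, rtol=0):
        raise ValueError(
            f"risk levels do not match the i/{bins} grid; re-binning is not performed"
        )
    return RiskDistribution(bins=bins, probs=prob)
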