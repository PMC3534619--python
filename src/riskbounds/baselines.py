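"""Comparators and scale conversions for the distribution-free bounds.

The main comparator is the beta-distributed risk baseline: among smooth
unimodal risk distributions, the beta with shapes ``a = k(1/PVE - 1)`` and
``b = (1-k)(1/PVE - 1)`` is the unique beta matching mean ``k`` and variance
``PVE * k(1-k)``.  Its (discretized) AUC and ROC stand in for earlier
liability-scale approximations of prediction limits, and sit at or below
the distribution-free optima by construction.

Also here: the planning identity ``R^2 = r^2 H^2`` for a prospective GWAS,
the twin-correlation estimate of observed-scale heritability, and the
Dempster-Lerner liability-to-binary-scale conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .risk_model import DiseaseParams, RiskDistribution, auc_oracle

__all__ = [
    "BetaRiskParams",
    "beta_params",
    "discretize_beta",
    "beta_auc",
    "beta_roc_points",
    "gwas_r2",
    "twin_h2_binary",
    "liability_to_binary_h2",
]


@dataclass(frozen=True)
class BetaRiskParams:
    """Shape parameters of the moment-matched beta risk distribution.

    (``b_shape`` rather than ``b`` to avoid clashing with the bin count.)
    """

    a: float
    b_shape: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b_shape > 0):
            raise ValueError("beta shapes must be positive")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b_shape)

    @property
    def variance(self) -> float:
        s = self.a + self.b_shape
        return self.a * self.b_shape / (s * s * (s + 1.0))


def beta_params(params: DiseaseParams) -> BetaRiskParams:
    """The unique beta shapes with mean k and variance PVE * k(1-k)."""
    if not 0.0 < params.pve < 1.0:
        raise ValueError("beta baseline requires 0 < pve < 1")
    c = 1.0 / params.pve - 1.0
    return BetaRiskParams(a=params.k * c, b_shape=(1.0 - params.k) * c)


def discretize_beta(bp: BetaRiskParams, b: int) -> RiskDistribution:
    """Project a beta risk density onto the ``i/b`` grid by cell probability.

    Bin ``i`` receives the beta CDF mass of the cell ``[(i-1/2)/b,
    (i+1/2)/b]`` (clipped to [0, 1]); the result is renormalized.  Mean and
    PVE of the discretization converge to the beta's at rate O(1/b).
    """
    if b < 2:
        raise ValueError(f"b must be >= 2, got {b}")
    edges = np.clip((np.arange(b + 2) - 0.5) / b, 0.0, 1.0)
    cdf = stats.beta.cdf(edges, bp.a, bp.b_shape)
    p = np.diff(cdf)
    p /= p.sum()
    return RiskDistribution(bins=b, probs=p)


def beta_auc(params: DiseaseParams, b: int = 1000) -> float:
    """AUC if risk truly followed the moment-matched beta distribution.

    One feasible distribution among all matching (k, PVE): never exceeds the
    distribution-free maximum for the same parameters.
    """
    return auc_oracle(discretize_beta(beta_params(params), b))


def beta_roc_points(params: DiseaseParams, b: int = 1000) -> np.ndarray:
    """Threshold-swept ROC (rows of (1 - Sp, Se)) of the discretized beta."""
    from .risk_model import roc_points

    return roc_points(discretize_beta(beta_params(params), b))


def gwas_r2(r: float, h2: float) -> float:
    """Phenotypic variance a planned GWAS may explain: ``R^2 = r^2 H^2``.

    ``r`` is the anticipated correlation between GWAS-estimated and true
    genetic risk; ``h2`` the broad-sense heritability on the binary scale.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("correlation r must be in [0, 1]")
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("heritability must be in [0, 1]")
    return r * r * h2


def twin_h2_binary(r_mz: float, r_dz: float) -> float:
    """Observed-scale heritability from twin correlations: ``2(r_MZ - r_DZ)``.

    Correlations are computed on the binary outcomes of monozygotic and
    dizygotic pairs.  Estimates outside [0, 1] (sampling noise) are clamped
    with a warning rather than rejected.
    """
    for name, r in (("r_mz", r_mz), ("r_dz", r_dz)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name} must be a correlation in [-1, 1]")
    if r_mz < r_dz:
        raise ValueError("r_mz < r_dz violates the twin model")
    h2 = 2.0 * (r_mz - r_dz)
    if h2 > 1.0:
        warnings.warn(
            f"twin heritability estimate {h2:.3f} clamped to 1", stacklevel=2
        )
    return float(np.clip(h2, 0.0, 1.0))


def liability_to_binary_h2(h2_liab: float, k: float) -> float:
    """Dempster-Lerner conversion of liability-scale heritability.

    ``h2_obs = h2_liab * z^2 / (k(1-k))`` where ``z`` is the standard normal
    density at the liability threshold for prevalence ``k``.  Formula from
    the standard quantitative-genetics literature.  Results above 1 are
    clamped with a warning.
    """
    if not 0.0 < k < 1.0:
        raise ValueError("prevalence k must be in (0, 1)")
    if not 0.0 <= h2_liab <= 1.0:
        raise ValueError("liability heritability must be in [0, 1]")
    z = stats.norm.pdf(stats.norm.ppf(k))
    h2 = h2_liab * z * z / (k * (1.0 - k))
    if h2 > 1.0:
        warnings.warn(
            f"observed-scale heritability {h2:.3f} clamped to 1", stacklevel=2
        )
    return float(np.clip(h2, 0.0, 1.0))
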