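import numpy as np
import pytest

from riskbounds import RiskDistribution


@pytest.fixture
def two_point() -> RiskDistribution:
    """Half the population at risk 0.2, half at risk 0.4 (b = 10).

    Mean risk 0.3, PVE 1/21, ideal-predictor AUC 13/21 — all derivable by
    hand, so this distribution anchors most exact-value checks.
    """
    p = np.zeros(11)
    p[2] = p[4] = 0.5
    return RiskDistribution(bins=10, probs=p)


def point_mass(b: int, i: int) -> RiskDistribution:
    p = np.zeros(b + 1)
    p[i] = 1.0
    return RiskDistribution(bins=b, probs=p)


def extreme_mix(b: int, k: float) -> RiskDistribution:
    """Mass 1-k at risk 0 and k at risk 1: maximal variance for mean k."""
    p = np.zeros(b + 1)
    p[0], p[b] = 1.0 - k, k
    return RiskDistribution(bins=b, probs=p)


@pytest.fixture
def random_distributions():
    """Seeded Dirichlet draws on the b = 25 grid, non-degenerate mean."""
    rng = np.random.default_rng(20260928)
    out = []
    while len(out) < 50:
        d = RiskDistribution(bins=25, probs=rng.dirichlet(np.full(26, 0.3)))
        if 1e-6 < d.mean_risk() < 1 - 1e-6:
            out.append(d)
    return out
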