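"""Exact arithmetic on binned risk distributions: the package's oracle."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskbounds import (
    RiskDistribution,
    auc_oracle,
    case_control_densities,
    mean_risk,
    pve_of_distribution,
    read_distribution,
    roc_points,
    sens_spec_at_threshold,
    write_distribution,
)
from conftest import extreme_mix, point_mass


class TestValidation:
    def test_probs_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            RiskDistribution(bins=4, probs=[0.5, 0.1, 0.1, 0.1, 0.1])

    def test_probs_must_be_nonnegative(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            RiskDistribution(bins=2, probs=[1.5, -0.5, 0.0])

    def test_length_must_match_bins(self):
        with pytest.raises(ValueError, match="length"):
            RiskDistribution(bins=10, probs=np.full(10, 0.1))

    @pytest.mark.parametrize("op", [pve_of_distribution, auc_oracle,
                                    case_control_densities])
    def test_degenerate_mean_rejected(self, op):
        # all mass at risk zero: nobody ever gets sick, accuracy undefined
        with pytest.raises(ValueError, match="undefined"):
            op(point_mass(10, 0))


class TestMoments:
    def test_mean_risk_two_point(self, two_point):
        assert mean_risk(two_point) == pytest.approx(0.3, abs=1e-15)

    @pytest.mark.parametrize("i, expected", [(0, 0.0), (10, 1.0)])
    def test_mean_risk_degenerate(self, i, expected):
        assert mean_risk(point_mass(10, i)) == expected

    def test_pve_two_point(self, two_point):
        # residual variance 0.2 against phenotypic variance 0.21
        assert pve_of_distribution(two_point) == pytest.approx(1 - 0.2 / 0.21)

    def test_pve_extremes(self):
        assert pve_of_distribution(extreme_mix(10, 0.3)) == pytest.approx(1.0)
        assert pve_of_distribution(point_mass(10, 4)) == pytest.approx(0.0, abs=1e-12)

    def test_pve_forms_agree(self, random_distributions):
        """Residual-variance and second-moment forms of PVE coincide."""
        for d in random_distributions:
            k = mean_risk(d)
            m2 = float(d.probs @ d.levels**2)
            second_moment_form = (m2 - k * k) / (k * (1 - k))
            assert pve_of_distribution(d) == pytest.approx(
                second_moment_form, abs=1e-12
            )
            assert 0.0 <= pve_of_distribution(d) <= 1.0


class TestCaseControl:
    def test_two_point_densities(self, two_point):
        dens = case_control_densities(two_point)
        assert dens.p_x[2] == pytest.approx(4 / 7)
        assert dens.p_x[4] == pytest.approx(3 / 7)
        assert dens.p_y[2] == pytest.approx(1 / 3)
        assert dens.p_y[4] == pytest.approx(2 / 3)

    def test_single_bin_gives_point_masses(self):
        dens = case_control_densities(point_mass(10, 3))
        assert dens.p_x[3] == pytest.approx(1.0)
        assert dens.p_y[3] == pytest.approx(1.0)

    def test_extreme_mix_separates(self):
        dens = case_control_densities(extreme_mix(10, 0.5))
        assert dens.p_x[0] == pytest.approx(1.0)
        assert dens.p_y[10] == pytest.approx(1.0)

    def test_densities_normalized(self, random_distributions):
        for d in random_distributions:
            dens = case_control_densities(d)
            assert dens.p_x.sum() == pytest.approx(1.0, abs=1e-9)
            assert dens.p_y.sum() == pytest.approx(1.0, abs=1e-9)
            assert dens.p_x.min() >= 0 and dens.p_y.min() >= 0


class TestAUCOracle:
    def test_two_point(self, two_point):
        assert auc_oracle(two_point) == pytest.approx(13 / 21, abs=1e-12)

    def test_single_bin_is_chance(self):
        assert auc_oracle(point_mass(10, 5)) == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert auc_oracle(extreme_mix(10, 0.3)) == pytest.approx(1.0)

    def test_risk_ranking_beats_chance(self, random_distributions):
        # cases stochastically dominate controls under the ideal ranking
        for d in random_distributions:
            assert auc_oracle(d) >= 0.5 - 1e-12


class TestThresholds:
    def test_two_point_at_t3(self, two_point):
        se, sp = sens_spec_at_threshold(two_point, 3)
        assert se == pytest.approx(2 / 3)
        assert sp == pytest.approx(4 / 7)

    def test_endpoints(self, two_point):
        assert sens_spec_at_threshold(two_point, 0) == pytest.approx((1.0, 0.0))
        assert sens_spec_at_threshold(two_point, 11) == pytest.approx((0.0, 1.0))

    def test_threshold_out_of_range(self, two_point):
        with pytest.raises(ValueError, match="0..11"):
            sens_spec_at_threshold(two_point, 12)

    def test_roc_monotone_and_area(self, random_distributions):
        """Sweeping the threshold traces a monotone ROC whose trapezoidal
        area reproduces the Mann-Whitney AUC (ties as the half term)."""
        for d in random_distributions:
            pts = roc_points(d)
            fpr, se = pts[:, 0], pts[:, 1]
            assert np.all(np.diff(se) >= -1e-12)
            assert np.all(np.diff(fpr) >= -1e-12)
            area = np.trapezoid(se, fpr)
            assert area == pytest.approx(auc_oracle(d), abs=1e-9)


class TestArbitraryDistributions:
    @given(
        weights=st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=3, max_size=21
        ).filter(lambda w: sum(w) > 1e-6)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_accuracy_measures_well_defined(self, weights):
        """For any histogram with non-degenerate mean: AUC in [0.5, 1],
        PVE in [0, 1], and the threshold ROC integrates back to the AUC."""
        probs = np.asarray(weights) / sum(weights)
        d = RiskDistribution(bins=len(probs) - 1, probs=probs)
        k = mean_risk(d)
        if not 1e-9 < k < 1 - 1e-9:
            return
        assert 0.0 <= pve_of_distribution(d) <= 1.0 + 1e-12
        auc = auc_oracle(d)
        assert 0.5 - 1e-12 <= auc <= 1.0 + 1e-12
        pts = roc_points(d)
        assert np.trapezoid(pts[:, 1], pts[:, 0]) == pytest.approx(auc, abs=1e-9)


class TestIO:
    def test_roundtrip(self, two_point, tmp_path):
        path = tmp_path / "dist.csv"
        write_distribution(two_point, path)
        back = read_distribution(path)
        assert back.bins == two_point.bins
        np.testing.assert_allclose(back.probs, two_point.probs, atol=1e-12)

    def test_wrong_grid_rejected(self):
        text = "risk,probability\n0.0,0.5\n0.3,0.5\n"
        with pytest.raises(ValueError, match="grid"):
            read_distribution(io.StringIO(text))

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            read_distribution(io.StringIO("a,b\n0,1\n"))
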