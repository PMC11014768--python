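"""ML fitting, standard errors, identification, LRT/NCP and power."""

import numpy as np
import pytest

from ivclpm import (
    DataGenParams,
    FitResult,
    MomentSet,
    apply_restrictions,
    build_clpm,
    build_iv_clpm,
    build_ivr,
    fit_ml,
    local_identification,
    lrt,
    power_from_ncp,
    residual_correlations,
    standard_errors,
    two_wave_moments,
)
from ivclpm.models import fix_parameters
from ivclpm.models import ModelSpec


def ivclpm_moments(theta, n=1000):
    m = build_iv_clpm()
    sigma = m.ram.expected_covariance(theta)
    mu = m.ram.expected_means(theta)
    return m, MomentSet(labels=m.ram.labels, cov=sigma, means=mu, n=n)


class TestFitML:
    def test_saturated_fit_reproduces_input_moments(self, figure_set_params):
        """The just-identified CLPM is a reparameterization of the
        4-variable moments: discrepancy 0 and implied moments equal the
        input."""
        mom = two_wave_moments(figure_set_params, 5).subset(["X1", "Y1", "X2", "Y2"])
        fit = fit_ml(build_clpm(), mom)
        assert abs(fit.discrepancy) < 1e-10
        sigma = fit.model.ram.expected_covariance(fit.estimates)
        assert np.abs(sigma - mom.cov).max() < 1e-8
        mu = fit.model.ram.expected_means(fit.estimates)
        assert np.abs(mu - mom.means).max() < 1e-10

    def test_generating_parameters_recovered_exactly(self, ivclpm_theta):
        """Fitting the true model to its own implied moments returns the
        generating values (exact-data-simulation property)."""
        model, mom = ivclpm_moments(ivclpm_theta)
        fit = fit_ml(model, mom)
        assert fit.converged
        for name, val in ivclpm_theta.items():
            assert fit.estimates[name] == pytest.approx(val, abs=1e-6), name

    def test_clpm_equals_multivariate_regression(self, figure_set_params):
        """The CLPM lagged block has the closed form S21 S11^-1."""
        mom = two_wave_moments(figure_set_params, 7).subset(["X1", "Y1", "X2", "Y2"])
        fit = fit_ml(build_clpm(), mom)
        B = mom.cov[2:, :2] @ np.linalg.inv(mom.cov[:2, :2])
        assert fit.estimates["bX2X1"] == pytest.approx(B[0, 0], abs=1e-8)
        assert fit.estimates["bX2Y1"] == pytest.approx(B[0, 1], abs=1e-8)
        assert fit.estimates["bY2X1"] == pytest.approx(B[1, 0], abs=1e-8)
        assert fit.estimates["bY2Y1"] == pytest.approx(B[1, 1], abs=1e-8)

    def test_aic_identity(self, figure_set_params):
        mom = two_wave_moments(figure_set_params, 5)
        fit = fit_ml(build_iv_clpm(), mom)
        assert fit.aic - fit.minus2lnL - 2 * fit.n_free == pytest.approx(0.0, abs=1e-12)

    def test_non_pd_moments_rejected(self):
        cov = np.array([[1.0, 1.2], [1.2, 1.0]])
        mom = MomentSet(labels=["IVx", "X"], cov=cov, means=np.zeros(2), n=10)
        with pytest.raises(ValueError, match="positive-definite"):
            fit_ml(build_ivr(), MomentSet(labels=["IVx", "X", "Y"],
                                          cov=np.pad(cov, ((0, 1), (0, 1))) + np.diag([0, 0, 1.0]),
                                          means=np.zeros(3), n=10))


class TestStandardErrors:
    def test_positive_on_converged_just_identified_fit(self, figure_set_params):
        mom = two_wave_moments(figure_set_params, 5).subset(["X1", "Y1", "X2", "Y2"])
        fit = fit_ml(build_clpm(), mom, compute_se=True)
        assert fit.converged
        assert all(v > 0 for v in fit.se.values())

    def test_slope_se_matches_regression_formula(self):
        """For a single regression y = b x + e, the large-n ML standard
        error of b is sqrt(Ve / (n Vx))."""
        from ivclpm.ram import Parameter, RAMSpec

        A = np.array([[0.0, 0.0], ["b", 0.0]], dtype=object)
        S = np.array([["Vx", 0.0], [0.0, "Ve"]], dtype=object)
        M = np.array(["m_x", "m_y"], dtype=object)
        ram = RAMSpec(labels=["x", "y"], A=A, S=S, M=M,
                      free_params=[Parameter("b"), Parameter("Vx", 1.0),
                                   Parameter("Ve", 1.0), Parameter("m_x"),
                                   Parameter("m_y")])
        model = ModelSpec(ram=ram, causal_params={}, family="ivr",
                          direction="unidirectional")
        b, vx, ve, n = 0.4, 2.0, 1.5, 1000
        cov = np.array([[vx, b * vx], [b * vx, b**2 * vx + ve]])
        mom = MomentSet(labels=["x", "y"], cov=cov, means=np.zeros(2), n=n)
        fit = fit_ml(model, mom, compute_se=True)
        assert fit.se["b"] == pytest.approx(np.sqrt(ve / (n * vx)), rel=0.02)

    def test_se_scales_inverse_sqrt_n(self, figure_set_params):
        mom = two_wave_moments(figure_set_params, 5).subset(["X1", "Y1", "X2", "Y2"])
        f1 = fit_ml(build_clpm(), mom, compute_se=True)
        mom4 = MomentSet(labels=mom.labels, cov=mom.cov, means=mom.means, n=4 * mom.n)
        f4 = fit_ml(build_clpm(), mom4, compute_se=True)
        for name in ("bY2X1", "bX2X1"):
            assert f1.se[name] / f4.se[name] == pytest.approx(2.0, rel=0.01)


class TestIdentification:
    def test_full_bidirectional_ivclpm_is_identified(self):
        rep = local_identification(build_iv_clpm())
        assert rep.identified and rep.rank == rep.n_free

    def test_saturated_clpm_is_identified(self):
        rep = local_identification(build_clpm())
        assert rep.identified

    def test_reciprocal_pair_unidentified_without_instruments(self):
        """Freeing both wave-1 reciprocal proximal paths while cutting the
        wave-1 instrument paths leaves the pair unidentified."""
        m = build_iv_clpm()
        ram = fix_parameters(m.ram, {"bx1": 0.0, "by1": 0.0})
        broken = ModelSpec(ram=ram, causal_params={}, family="ivclpm",
                           direction="bidirectional")
        rep = local_identification(broken)
        assert not rep.identified
        assert rep.rank < rep.n_free


def fit_like(minus2lnL: float, n_params: int, names=None) -> FitResult:
    """A FitResult shell holding externally reported statistics."""
    names = names or [f"p{i}" for i in range(n_params)]
    return FitResult(estimates={n: 0.0 for n in names}, minus2lnL=minus2lnL,
                     n_free=n_params, df=0, aic=minus2lnL + 2 * n_params,
                     converged=True, gradient_norm=0.0, discrepancy=0.0)


class TestLRT:
    def test_published_two_df_comparison(self):
        """-2lnL 31,707.37 (16 parameters) vs 31,699.08 (18 parameters):
        NCP 8.29 on 2 df, p = 0.0159; AIC of the full model 31,735.08."""
        names = [f"p{i}" for i in range(18)]
        full = fit_like(31_699.08, 18, names)
        restricted = fit_like(31_707.37, 16, names[:16])
        res = lrt(full, restricted)
        assert res.ncp == pytest.approx(8.29, abs=1e-9)
        assert res.delta_df == 2
        # chi2 upper tail at (8.29, 2df) is 0.015843; the published 0.0159
        # came from the unrounded likelihoods
        assert res.p_value == pytest.approx(0.0159, abs=1e-4)
        assert full.aic == pytest.approx(31_735.08, abs=1e-9)

    def test_self_comparison_is_degenerate(self):
        full = fit_like(100.0, 5)
        res = lrt(full, full)
        assert res.ncp == 0.0 and res.p_value == 1.0

    def test_non_nested_inputs_rejected(self):
        full = fit_like(100.0, 5, ["a", "b", "c", "d", "e"])
        other = fit_like(101.0, 3, ["x", "y", "z"])
        with pytest.raises(ValueError, match="not nested"):
            lrt(full, other)

    def test_likelihood_decrease_raises(self):
        names = ["a", "b", "c"]
        full = fit_like(100.0, 3, names)
        bad = fit_like(99.0, 2, names[:2])
        with pytest.raises(ValueError, match="decreased"):
            lrt(full, bad)

    def test_ncp_hierarchy_monotone(self, figure_set_params):
        """6 df omnibus >= 3 df per direction >= each constituent 1 df,
        on exact moments."""
        mom = two_wave_moments(figure_set_params, 10)
        m = build_iv_clpm()
        full = fit_ml(m, mom)

        def ncp(names):
            return lrt(full, fit_ml(apply_restrictions(m, names), mom,
                                    theta0=full.estimates)).ncp

        omnibus = ncp(["bY1X1", "bX1Y1", "bY2X1", "bX2Y1", "bY2X2", "bX2Y2"])
        for trio in (["bY1X1", "bY2X1", "bY2X2"], ["bX1Y1", "bX2Y1", "bX2Y2"]):
            three = ncp(trio)
            assert omnibus >= three - 1e-6
            for single in trio:
                assert three >= ncp([single]) - 1e-6

    def test_true_zero_restriction_has_zero_ncp(self, unidirectional_params):
        """Restricting causal parameters whose generating values are zero
        costs no likelihood on exact moments."""
        mom = two_wave_moments(unidirectional_params, 5)
        m = build_iv_clpm()
        full = fit_ml(m, mom)
        res = lrt(full, fit_ml(apply_restrictions(m, ["bX1Y1", "bX2Y1", "bX2Y2"]),
                               mom, theta0=full.estimates))
        assert res.ncp < 1e-6

    def test_unidirectional_vs_bidirectional_ncps(self, unidirectional_params):
        """On unidirectional-causation moments the parsimonious
        unidirectional model gives slightly smaller 1 df NCPs than the
        bidirectional model at moderate intervals (no power advantage);
        at dT = 1 the two are nearly equal, the bidirectional wave-2
        reciprocal path absorbing the restricted signal."""
        mb, mu = build_iv_clpm(True), build_iv_clpm(False)
        for dT in (5, 20):
            mom = two_wave_moments(unidirectional_params, dT)
            momu = mom.subset(mu.ram.labels)
            fb, fu = fit_ml(mb, mom), fit_ml(mu, momu)
            for name in ("bY1X1", "bY2X1", "bY2X2"):
                nb = lrt(fb, fit_ml(apply_restrictions(mb, [name]), mom,
                                    theta0=fb.estimates)).ncp
                nu = lrt(fu, fit_ml(apply_restrictions(mu, [name]), momu,
                                    theta0=fu.estimates)).ncp
                assert nu <= nb + 1e-6


class TestPower:
    def test_zero_ncp_gives_alpha(self):
        for alpha in (0.01, 0.05, 0.2):
            assert power_from_ncp(0.0, 2, alpha) == pytest.approx(alpha, abs=1e-12)

    def test_classic_calibration_point(self):
        """ncp 7.849 at 1 df, alpha 0.05 is the textbook 80%-power point."""
        assert power_from_ncp(7.849, 1, 0.05) == pytest.approx(0.80, abs=5e-3)

    def test_strictly_increasing_in_ncp(self):
        grid = [power_from_ncp(x, 3, 0.05) for x in np.linspace(0, 20, 15)]
        assert all(b > a for a, b in zip(grid, grid[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            power_from_ncp(-1.0, 1, 0.05)
        with pytest.raises(ValueError):
            power_from_ncp(1.0, 1, 1.5)


class TestResidualCorrelations:
    def test_formula(self):
        fit = fit_like(0.0, 1, ["x"])
        fit.estimates = {"Cx1y1": 0.0, "Vx1": 1.0, "Vy1": 2.0,
                         "Cx2y2": 0.3, "Vx2": 1.0, "Vy2": 1.0}
        rc = residual_correlations(fit)
        assert rc["rexy1"] == 0.0
        assert rc["rexy2"] == pytest.approx(0.3)

    def test_wave1_sign_flips_at_short_intervals(self, figure_set_params):
        """With generating residual correlation +0.3, the IV-CLPM's wave-1
        residual correlation is negative at a short interval: the
        cumulative proximal effects overshoot the observed cross-sectional
        covariance."""
        fit = fit_ml(build_iv_clpm(), two_wave_moments(figure_set_params, 1))
        assert residual_correlations(fit)["rexy1"] < 0

    def test_missing_parameters_rejected(self):
        fit = fit_like(0.0, 1, ["x"])
        with pytest.raises(ValueError, match="CLPM"):
            residual_correlations(fit)
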