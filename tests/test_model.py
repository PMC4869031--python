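"""GLMM likelihood and multimodel inference: quadrature accuracy,
degenerate collapses, candidate enumeration, averaging arithmetic, the
effect-size translation, and residual diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.integrate import trapezoid
from scipy.special import gammaln

from conflict_ecology.model import (
    FitResult,
    LikelihoodError,
    _DesignArrays,
    _marginal,
    akaike_weights,
    enumerate_candidates,
    fit_nb2_glmm,
    model_average,
    nb2_glmm_loglik,
    residual_diagnostics,
    salmon_effect_percent,
)
from conflict_ecology.recovery import simulate_and_assemble, single_replicate


@pytest.fixture(scope="module")
def tiny_design():
    design, truth, _ = simulate_and_assemble(21, n_units=4, n_years=8)
    return design


@pytest.fixture(scope="module")
def tiny_terms(tiny_design):
    return tuple(tiny_design.annual_terms)


def brute_force_marginal(design, terms, beta, phi, sigma, half_width=8.0, n_grid=40001):
    """Dense-trapezoid integration over each unit's random intercept."""
    d = _DesignArrays(design.data, terms)
    eta = d.X @ np.asarray(beta) + d.offset
    total = 0.0
    for j in range(d.n_units):
        rows = d.unit_idx == j
        a = np.linspace(-half_width * sigma, half_width * sigma, n_grid)
        log_joint = np.zeros_like(a)
        for yv, ev in zip(d.y[rows], eta[rows]):
            mu = np.exp(ev + a)
            log_joint += (
                gammaln(yv + phi) - gammaln(phi) - gammaln(yv + 1)
                + phi * np.log(phi) + yv * (ev + a) - (yv + phi) * np.log(mu + phi)
            )
        dens = np.exp(log_joint - 0.5 * a**2 / sigma**2) / np.sqrt(
            2 * np.pi * sigma**2
        )
        total += np.log(trapezoid(dens, a))
    return total


class TestMarginalLoglik:
    def test_sigma_zero_equals_plain_nb2(self, tiny_design, tiny_terms):
        rng = np.random.default_rng(1)
        p = len(tiny_terms) + 1
        beta = np.concatenate([[-9.5], rng.normal(0, 0.2, p - 1)])
        ll_glmm = nb2_glmm_loglik(beta, 0.8, 0.0, tiny_design, tiny_terms)
        d = _DesignArrays(tiny_design.data, tiny_terms)
        lnalpha = np.log(1 / 0.8)
        mod = sm.NegativeBinomial(d.y, d.X, offset=d.offset, loglike_method="nb2")
        ll_sm = mod.loglike(np.concatenate([beta, [lnalpha]]))
        assert ll_glmm == pytest.approx(ll_sm, abs=1e-8)

    def test_poisson_limit(self, tiny_design, tiny_terms):
        rng = np.random.default_rng(2)
        beta = np.concatenate([[-9.5], rng.normal(0, 0.2, len(tiny_terms))])
        ll_nb = nb2_glmm_loglik(beta, 1e6, 0.0, tiny_design, tiny_terms)
        d = _DesignArrays(tiny_design.data, tiny_terms)
        mu = np.exp(d.X @ beta + d.offset)
        ll_pois = float(np.sum(d.y * np.log(mu) - mu - gammaln(d.y + 1)))
        assert ll_nb == pytest.approx(ll_pois, abs=1e-3)

    def test_matches_dense_grid_oracle(self, tiny_design, tiny_terms):
        # tiny instance: 4 units x 5 years
        sub = tiny_design.data.groupby("unit_id").head(5)
        small = type(tiny_design)(
            data=sub, annual_terms=tiny_design.annual_terms,
            spatial_terms=tiny_design.spatial_terms, mode=tiny_design.mode,
        )
        rng = np.random.default_rng(3)
        beta = np.concatenate([[-9.2], rng.normal(0, 0.2, len(tiny_terms))])
        phi, sigma = 0.7, 0.4
        ll = nb2_glmm_loglik(beta, phi, sigma, small, tiny_terms)
        oracle = brute_force_marginal(small, tiny_terms, beta, phi, sigma)
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_gradient_matches_numerical(self, tiny_design, tiny_terms):
        d = _DesignArrays(tiny_design.data, tiny_terms)
        rng = np.random.default_rng(4)
        p = d.X.shape[1]
        theta = np.concatenate(
            [[-9.5], rng.normal(0, 0.2, p - 1), [np.log(0.8)], [np.log(0.5)]]
        )
        _, g = _marginal(theta, d, 15, True, {}, None)
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += 1e-6
            tm[i] -= 1e-6
            lp, _ = _marginal(tp, d, 15, False, {})
            lm, _ = _marginal(tm, d, 15, False, {})
            num = (lp - lm) / 2e-6
            assert g[i] == pytest.approx(num, abs=1e-4, rel=1e-5)

    def test_nonfinite_predictor_identified(self, tiny_design, tiny_terms):
        bad = tiny_design.data.copy()
        bad.loc[bad.index[3], "offset_log_area"] = np.inf
        with pytest.raises(LikelihoodError, match="row"):
            nb2_glmm_loglik(
                np.zeros(len(tiny_terms) + 1), 0.7, 0.4, bad, tiny_terms
            )

    def test_invalid_params_rejected(self, tiny_design, tiny_terms):
        beta = np.zeros(len(tiny_terms) + 1)
        with pytest.raises(LikelihoodError):
            nb2_glmm_loglik(beta, -1.0, 0.4, tiny_design, tiny_terms)
        with pytest.raises(LikelihoodError):
            nb2_glmm_loglik(beta, 0.7, -0.1, tiny_design, tiny_terms)


class TestFit:
    def test_sigma_zero_collapse_matches_independent_glm(self):
        # simulate without random effects; our GLMM fit should agree with
        # an independent NB2 GLM fit
        from conflict_ecology.synthetic import TruthParams

        truth = TruthParams(sigma_alpha=0.0)
        design, _, _ = simulate_and_assemble(31, n_units=20, n_years=25, truth=truth)
        terms = tuple(design.annual_terms) + tuple(design.spatial_terms)
        fit = fit_nb2_glmm(design, terms, seed=0, n_starts=2)
        d = _DesignArrays(design.data, terms)
        glm = sm.NegativeBinomial(
            d.y, d.X, offset=d.offset, loglike_method="nb2"
        ).fit(disp=0, maxiter=200)
        ours = np.array(
            [fit.beta["intercept"]] + [fit.beta[t] for t in terms]
        )
        if fit.sigma_alpha < 0.05:  # near the boundary, as simulated
            np.testing.assert_allclose(ours, glm.params[:-1], atol=2e-2)

    def test_deterministic_refit(self, tiny_design):
        terms = tuple(tiny_design.annual_terms)
        a = fit_nb2_glmm(tiny_design, terms, seed=5, n_starts=2)
        b = fit_nb2_glmm(tiny_design, terms, seed=5, n_starts=2)
        assert a.loglik == b.loglik
        assert a.beta == b.beta

    def test_recovers_truth_single_replicate(self):
        r = single_replicate(17, n_units=55, n_years=30)
        assert r["converged"]
        assert np.sign(r["beta_salmon"]) == -1.0
        assert 0.3 < r["phi"] < 1.5
        assert abs(r["beta_salmon"] - (-0.3)) < 3.5 * r["se_salmon"]


class TestCandidates:
    def test_salmon_areas_count(self):
        annual = ["salmon_biomass", "recent_conflict", "recent_hunt",
                  "annual_temp", "annual_precip"]
        spatial = ["bear_density", "human_density", "normal_temp", "normal_precip"]
        cands = enumerate_candidates(annual_terms=annual, spatial_terms=spatial)
        assert len(cands) == 32
        assert all(set(spatial) <= set(c) for c in cands)

    def test_full_region_count(self):
        annual = ["recent_conflict", "recent_hunt", "annual_temp", "annual_precip"]
        spatial = ["bear_density", "human_density", "normal_temp",
                   "normal_precip", "salmon_present"]
        cands = enumerate_candidates(annual_terms=annual, spatial_terms=spatial)
        assert len(cands) == 16

    def test_zero_annual_terms(self):
        cands = enumerate_candidates(annual_terms=[], spatial_terms=["a", "b"])
        assert cands == [("a", "b")]


def _mock_fit(terms, beta, aicc, se=None):
    se = se or {}
    return FitResult(
        terms=tuple(terms),
        beta={"intercept": 0.0, **beta},
        phi=0.7,
        sigma_alpha=0.3,
        loglik=0.0,
        aicc=aicc,
        converged=True,
        se={"intercept": 0.1, **se},
        n_obs=100,
        k_params=len(terms) + 3,
    )


class TestModelAverage:
    def test_single_candidate_identity(self):
        fit = _mock_fit(["x"], {"x": 0.4}, aicc=100.0, se={"x": 0.1})
        avg = model_average([fit])
        assert avg.estimate("x") == pytest.approx(0.4)
        assert avg.rvi("x") == pytest.approx(1.0)

    def test_equal_weight_hand_computation(self):
        f1 = _mock_fit(["x"], {"x": 0.2}, aicc=50.0, se={"x": 0.0})
        f2 = _mock_fit([], {}, aicc=50.0)
        avg = model_average([f1, f2])
        assert avg.estimate("x") == pytest.approx(0.1)
        assert avg.rvi("x") == pytest.approx(0.5)
        # unconditional SE includes between-model spread: w(0.1^2)*2 = 0.01
        assert avg.table.set_index("term").at["x", "se"] == pytest.approx(0.1)

    def test_weights_sum_to_one(self):
        fits = [
            _mock_fit(["x"], {"x": 0.1}, aicc=10.0 + i, se={"x": 0.1})
            for i in range(5)
        ]
        avg = model_average(fits)
        assert avg.weights.sum() == pytest.approx(1.0)

    def test_weights_invariant_to_constant_shift(self):
        aiccs = np.array([12.0, 15.0, 19.0])
        np.testing.assert_allclose(
            akaike_weights(aiccs), akaike_weights(aiccs + 1234.5), atol=1e-12
        )

    def test_no_converged_fits_errors(self):
        bad = _mock_fit(["x"], {"x": 0.1}, aicc=10.0)
        bad.converged = False
        with pytest.raises(Exception, match="converged"):
            model_average([bad])


class TestSalmonEffect:
    def test_null_effect(self):
        assert salmon_effect_percent(0.0, 0.5) == pytest.approx(0.0)

    def test_hand_evaluated_formula(self):
        # 100 (exp(-0.3 ln 0.5 / (2*0.5)) - 1) = 23.11%
        pct = salmon_effect_percent(-0.3, 0.5, fold=0.5)
        assert pct == pytest.approx(23.114, abs=0.01)

    def test_halving_doubling_symmetry(self):
        p_half = salmon_effect_percent(-0.3, 0.5, fold=0.5)
        p_double = salmon_effect_percent(-0.3, 0.5, fold=2.0)
        assert (1 + p_half / 100.0) * (1 + p_double / 100.0) == pytest.approx(1.0)

    def test_monotone_decreasing_in_beta(self):
        vals = [salmon_effect_percent(b, 0.5, 0.5) for b in (-0.5, -0.3, 0.0, 0.3)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_ci_transform(self):
        pct, (lo, hi) = salmon_effect_percent(
            -0.3, 0.5, fold=0.5, beta_ci=(-0.5, -0.1)
        )
        assert lo < pct < hi

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            salmon_effect_percent(-0.3, 0.0)
        with pytest.raises(ValueError):
            salmon_effect_percent(-0.3, 0.5, fold=-1.0)


@pytest.fixture(scope="module")
def fitted():
    design, truth, _ = simulate_and_assemble(41, n_units=15, n_years=25)
    terms = tuple(design.annual_terms) + tuple(design.spatial_terms)
    fit = fit_nb2_glmm(design, terms, seed=1, n_starts=2)
    return design, fit


class TestResidualDiagnostics:

    def test_mean_pearson_near_zero(self, fitted):
        design, fit = fitted
        resid, _ = residual_diagnostics(fit, design)
        assert abs(resid["pearson"].mean()) < 0.15

    def test_white_noise_autocorr_centred(self, fitted):
        design, fit = fitted
        _, summary = residual_diagnostics(fit, design)
        assert abs(summary["lag1_autocorr"].mean()) < 0.25

    def test_injected_ar1_unit_flagged(self, fitted):
        design, fit = fitted
        data = design.data.copy()
        unit = data["unit_id"].iloc[0]
        rows = data["unit_id"] == unit
        n = rows.sum()
        # overwrite one unit's response with a strongly autocorrelated series
        ar = np.zeros(n)
        rng = np.random.default_rng(0)
        for i in range(1, n):
            ar[i] = 0.95 * ar[i - 1] + rng.normal(0, 0.3)
        # counts large enough that discreteness cannot mask the correlation
        data.loc[rows, "y"] = np.round(30.0 * np.exp(ar)).astype(int)
        contaminated = type(design)(
            data=data, annual_terms=design.annual_terms,
            spatial_terms=design.spatial_terms, mode=design.mode,
        )
        _, summary = residual_diagnostics(fit, contaminated)
        assert summary.set_index("unit_id").at[unit, "flagged"]
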