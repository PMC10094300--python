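"""Propensity models, stabilized weights, balance and positivity diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mobipw.synthetic import generate_cohort, make_kora_like_config
from mobipw.weighting import (
    BinaryPropensityWeighter,
    ContinuousGPSWeighter,
    PositivityError,
    PropensityFit,
    balance_report,
    design_matrix,
    fit_propensity_binary,
    positivity_diagnostics,
    stabilized_weights,
)


class TestBinaryPropensity:
    def test_independent_confounder_gives_marginal_probabilities(self, rng):
        n = 20_000
        x = pd.DataFrame({"x": (rng.random(n) < 0.5).astype(float)})
        e = (rng.random(n) < 0.3).astype(float)
        fit = BinaryPropensityWeighter().fit(x, e).fit_
        assert np.allclose(fit.conditional, e.mean(), atol=0.02)

    def test_deterministic_exposure_raises_separation_error(self):
        x = pd.DataFrame({"x": np.r_[np.zeros(50), np.ones(50)]})
        e = x["x"].to_numpy()
        with pytest.raises(PositivityError):
            BinaryPropensityWeighter().fit(x, e)

    def test_recovers_generator_assignment_coefficients(self):
        # exposure logit is linear in the confounders' numeric codes; the
        # propensity model is therefore correctly specified and should
        # recover each coefficient within 3 SE at n = 20000
        cfg = make_kora_like_config("quality", n=20_000, seed=21, truth="null")
        table = generate_cohort(cfg).table
        # every covariate entering the assignment model (a moderator with an
        # exposure effect must be included too, else omitted-variable
        # attenuation of the logistic coefficients)
        conf = [c.name for c in cfg.covariates if c.confounder_strength != 0.0]
        X = table.df[conf].astype(float)
        e = table.df["exposure"].to_numpy(float)
        import statsmodels.api as sm

        res = sm.Logit(e, sm.add_constant(X)).fit(disp=0)
        truth = {c.name: c.confounder_strength for c in cfg.covariates}
        zs = np.array([(res.params[n] - truth[n]) / res.bse[n] for n in conf])
        # 9 simultaneous 3-SE checks: allow one sampling excursion, bound all
        assert (np.abs(zs) < 3).sum() >= len(conf) - 1
        assert (np.abs(zs) < 4.2).all()


class TestContinuousGPS:
    def test_independence_limit_gives_unit_weights(self, rng):
        n = 5000
        x = pd.DataFrame({"x": rng.standard_normal(n)})
        e = 0.5 + 0.1 * rng.standard_normal(n)
        w = ContinuousGPSWeighter().fit(x, e)
        assert abs(w.weights_.mean() - 1) < 0.05
        assert np.quantile(np.abs(w.weights_ - 1), 0.9) < 0.25

    def test_conditional_density_matches_gaussian_oracle(self, rng):
        # e = a + b x + N(0, sigma^2): f(e|x) is N(a + b x, sigma^2), which a
        # residual KDE must approach at n = 20000
        n, a, b, sigma = 20_000, 0.4, 0.2, 0.08
        x = rng.standard_normal(n)
        e = a + b * x + rng.normal(0, sigma, n)
        fit = ContinuousGPSWeighter().fit(pd.DataFrame({"x": x}), e).fit_
        oracle = stats.norm.pdf(e, loc=a + b * x, scale=sigma)
        rel = fit.conditional / oracle
        inner = oracle > 0.05 * oracle.max()  # KDE tails are noisy by nature
        assert np.median(np.abs(rel[inner] - 1)) < 0.05

    def test_constant_exposure_raises(self):
        with pytest.raises(ValueError, match="constant"):
            ContinuousGPSWeighter().fit(pd.DataFrame({"x": [1.0, 2.0]}), np.array([0.5, 0.5]))


class TestStabilizedWeights:
    def test_conditional_equal_marginal_gives_exact_ones(self):
        e = np.array([1.0, 0.0, 1.0, 0.0])
        fit = PropensityFit("binary", conditional=np.array([0.5, 0.5, 0.5, 0.5]),
                            marginal=np.array([0.5, 0.5, 0.5, 0.5]), exposure=e,
                            coef=pd.Series(dtype=float))
        ws = stabilized_weights(fit, e)
        np.testing.assert_array_equal(ws.weights, np.ones(4))

    def test_single_record_arithmetic(self):
        # marginal exposure rate 0.3, exposed record with propensity 0.6 -> 0.5
        e = np.array([1.0])
        fit = PropensityFit("binary", conditional=np.array([0.6]),
                            marginal=np.array([0.3]), exposure=e, coef=pd.Series(dtype=float))
        assert stabilized_weights(fit, e).weights[0] == pytest.approx(0.5)

    def test_mean_weight_near_one_on_confounded_cohort(self):
        table = generate_cohort(make_kora_like_config("quality", n=2534, seed=5)).table
        X = design_matrix(table, table.confounders)
        w = BinaryPropensityWeighter().fit(X, table.df["exposure"].to_numpy(float))
        assert abs(w.weights_.mean() - 1.0) < 0.05

    def test_nonfinite_weight_lists_offenders(self):
        e = np.array([1.0, 0.0])
        fit = PropensityFit("binary", conditional=np.array([0.0, 0.5]),
                            marginal=np.array([0.5, 0.5]), exposure=e, coef=pd.Series(dtype=float))
        with pytest.raises(PositivityError, match="records"):
            stabilized_weights(fit, e)


class TestBalanceReport:
    def test_unit_weights_leave_after_equal_before(self, kora_cohort):
        table = kora_cohort.table
        rep = balance_report(table, np.ones(table.n))
        np.testing.assert_allclose(rep["before"], rep["after"], rtol=1e-12)

    def test_weighting_balances_confounded_cohort(self):
        table = generate_cohort(make_kora_like_config("quality", n=10_000, seed=6)).table
        e = table.df["exposure"].to_numpy(float)
        X = design_matrix(table, table.confounders)
        w = BinaryPropensityWeighter().fit(X, e)
        rep = balance_report(table, w.weights_, exposure=e)
        assert (rep["after"] < 0.1).all()
        # balance monotonicity for the truly confounding covariates
        strong = rep[rep["before"] > 0.1]
        assert (strong["after"] < strong["before"]).all()

    def test_independent_covariate_has_near_zero_smd(self, rng):
        n = 50_000
        df = pd.DataFrame({"x": rng.standard_normal(n), "e": (rng.random(n) < 0.3).astype(float)})
        rep = balance_report(df, np.ones(n), exposure=df["e"].to_numpy(), confounders=["x"])
        assert rep["before"].iloc[0] < 0.03

    def test_continuous_exposure_uses_weighted_correlation(self, rng):
        n = 20_000
        x = rng.standard_normal(n)
        e = 0.5 + 0.05 * x + 0.08 * rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "e": e})
        rep = balance_report(df, np.ones(n), exposure=e, confounders=["x"])
        assert rep["statistic"].iloc[0] == "correlation"
        assert rep["before"].iloc[0] == pytest.approx(abs(np.corrcoef(x, e)[0, 1]), abs=1e-9)

    def test_zero_variance_covariate_warns_and_reports_zero(self, rng):
        n = 200
        df = pd.DataFrame({"x": np.ones(n), "e": (rng.random(n) < 0.5).astype(float)})
        with pytest.warns(UserWarning, match="zero variance"):
            rep = balance_report(df, np.ones(n), exposure=df["e"].to_numpy(), confounders=["x"])
        assert rep["before"].iloc[0] == 0.0 and bool(rep["zero_variance"].iloc[0])


class TestPositivityDiagnostics:
    def _fit(self, e):
        return PropensityFit("binary", conditional=np.full(len(e), 0.5),
                             marginal=np.full(len(e), 0.5), exposure=e, coef=pd.Series(dtype=float))

    def test_unit_weights_do_not_flag(self):
        e = np.array([1.0, 0.0, 1.0, 0.0])
        out = positivity_diagnostics(self._fit(e), np.ones(4))
        assert out["weight_mean"] == 1.0 and not out["flag"]

    def test_extreme_weight_flags_at_cap(self):
        e = np.array([1.0, 0.0, 1.0, 0.0])
        out = positivity_diagnostics(self._fit(e), np.array([1.0, 1.0, 1.0, 50.0]), max_cap=20)
        assert out["flag"]

    def test_kora_cohort_raises_no_flag(self, kora_cohort):
        table = kora_cohort.table
        X = design_matrix(table, table.confounders)
        w = BinaryPropensityWeighter().fit(X, table.df["exposure"].to_numpy(float))
        out = positivity_diagnostics(w.fit_, w.weights_)
        assert not out["flag"]


def test_functional_wrapper_matches_estimator(kora_cohort):
    table = kora_cohort.table
    fit = fit_propensity_binary(table, table.confounders)
    est = BinaryPropensityWeighter().fit(
        design_matrix(table, table.confounders), table.df["exposure"].to_numpy(float)
    )
    np.testing.assert_allclose(fit.conditional, est.fit_.conditional)
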