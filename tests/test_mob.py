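"""Weighted logistic node model, instability tests, split search, tree growth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit

from mobipw.mob import (
    DegenerateModelError,
    MOBControls,
    MOBLogisticTree,
    fit_weighted_logistic,
    grow_tree,
    instability_test,
    search_split,
    select_split_variable,
    weighted_logistic,
)
from mobipw.scoretest import InstabilityResult
from mobipw.synthetic import generate_cohort, make_kora_like_config

counts = st.integers(min_value=5, max_value=2000)


def _arrays_from_2x2(a, b, c, d):
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    e = np.r_[np.ones(a + b), np.zeros(c + d)]
    return y, e


class TestWeightedLogisticFit:
    def test_saturated_fit_matches_printed_odds_ratio(self, table3_arrays):
        y, e = table3_arrays
        fit = fit_weighted_logistic(y, e)
        assert round(float(np.exp(fit.beta1)), 2) == 1.78
        # saturated 2-parameter fit equals the cross-product ratio exactly
        assert np.exp(fit.beta1) == pytest.approx((641 * 475) / (133 * 1285), abs=1e-8)

    @given(a=counts, b=counts, c=counts, d=counts)
    def test_model_se_equals_woolf_formula(self, a, b, c, d):
        y, e = _arrays_from_2x2(a, b, c, d)
        fit = fit_weighted_logistic(y, e)
        woolf = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert fit.se(robust=False)[1] == pytest.approx(woolf, rel=1e-6)

    def test_scores_sum_to_zero_at_optimum(self, table3_arrays):
        y, e = table3_arrays
        fit = fit_weighted_logistic(y, e, np.linspace(0.5, 2.0, len(y)))
        assert np.abs(fit.scores.sum(axis=0)).max() < 1e-6

    def test_constant_exposure_rejected(self):
        with pytest.raises(DegenerateModelError, match="constant"):
            fit_weighted_logistic(np.array([0, 1, 0, 1]), np.ones(4))

    def test_single_outcome_class_rejected(self):
        with pytest.raises(DegenerateModelError, match="single value"):
            fit_weighted_logistic(np.ones(4), np.array([0, 1, 0, 1]))

    def test_matches_statsmodels_freq_weight_glm(self, rng):
        import statsmodels.api as sm

        n = 400
        e = (rng.random(n) < 0.4).astype(float)
        y = (rng.random(n) < expit(0.3 + 0.5 * e)).astype(float)
        w = rng.integers(1, 5, n).astype(float)  # integer frequency weights
        fit = fit_weighted_logistic(y, e, w)
        X = sm.add_constant(pd.DataFrame({"e": e}))
        res = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit()
        np.testing.assert_allclose(fit.beta, res.params.to_numpy(), rtol=1e-6)
        np.testing.assert_allclose(fit.loglik, res.llf, rtol=1e-8)
        np.testing.assert_allclose(fit.se(robust=False), res.bse.to_numpy(), rtol=1e-5)

    def test_separation_reported_as_nonconverged(self):
        e = np.r_[np.zeros(60), np.ones(60)]
        y = e.copy()
        y[:3] = 1  # nearly separated
        y[-3:] = 0
        fit = fit_weighted_logistic(y, e)
        assert np.isfinite(fit.loglik)


class TestInstabilityTest:
    def test_signal_covariate_detected(self, rng):
        # moderator flipping the sign of beta1 between halves -> tiny p
        n = 2000
        z = np.repeat([0.0, 1.0], n // 2)
        e = (rng.random(n) < 0.4).astype(float)
        beta1 = np.where(z == 0, 0.9, -0.9)
        y = (rng.random(n) < expit(0.4 + beta1 * e)).astype(float)
        fit = fit_weighted_logistic(y, e)
        res = instability_test(fit, z, covariate="z", kind="binary")
        assert res.p_value < 1e-4

    def test_continuous_null_p_value_not_extreme(self, rng):
        n = 2000
        e = (rng.random(n) < 0.3).astype(float)
        y = (rng.random(n) < expit(0.8 + 0.4 * e)).astype(float)
        fit = fit_weighted_logistic(y, e)
        res = instability_test(fit, rng.standard_normal(n), kind="continuous")
        assert res.kind == "suplm" and 0.0 < res.p_value <= 1.0

    def test_constant_moderator_rejected(self, rng):
        n = 200
        e = (rng.random(n) < 0.5).astype(float)
        y = (rng.random(n) < 0.6).astype(float)
        fit = fit_weighted_logistic(y, e)
        with pytest.raises(ValueError, match="constant"):
            instability_test(fit, np.ones(n), kind="ordinal")

    def test_binary_moderator_reduces_to_chi_square(self, rng):
        # a single cut point: the max-LM and the nominal chi-square statistic
        # coincide, and the p-value is the exact chi-square(2) tail
        from scipy import stats

        n = 1000
        z = (rng.random(n) < 0.4).astype(float)
        e = (rng.random(n) < 0.4).astype(float)
        y = (rng.random(n) < expit(0.5 + 0.3 * e)).astype(float)
        fit = fit_weighted_logistic(y, e)
        r_ord = instability_test(fit, z, kind="binary")
        r_nom = instability_test(fit, z.astype(int).astype(str), kind="nominal")
        assert r_ord.statistic == pytest.approx(r_nom.statistic, rel=1e-8)
        assert r_ord.p_value == pytest.approx(stats.chi2.sf(r_ord.statistic, 2), rel=1e-10)


class TestSelectSplitVariable:
    def _res(self, name, p):
        return InstabilityResult(name, 1.0, p, "chisq", 2, 1)

    def test_no_rejection_when_all_adjusted_p_above_alpha(self):
        out = select_split_variable([self._res("a", 0.05), self._res("b", 0.2)])
        assert out is None

    def test_smallest_adjusted_p_wins(self):
        results = [self._res("a", 0.2), self._res("b", 0.001), self._res("c", 0.01)]
        out = select_split_variable(results)
        assert out.covariate == "b" and out.p_adjusted == pytest.approx(0.003)

    def test_bonferroni_multiplies_by_candidate_count(self):
        results = [self._res(f"v{i}", 0.01 if i == 0 else 0.9) for i in range(40)]
        out = select_split_variable(results)
        assert out is None  # 0.01 * 40 = 0.4 > 0.05
        assert results[0].p_adjusted == pytest.approx(0.4)

    def test_ties_broken_by_input_order(self):
        results = [self._res("first", 0.001), self._res("second", 0.001)]
        out = select_split_variable(results, MOBControls(bonferroni=False))
        assert out.covariate == "first"


class TestSearchSplit:
    def test_binary_moderator_has_single_partition(self, rng):
        n = 400
        z = np.repeat([0, 1], n // 2)
        e = np.tile([0.0, 1.0], n // 2)
        y = (rng.random(n) < expit(0.2 + 0.4 * e + 0.8 * z)).astype(float)
        split, _ = search_split(y, e, None, z, "ordered", minsize=50)
        assert split.threshold == 0.0

    def test_minsize_blocks_unbalanced_partition(self, rng):
        n = 300
        z = np.r_[np.zeros(20), np.ones(280)]
        e = np.tile([0.0, 1.0], n // 2)
        y = (rng.random(n) < 0.6).astype(float)
        assert search_split(y, e, None, z, "ordered", minsize=50) is None

    def test_planted_likert_threshold_recovered(self, rng):
        # parameter change between ordered levels 2 and 3 (1-based) of a
        # 5-level moderator -> recovered threshold at code 1 (0-based)
        n = 4000
        z = rng.integers(0, 5, n).astype(float)
        e = (rng.random(n) < 0.4).astype(float)
        beta0 = np.where(z <= 1, 0.2, 1.2)
        y = (rng.random(n) < expit(beta0 + 0.3 * e)).astype(float)
        split, _ = search_split(y, e, None, z, "ordered", minsize=100)
        assert split.threshold == 1.0

    def test_nominal_search_matches_brute_force_oracle(self, rng):
        # exhaustive oracle over all 7 binary partitions of 4 levels
        from itertools import combinations

        n = 400
        z = np.array([f"l{i}" for i in rng.integers(0, 4, n)])
        e = (rng.random(n) < 0.5).astype(float)
        shift = np.isin(z, ["l1", "l3"]) * 1.2
        y = (rng.random(n) < expit(-0.4 + 0.5 * e + shift)).astype(float)

        def oracle():
            levels = ["l0", "l1", "l2", "l3"]
            best, best_ll = None, -np.inf
            seen = set()
            for r in range(1, 4):
                for sub in combinations(levels, r):
                    key = frozenset(sub)
                    if key in seen or frozenset(set(levels) - set(sub)) in seen:
                        continue
                    seen.add(key)
                    mask = np.isin(z, sub)
                    if mask.sum() < 30 or (~mask).sum() < 30:
                        continue
                    ll = (fit_weighted_logistic(y[mask], e[mask]).loglik
                          + fit_weighted_logistic(y[~mask], e[~mask]).loglik)
                    if ll > best_ll:
                        best, best_ll = key, ll
            return best, best_ll

        split, ll = search_split(y, e, None, z, "nominal", minsize=30)
        oracle_set, oracle_ll = oracle()
        got = frozenset(split.left_levels)
        assert got == oracle_set or got == frozenset({"l0", "l1", "l2", "l3"}) - oracle_set
        assert ll == pytest.approx(oracle_ll, abs=1e-6)


class TestGrowTree:
    def test_maxdepth_one_gives_at_most_two_terminals(self, kora_cohort):
        table = kora_cohort.table
        tree = grow_tree(table, "good_health", "exposure",
                         moderators=table.moderators, controls=MOBControls(maxdepth=1))
        assert len(tree.terminal_nodes_) <= 2

    def test_structure_invariants(self, kora_cohort):
        table = kora_cohort.table
        tree = grow_tree(table, "good_health", "exposure", moderators=table.moderators)
        for node in tree.nodes_:
            assert node.n >= 100
            assert node.depth <= 3
            if not node.is_terminal:
                left, right = node.children
                # children partition the parent's records exactly
                merged = np.sort(np.concatenate([left.indices, right.indices]))
                np.testing.assert_array_equal(merged, np.sort(node.indices))
                # likelihood gain: parent's parameters are feasible in both children
                assert left.fit.loglik + right.fit.loglik >= node.fit.loglik - 1e-6

    def test_saturated_node_or_equals_cross_product_ratio(self, kora_cohort):
        table = kora_cohort.table
        df = table.df
        tree = grow_tree(table, "good_health", "exposure", moderators=table.moderators)
        y = df["good_health"].to_numpy(float)
        e = df["exposure"].to_numpy(float)
        for node in tree.terminal_nodes_:
            yy, ee = y[node.indices], e[node.indices]
            a = np.sum((yy == 1) & (ee == 1))
            b = np.sum((yy == 0) & (ee == 1))
            c = np.sum((yy == 1) & (ee == 0))
            d = np.sum((yy == 0) & (ee == 0))
            assert np.exp(node.fit.beta1) == pytest.approx((a * d) / (b * c), abs=1e-8)

    def test_apply_routes_records_to_their_training_nodes(self, kora_cohort):
        table = kora_cohort.table
        tree = grow_tree(table, "good_health", "exposure", moderators=table.moderators)
        ids = tree.apply(table.df)
        for node in tree.terminal_nodes_:
            assert (ids[node.indices] == node.id).all()

    def test_missing_values_rejected(self, kora_cohort):
        df = kora_cohort.table.df.copy()
        df.loc[0, "school_education"] = np.nan
        est = MOBLogisticTree(exposure="exposure", moderators=["school_education"])
        with pytest.raises(ValueError, match="complete cases"):
            est.fit(df, df["good_health"].to_numpy(float))

    def test_degenerate_root_raises(self):
        df = pd.DataFrame({"exposure": [0.0, 1.0] * 60, "z": [0, 1] * 60})
        est = MOBLogisticTree(exposure="exposure", moderators=["z"])
        with pytest.raises(DegenerateModelError):
            est.fit(df, np.ones(120))

    def test_deterministic_given_table(self, kora_cohort):
        table = kora_cohort.table
        t1 = grow_tree(table, "good_health", "exposure", moderators=table.moderators)
        t2 = grow_tree(table, "good_health", "exposure", moderators=table.moderators)
        assert t1.to_dict() == t2.to_dict()

    def test_sklearn_params_round_trip(self):
        est = MOBLogisticTree(alpha=0.01, minsize=50)
        params = est.get_params()
        assert params["alpha"] == 0.01
        clone = MOBLogisticTree(**params)
        assert clone.get_params() == params


def test_general_weighted_logistic_recovers_interaction(rng):
    n = 5000
    e = (rng.random(n) < 0.4).astype(float)
    g = (rng.random(n) < 0.5).astype(float)
    y = (rng.random(n) < expit(0.2 + 0.7 * e - 0.6 * e * g)).astype(float)
    X = np.column_stack([np.ones(n), e, g, e * g])
    fit = weighted_logistic(X, y)
    assert abs(fit.beta[3] + 0.6) < 3.5 * fit.se(robust=False)[3]
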