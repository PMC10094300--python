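"""Stabilized inverse-probability weighting and balance diagnostics.

Binary exposures: propensity scores e(X) = P(E=1 | X) from a maximum-
likelihood logistic regression on the confounders; stabilized weight
sw = P(E=e_i) / P(E=e_i | X_i) with the marginal probability taken from the
raw sample.

Continuous exposures: generalized propensity scores.  The exposure is
modelled linearly in the confounders; the conditional density f(E_i | X_i)
is a Gaussian kernel density estimate of the residuals evaluated at record
i's residual, the marginal density f(E_i) a KDE of the exposure itself
(Silverman bandwidth for both); sw = f(E_i) / f(E_i | X_i).

Balance diagnostics: absolute standardized mean differences (binary
exposure; denominator = unweighted pooled SD, computed once, so before/after
share a scale) or absolute weighted exposure-covariate Pearson correlations
(continuous exposure), with the conventional 0.1 threshold.  Categorical
confounders are expanded to one indicator per level (reference included).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator

from .cohort import CohortError, CohortTable

__all__ = [
    "PositivityError",
    "PropensityFit",
    "WeightSet",
    "BinaryPropensityWeighter",
    "ContinuousGPSWeighter",
    "fit_propensity_binary",
    "fit_gps_continuous",
    "stabilized_weights",
    "balance_report",
    "positivity_diagnostics",
    "design_matrix",
    "love_plot",
]

BALANCE_THRESHOLD = 0.1


class PositivityError(RuntimeError):
    """Positivity / overlap violation (e.g., perfect separation of exposure)."""


@dataclass
class PropensityFit:
    kind: str                   # binary | continuous
    conditional: np.ndarray     # e_i = P(E=1|X) (binary) or f(E_i|X_i) (continuous)
    marginal: np.ndarray        # P(E=e_i) or f(E_i), per record
    exposure: np.ndarray
    coef: pd.Series
    bandwidth_conditional: float | None = None
    bandwidth_marginal: float | None = None


@dataclass
class WeightSet:
    weights: np.ndarray
    summary: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(self.weights.mean())

    @property
    def max(self) -> float:
        return float(self.weights.max())

    @property
    def min(self) -> float:
        return float(self.weights.min())


def _frame(table) -> pd.DataFrame:
    return table.df if isinstance(table, CohortTable) else table


def _kinds(table, columns) -> dict[str, str]:
    if isinstance(table, CohortTable):
        return {c: table.schema[c].kind for c in columns if c in table.schema}
    df = _frame(table)
    return {
        c: ("nominal" if not pd.api.types.is_numeric_dtype(df[c]) else "continuous")
        for c in columns
    }


def design_matrix(table, columns: list[str]) -> pd.DataFrame:
    """Numeric design: binary/ordinal/continuous as-is, nominal as dummies."""
    df = _frame(table)
    kinds = _kinds(table, columns)
    parts = []
    for c in columns:
        if kinds.get(c) == "nominal":
            d = pd.get_dummies(df[c].astype(str), prefix=c, drop_first=True, dtype=float)
            parts.append(d)
        else:
            parts.append(df[[c]].astype(float))
    X = pd.concat(parts, axis=1)
    if X.isna().any().any():
        raise CohortError("confounders contain missing values; filter complete cases first")
    return X


def _expanded_balance_columns(table, columns: list[str]) -> pd.DataFrame:
    """Per-level indicators for categorical confounders (reference included)."""
    df = _frame(table)
    kinds = _kinds(table, columns)
    parts = []
    for c in columns:
        if kinds.get(c) in ("nominal", "ordinal", "binary"):
            parts.append(pd.get_dummies(df[c], prefix=c, drop_first=False, dtype=float))
        else:
            parts.append(df[[c]].astype(float))
    return pd.concat(parts, axis=1)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class BinaryPropensityWeighter(BaseEstimator):
    """Logistic propensity model + stabilized inverse-probability weights.

    ``fit(X, e)`` takes the confounder design (DataFrame) and the binary
    exposure; fitted attributes: ``propensity_``, ``coef_``, ``weights_``,
    ``fit_`` (the full :class:`PropensityFit`), ``weight_set_``.
    """

    def __init__(self, add_intercept: bool = True):
        self.add_intercept = add_intercept

    def fit(self, X: pd.DataFrame, e) -> "BinaryPropensityWeighter":
        e = np.asarray(e, dtype=float)
        if not set(np.unique(e)) <= {0.0, 1.0}:
            raise ValueError("binary exposure must be coded 0/1")
        if e.min() == e.max():
            raise PositivityError("exposure is constant; no propensity model")
        Xd = X.astype(float)
        design = sm.add_constant(Xd, has_constant="add") if self.add_intercept else Xd
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(e, design).fit(disp=0, maxiter=200)
            except Exception as exc:  # statsmodels PerfectSeparation & friends
                raise PositivityError(
                    "propensity model failed (likely perfect separation); "
                    f"review the confounder list: {exc}"
                ) from exc
        if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 30:
            raise PositivityError(
                "propensity model did not converge / separated exposure groups; "
                "review the confounder list (positivity violation)"
            )
        ps = np.asarray(res.predict(design))
        p_marg = float(e.mean())
        marginal = np.where(e == 1, p_marg, 1 - p_marg)
        self.fit_ = PropensityFit("binary", ps, marginal, e, pd.Series(res.params))
        self.propensity_ = ps
        self.coef_ = res.params
        self.weight_set_ = stabilized_weights(self.fit_, e)
        self.weights_ = self.weight_set_.weights
        return self


class ContinuousGPSWeighter(BaseEstimator):
    """Generalized propensity scores for a continuous exposure.

    Linear exposure model + Gaussian KDE (Silverman bandwidth) of residuals
    (conditional density) and of the exposure (marginal density).
    """

    def __init__(self, bw_method: str = "silverman", add_intercept: bool = True):
        self.bw_method = bw_method
        self.add_intercept = add_intercept

    def fit(self, X: pd.DataFrame, e) -> "ContinuousGPSWeighter":
        e = np.asarray(e, dtype=float)
        if np.ptp(e) == 0:
            raise ValueError("exposure is constant; density undefined")
        Xd = X.astype(float)
        design = sm.add_constant(Xd, has_constant="add") if self.add_intercept else Xd
        res = sm.OLS(e, design).fit()
        resid = np.asarray(res.resid)
        if resid.std() < 1e-12:
            raise ValueError("zero residual variance; conditional density degenerate")
        kde_resid = gaussian_kde(resid, bw_method=self.bw_method)
        kde_marg = gaussian_kde(e, bw_method=self.bw_method)
        conditional = kde_resid(resid)
        marginal = kde_marg(e)
        self.fit_ = PropensityFit(
            "continuous", conditional, marginal, e, pd.Series(res.params),
            bandwidth_conditional=float(kde_resid.factor * resid.std(ddof=1)),
            bandwidth_marginal=float(kde_marg.factor * e.std(ddof=1)),
        )
        self.coef_ = res.params
        self.weight_set_ = stabilized_weights(self.fit_, e)
        self.weights_ = self.weight_set_.weights
        return self


# ---------------------------------------------------------------------------
# functional wrappers (spec operations)
# ---------------------------------------------------------------------------

def fit_propensity_binary(table, confounders: list[str]) -> PropensityFit:
    df = _frame(table)
    exposure = table.exposure_col if isinstance(table, CohortTable) else "exposure"
    X = design_matrix(table, confounders)
    return BinaryPropensityWeighter().fit(X, df[exposure].to_numpy()).fit_


def fit_gps_continuous(table, confounders: list[str]) -> PropensityFit:
    df = _frame(table)
    exposure = table.exposure_col if isinstance(table, CohortTable) else "exposure"
    X = design_matrix(table, confounders)
    return ContinuousGPSWeighter().fit(X, df[exposure].to_numpy()).fit_


def stabilized_weights(fit: PropensityFit, exposure) -> WeightSet:
    """sw_i = marginal / conditional for the record's observed exposure."""
    e = np.asarray(exposure, dtype=float)
    if fit.kind == "binary":
        cond = np.where(e == 1, fit.conditional, 1 - fit.conditional)
    else:
        cond = fit.conditional
    with np.errstate(divide="ignore", invalid="ignore"):
        sw = fit.marginal / cond
    bad = ~np.isfinite(sw) | (sw <= 0)
    if bad.any():
        raise PositivityError(
            f"non-finite or non-positive stabilized weights for records "
            f"{np.flatnonzero(bad)[:10].tolist()}"
        )
    ws = WeightSet(sw)
    ws.summary = {"mean": ws.mean, "max": ws.max, "min": ws.min, "n": len(sw)}
    return ws


def _weighted_mean(x, w):
    return float(np.average(x, weights=w))


def _weighted_corr(x, e, w):
    mx, me = _weighted_mean(x, w), _weighted_mean(e, w)
    cov = np.average((x - mx) * (e - me), weights=w)
    vx = np.average((x - mx) ** 2, weights=w)
    ve = np.average((e - me) ** 2, weights=w)
    if vx <= 0 or ve <= 0:
        return 0.0
    return float(cov / np.sqrt(vx * ve))


def balance_report(
    table, weights, exposure=None, confounders: list[str] | None = None,
    threshold: float = BALANCE_THRESHOLD,
) -> pd.DataFrame:
    """Before/after covariate balance, one row per expanded confounder term.

    Binary exposure: absolute (weighted) standardized mean difference with an
    unweighted pooled-SD denominator.  Continuous exposure: absolute
    (weighted) exposure-covariate Pearson correlation.
    """
    df = _frame(table)
    if confounders is None:
        confounders = table.confounders
    if exposure is None:
        exposure = df[table.exposure_col].to_numpy(dtype=float)
    else:
        exposure = np.asarray(exposure, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    ones = np.ones(len(df))
    binary_exposure = set(np.unique(exposure)) <= {0.0, 1.0}
    expanded = _expanded_balance_columns(table, confounders)

    rows = []
    for name in expanded.columns:
        x = expanded[name].to_numpy(dtype=float)
        zero_var = bool(np.ptp(x) == 0)
        if zero_var:
            warnings.warn(f"covariate term {name!r} has zero variance; balance set to 0")
            before = after = 0.0
        elif binary_exposure:
            m1, m0 = exposure == 1, exposure == 0
            sd_pool = np.sqrt((x[m1].var(ddof=1) + x[m0].var(ddof=1)) / 2)
            if sd_pool == 0:
                before = after = 0.0
                zero_var = True
            else:
                before = abs(x[m1].mean() - x[m0].mean()) / sd_pool
                after = abs(
                    _weighted_mean(x[m1], w[m1]) - _weighted_mean(x[m0], w[m0])
                ) / sd_pool
        else:
            before = abs(_weighted_corr(x, exposure, ones))
            after = abs(_weighted_corr(x, exposure, w))
        rows.append({
            "covariate": name,
            "statistic": "smd" if binary_exposure else "correlation",
            "before": float(before),
            "after": float(after),
            "balanced": bool(after < threshold),
            "zero_variance": zero_var,
        })
    return pd.DataFrame(rows)


def positivity_diagnostics(
    fit: PropensityFit, weights: WeightSet | np.ndarray,
    mean_tolerance: float = 0.1, max_cap: float = 20.0,
) -> dict:
    """Weight extremes and propensity overlap; flags suspected violations."""
    w = weights.weights if isinstance(weights, WeightSet) else np.asarray(weights, dtype=float)
    out = {
        "weight_mean": float(w.mean()),
        "weight_max": float(w.max()),
        "weight_min": float(w.min()),
        "mean_tolerance": mean_tolerance,
        "max_cap": max_cap,
    }
    if fit.kind == "binary":
        e = fit.exposure
        qs = [0.0, 0.05, 0.25, 0.5, 0.75, 0.95, 1.0]
        out["propensity_quantiles_exposed"] = np.quantile(fit.conditional[e == 1], qs).tolist()
        out["propensity_quantiles_unexposed"] = np.quantile(fit.conditional[e == 0], qs).tolist()
    out["flag"] = bool(abs(out["weight_mean"] - 1.0) > mean_tolerance or out["weight_max"] > max_cap)
    return out


def love_plot(report: pd.DataFrame, path=None, threshold: float = BALANCE_THRESHOLD):
    """Dot plot of before/after balance statistics (optional figure output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = report.iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(rep) + 1.5))
    ypos = np.arange(len(rep))
    ax.scatter(rep["before"], ypos, label="before", marker="o", color="#c44e52")
    ax.scatter(rep["after"], ypos, label="after", marker="s", color="#4c72b0")
    ax.axvline(threshold, color="grey", ls="--", lw=1)
    ax.set_yticks(ypos, rep["covariate"])
    ax.set_xlabel(f"absolute {rep['statistic'].iloc[0]}")
    ax.legend(loc="lower right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
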