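"""Per-subgroup effect estimates and the heterogeneity-vs-prevalence step.

For every terminal node of a grown tree: odds ratio exp(beta1) with a
robust (sandwich) Wald confidence interval, weighted good-outcome prevalence,
and — for binary exposures — the risk difference P[Y=1|E=1] - P[Y=1|E=0]
with a seeded percentile-bootstrap confidence interval (default B = 2000).
For continuous exposures the OR is rescaled to a stated exposure increment
(default 0.1 units, matching the NDVI reporting convention).

Sibling subgroups are then classified by Wald contrasts on the two model
parameters: does the split reflect *slope heterogeneity* (different exposure
effects), only a *prevalence difference* (different intercepts), both, or
neither.  An informal CI-overlap report is attached alongside the formal
contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mob import MOBLogisticTree, NodeFit

__all__ = [
    "NodeEffect",
    "SplitClassification",
    "node_effects",
    "effects_table",
    "rescale_or",
    "bootstrap_rd",
    "classify_split",
    "classification_table",
]


@dataclass
class NodeEffect:
    node_id: int
    n: int
    weight_sum: float
    prevalence: float                  # weighted share of good outcomes
    odds_ratio: float
    ci_low: float
    ci_high: float
    beta0: float
    beta1: float
    converged: bool
    rescaled_delta: float | None = None
    p_good_exposed: float | None = None    # binary exposure only
    p_good_unexposed: float | None = None
    risk_difference: float | None = None
    rd_ci_low: float | None = None
    rd_ci_high: float | None = None
    bootstrap_b: int | None = None
    bootstrap_failed: int | None = None


@dataclass
class SplitClassification:
    node_id: int
    left_id: int
    right_id: int
    variable: str
    z_intercept: float
    z_slope: float
    p_intercept: float
    p_slope: float
    label: str                         # slope heterogeneity | prevalence difference | both | neither
    ci_overlap_intercept: bool | None = None
    ci_overlap_slope: bool | None = None


def rescale_or(beta1: float, delta: float = 0.1) -> float:
    """Odds ratio per ``delta``-unit exposure increment: exp(delta * beta1)."""
    return float(np.exp(delta * beta1))


def _ci_log_scale(beta1: float, se: float, level: float, delta: float = 1.0):
    z = stats.norm.ppf(0.5 + level / 2)
    return (
        float(np.exp(delta * (beta1 - z * se))),
        float(np.exp(delta * (beta1 + z * se))),
    )


def bootstrap_rd(
    outcome, exposure, weights=None, n_boot: int = 2000, seed: int | None = 0,
    level: float = 0.95, max_retries: int = 100,
) -> dict:
    """Weighted risk difference with a seeded percentile-bootstrap CI.

    Records are resampled with replacement within the node (weights carried
    along); replicates in which an exposure arm vanishes are redrawn up to
    ``max_retries`` times each, then counted in ``failed``.
    """
    y = np.asarray(outcome, dtype=float)
    e = np.asarray(exposure, dtype=float)
    n = len(y)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if not ((e == 1).any() and (e == 0).any()):
        raise ValueError("both exposure arms must be present in the node")

    def rd_of(idx):
        ww, yy, ee = w[idx], y[idx], e[idx]
        s1 = np.sum(ww * ee)
        s0 = np.sum(ww * (1 - ee))
        if s1 == 0 or s0 == 0:
            return None
        return np.sum(ww * yy * ee) / s1 - np.sum(ww * yy * (1 - ee)) / s0

    point = rd_of(np.arange(n))
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    failed = 0
    for b in range(n_boot):
        val = None
        for _ in range(max_retries):
            val = rd_of(rng.integers(0, n, n))
            if val is not None:
                break
        if val is None:
            failed += 1
            val = np.nan
        reps[b] = val
    lo, hi = np.nanpercentile(reps, [100 * (0.5 - level / 2), 100 * (0.5 + level / 2)])
    return {
        "rd": float(point),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_boot": n_boot,
        "failed": failed,
    }


def node_effects(
    tree: MOBLogisticTree, outcome, weights=None, level: float = 0.95,
    exposure_values=None, rescale_delta: float | None = None,
    bootstrap: bool = True, n_boot: int = 2000, seed: int | None = 0,
) -> list[NodeEffect]:
    """Effect estimates for every terminal node of a grown tree.

    ``outcome`` / ``exposure_values`` / ``weights`` are the full-cohort arrays
    the tree was fitted on (node membership comes from the stored indices).
    ``rescale_delta`` switches on OR rescaling for continuous exposures;
    ``bootstrap`` adds risk differences for binary exposures.
    """
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    e_all = exposure_values
    effects = []
    for node in tree.terminal_nodes_:
        fit: NodeFit = node.fit
        se1 = fit.se(robust=True)[1]
        delta = rescale_delta if rescale_delta is not None else 1.0
        or_ = float(np.exp(delta * fit.beta1))
        if fit.converged and np.isfinite(se1):
            lo, hi = _ci_log_scale(fit.beta1, se1, level, delta)
        else:
            lo = hi = float("nan")
        yy = y[node.indices]
        ww = w[node.indices]
        eff = NodeEffect(
            node_id=node.id, n=node.n, weight_sum=fit.weight_sum,
            prevalence=float(np.average(yy, weights=ww)),
            odds_ratio=or_, ci_low=lo, ci_high=hi,
            beta0=fit.beta0, beta1=fit.beta1, converged=fit.converged,
            rescaled_delta=rescale_delta,
        )
        if e_all is not None:
            ee = np.asarray(e_all, dtype=float)[node.indices]
            if set(np.unique(ee)) <= {0.0, 1.0} and (ee == 1).any() and (ee == 0).any():
                s1, s0 = np.sum(ww * ee), np.sum(ww * (1 - ee))
                eff.p_good_exposed = float(np.sum(ww * yy * ee) / s1)
                eff.p_good_unexposed = float(np.sum(ww * yy * (1 - ee)) / s0)
                if bootstrap:
                    node_seed = None if seed is None else (int(seed) + node.id) % (2**31 - 1)
                    rd = bootstrap_rd(yy, ee, ww, n_boot=n_boot, seed=node_seed, level=level)
                    eff.risk_difference = rd["rd"]
                    eff.rd_ci_low = rd["ci_low"]
                    eff.rd_ci_high = rd["ci_high"]
                    eff.bootstrap_b = rd["n_boot"]
                    eff.bootstrap_failed = rd["failed"]
                else:
                    eff.risk_difference = eff.p_good_exposed - eff.p_good_unexposed
        effects.append(eff)
    return effects


def effects_table(effects: list[NodeEffect]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in effects])


def classify_split(
    fit_a: NodeFit, fit_b: NodeFit, level: float = 0.95,
    node_id: int = 0, left_id: int = 0, right_id: int = 0, variable: str = "",
) -> SplitClassification:
    """Wald contrasts between two sibling fits on (intercept, slope).

    z_j = (beta_j^a - beta_j^b) / sqrt(se_a^2 + se_b^2) with robust SEs; the
    label reads off which contrasts are significant at ``level``.
    """
    se_a, se_b = fit_a.se(robust=True), fit_b.se(robust=True)
    if not (np.isfinite(se_a).all() and np.isfinite(se_b).all()):
        raise ValueError("missing/invalid robust covariance; split unclassifiable")
    zs = (fit_a.beta - fit_b.beta) / np.sqrt(se_a**2 + se_b**2)
    ps = 2 * stats.norm.sf(np.abs(zs))
    alpha = 1 - level
    sig0, sig1 = ps[0] < alpha, ps[1] < alpha
    label = {
        (True, True): "both",
        (False, True): "slope heterogeneity",
        (True, False): "prevalence difference",
        (False, False): "neither",
    }[(bool(sig0), bool(sig1))]
    zcrit = stats.norm.ppf(0.5 + level / 2)

    def overlap(j):
        a_lo, a_hi = fit_a.beta[j] - zcrit * se_a[j], fit_a.beta[j] + zcrit * se_a[j]
        b_lo, b_hi = fit_b.beta[j] - zcrit * se_b[j], fit_b.beta[j] + zcrit * se_b[j]
        return bool(a_lo <= b_hi and b_lo <= a_hi)

    return SplitClassification(
        node_id=node_id, left_id=left_id, right_id=right_id, variable=variable,
        z_intercept=float(zs[0]), z_slope=float(zs[1]),
        p_intercept=float(ps[0]), p_slope=float(ps[1]), label=label,
        ci_overlap_intercept=overlap(0), ci_overlap_slope=overlap(1),
    )


def classification_table(tree: MOBLogisticTree, level: float = 0.95) -> pd.DataFrame:
    """Classify every executed split by its children's parameter contrasts."""
    rows = []
    for node in tree.nodes_:
        if node.is_terminal:
            continue
        left, right = node.children
        try:
            c = classify_split(
                left.fit, right.fit, level=level, node_id=node.id,
                left_id=left.id, right_id=right.id, variable=node.split.variable,
            )
        except ValueError:
            continue
        rows.append(vars(c))
    return pd.DataFrame(rows)
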