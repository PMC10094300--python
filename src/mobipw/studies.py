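"""Reproducible simulation studies that characterize the method.

Each function runs a seeded Monte-Carlo experiment on the synthetic cohort
generator and returns the summary quantities of interest:

* :func:`root_only_rate` — calibration of the tree's stopping rule: under a
  generator with a single (beta0, beta1) everywhere, how often does the tree
  stay root-only?
* :func:`split_recovery` — with the default planted depth-2 truth (leaf odds
  ratios 2.66 vs 0.91), how often are the planted split covariates recovered
  on the correct branch?
* :func:`ipw_debias` — with a null conditional exposure effect and strong
  confounding, does the unweighted odds ratio exclude 1 while the stabilized-
  weighted robust CI covers 1?  Plus the post-weighting balance check.
* :func:`suplm_calibration` — null rejection rate of the continuum supLM
  instability test at nominal alpha.

Problem sizes default to the study scale (n = 2534) with replicate counts
chosen so each experiment completes in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import expit

from .mob import MOBControls, MOBLogisticTree, fit_weighted_logistic, instability_test
from .synthetic import generate_cohort, make_kora_like_config
from .weighting import BinaryPropensityWeighter, balance_report, design_matrix

__all__ = ["root_only_rate", "split_recovery", "ipw_debias", "suplm_calibration"]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _fit_tree(table, controls: MOBControls, weights=None) -> MOBLogisticTree:
    est = MOBLogisticTree(
        exposure=table.exposure_col, moderators=table.moderators,
        kinds={c: m.kind for c, m in table.schema.items()},
        alpha=controls.alpha, minsize=controls.minsize, maxdepth=controls.maxdepth,
        bonferroni=controls.bonferroni, trim=controls.trim,
    )
    y = table.df[table.outcome_col].to_numpy(dtype=float)
    return est.fit(table.df, y, sample_weight=weights)


def root_only_rate(n_reps: int = 200, n: int = 2534, seed: int = 0,
                   exposure_kind: str = "quality") -> dict:
    """Share of replicates whose tree stays root-only under a constant truth."""
    controls = MOBControls()
    root_only = 0
    for s in _child_seeds(seed, n_reps):
        cfg = make_kora_like_config(exposure_kind, n=n, seed=int(s), truth="constant")
        tree = _fit_tree(generate_cohort(cfg).table, controls)
        root_only += int(len(tree.nodes_) == 1)
    return {"rate": root_only / n_reps, "n_reps": n_reps, "n": n}


def split_recovery(n_reps: int = 100, n: int = 2534, seed: int = 0,
                   exposure_kind: str = "quality") -> dict:
    """Recovery of the planted splits: discrimination covariate at the root,
    education covariate splitting the non-discriminated branch."""
    controls = MOBControls()
    D, S = "discrimination_disability", "school_education"
    root_hits = joint_hits = 0
    for s in _child_seeds(seed, n_reps):
        cfg = make_kora_like_config(exposure_kind, n=n, seed=int(s), truth="planted")
        table = generate_cohort(cfg).table
        tree = _fit_tree(table, controls)
        root = tree.tree_
        if root.split is None or root.split.variable != D:
            continue
        root_hits += 1
        # the child holding the D == 0 records (planted education split lives there)
        dvals = table.df[D].to_numpy()
        branch = next(
            (c for c in root.children if np.all(dvals[c.indices] == 0)), None
        )
        if branch is None:
            continue

        def subtree_splits(node):
            if node.split is not None:
                yield node.split.variable
                for ch in node.children:
                    yield from subtree_splits(ch)

        if S in set(subtree_splits(branch)):
            joint_hits += 1
    return {
        "rate": joint_hits / n_reps,
        "root_rate": root_hits / n_reps,
        "n_reps": n_reps,
        "n": n,
    }


def ipw_debias(n_reps: int = 200, n: int = 2534, seed: int = 0,
               smd_n: int = 10_000, level: float = 0.95,
               confounding_scale: float = 2.0) -> dict:
    """Null conditional effect + strong confounding: bias of the unweighted
    odds ratio and coverage of 1 by the stabilized-weighted robust CI; plus
    post-weighting standardized mean differences at a large n."""
    z = stats.norm.ppf(0.5 + level / 2)
    unweighted_excludes = weighted_covers = 0
    for s in _child_seeds(seed, n_reps):
        cfg = make_kora_like_config("quality", n=n, seed=int(s), truth="null",
                                    confounding_scale=confounding_scale)
        table = generate_cohort(cfg).table
        df = table.df
        y = df[table.outcome_col].to_numpy(dtype=float)
        e = df[table.exposure_col].to_numpy(dtype=float)
        raw = fit_weighted_logistic(y, e)
        se_raw = raw.se(robust=True)[1]
        if abs(raw.beta1) > z * se_raw:
            unweighted_excludes += 1
        X = design_matrix(table, table.confounders)
        sw = BinaryPropensityWeighter().fit(X, e).weights_
        wfit = fit_weighted_logistic(y, e, sw)
        se_w = wfit.se(robust=True)[1]
        if abs(wfit.beta1) <= z * se_w:
            weighted_covers += 1

    cfg = make_kora_like_config("quality", n=smd_n, seed=seed, truth="null",
                                confounding_scale=confounding_scale)
    table = generate_cohort(cfg).table
    e = table.df[table.exposure_col].to_numpy(dtype=float)
    X = design_matrix(table, table.confounders)
    w = BinaryPropensityWeighter().fit(X, e)
    rep = balance_report(table, w.weights_, exposure=e)
    return {
        "unweighted_excludes_rate": unweighted_excludes / n_reps,
        "weighted_covers_rate": weighted_covers / n_reps,
        "n_reps": n_reps,
        "n": n,
        "max_post_smd": float(rep["after"].max()),
        "max_pre_smd": float(rep["before"].max()),
        "all_balanced": bool((rep["after"] < 0.1).all()),
        "smd_n": smd_n,
        "weight_mean": float(w.weights_.mean()),
    }


def suplm_calibration(n_reps: int = 500, n: int = 2000, seed: int = 0,
                      alpha: float = 0.05) -> dict:
    """Null rejection rate of the continuum supLM test with a continuous
    moderator unrelated to the model parameters."""
    rng = np.random.default_rng(seed)
    controls = MOBControls()
    rejections = 0
    for _ in range(n_reps):
        e = (rng.random(n) < 0.3).astype(float)
        y = (rng.random(n) < expit(0.8 + 0.4 * e)).astype(float)
        zc = rng.standard_normal(n)
        fit = fit_weighted_logistic(y, e)
        res = instability_test(fit, zc, covariate="z", kind="continuous", controls=controls)
        rejections += int(res.p_value < alpha)
    return {"rate": rejections / n_reps, "n_reps": n_reps, "n": n, "alpha": alpha}
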