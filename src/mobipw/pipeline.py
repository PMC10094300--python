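"""End-to-end orchestration: generate/load -> preprocess -> weight -> tree -> infer.

Also houses the desk-scale comparison analyses: the 2x2 contingency-table
odds ratio (cross-product with a Woolf log-scale CI) and the weighted
exposure-by-group interaction likelihood-ratio test used for the
binary-sex/gender comparison analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .cohort import CohortError, CohortTable
from .inference import classification_table, effects_table, node_effects
from .mob import MOBControls, MOBLogisticTree, fit_weighted_logistic, weighted_logistic
from .preprocess import complete_case_filter
from .synthetic import GeneratorConfig, generate_cohort
from .weighting import (
    BinaryPropensityWeighter,
    ContinuousGPSWeighter,
    balance_report,
    design_matrix,
    positivity_diagnostics,
)

log = logging.getLogger("mobipw")

__all__ = [
    "ContingencyTable2x2",
    "or_from_2x2",
    "weighted_interaction_lrt",
    "RunConfig",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# 2x2 contingency table
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable2x2:
    """Counts: a = exposed/good, b = exposed/bad, c = unexposed/good, d = unexposed/bad."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"count {name} must be a nonnegative integer, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def or_from_2x2(t: ContingencyTable2x2, level: float = 0.95) -> dict:
    """Cross-product odds ratio (a*d)/(b*c) with the Woolf log-scale CI."""
    if min(t.a, t.b, t.c, t.d) == 0:
        raise ValueError("zero cell; odds ratio undefined (no continuity correction applied)")
    or_ = (t.a * t.d) / (t.b * t.c)
    se = np.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    z = stats.norm.ppf(0.5 + level / 2)
    return {
        "odds_ratio": float(or_),
        "ci_low": float(np.exp(np.log(or_) - z * se)),
        "ci_high": float(np.exp(np.log(or_) + z * se)),
        "se_log": float(se),
        "p_bad_exposed": 100.0 * t.b / (t.a + t.b),
        "p_bad_unexposed": 100.0 * t.d / (t.c + t.d),
    }


# ---------------------------------------------------------------------------
# weighted interaction LRT
# ---------------------------------------------------------------------------

def weighted_interaction_lrt(outcome, exposure, group, weights=None, level: float = 0.95) -> dict:
    """Weighted LRT for an exposure-by-group interaction in the logistic model.

    Compares logit P(Y=1) = b0 + b1 E + b2 G against the model with an extra
    b3 E*G term; reports 2 * delta(weighted log-likelihood) against
    chi-square(1), a robust Wald z for the interaction coefficient (the
    weighted LRT is only approximately calibrated under IPW), and stratified
    ORs with robust CIs per group level.
    """
    y = np.asarray(outcome, dtype=float)
    e = np.asarray(exposure, dtype=float)
    g = np.asarray(group, dtype=float)
    n = len(y)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if len(np.unique(g)) != 2:
        raise ValueError("group must be binary")
    ones = np.ones(n)
    X0 = np.column_stack([ones, e, g])
    X1 = np.column_stack([ones, e, g, e * g])
    f0 = weighted_logistic(X0, y, w)
    f1 = weighted_logistic(X1, y, w)
    lr = 2 * (f1.loglik - f0.loglik)
    z_int = f1.beta[3] / f1.se(robust=True)[3]
    zcrit = stats.norm.ppf(0.5 + level / 2)
    by_group = {}
    for lvl in np.unique(g):
        m = g == lvl
        fit = fit_weighted_logistic(y[m], e[m], w[m])
        se1 = fit.se(robust=True)[1]
        by_group[float(lvl)] = {
            "n": int(m.sum()),
            "odds_ratio": float(np.exp(fit.beta1)),
            "ci_low": float(np.exp(fit.beta1 - zcrit * se1)),
            "ci_high": float(np.exp(fit.beta1 + zcrit * se1)),
        }
    return {
        "lr_statistic": float(lr),
        "p_value": float(stats.chi2.sf(lr, 1)),
        "wald_z_interaction": float(z_int),
        "wald_p_interaction": float(2 * stats.norm.sf(abs(z_int))),
        "or_by_group": by_group,
    }


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One end-to-end analysis run (one exposure per run)."""

    input_csv: str | None = None                 # cohort CSV (+ .schema.json sidecar)
    generator: GeneratorConfig | None = None     # or: simulate the cohort
    outcome: str | None = None                   # default: schema outcome column
    exposure: str | None = None
    confounders: list[str] | None = None
    moderators: list[str] | None = None
    controls: MOBControls = field(default_factory=MOBControls)
    ci_level: float = 0.95
    n_boot: int = 2000
    rescale_delta: float | None = None           # continuous exposure OR increment
    seed: int = 0
    outdir: str = "mobipw_run"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("generator") is not None and not isinstance(d["generator"], GeneratorConfig):
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        if d.get("controls") is not None and not isinstance(d["controls"], MOBControls):
            d["controls"] = MOBControls(**d["controls"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.generator is not None:
            d["generator"] = self.generator.to_dict()
        d["controls"] = vars(self.controls)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; write every artifact plus a hashed run manifest.

    Rerunning with the same config (and seed) reproduces every output file,
    including the bootstrap intervals.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_path = None

    # --- stage: input -----------------------------------------------------
    if (config.input_csv is None) == (config.generator is None):
        raise CohortError("config must set exactly one of input_csv / generator")
    if config.generator is not None:
        gen_cfg = config.generator
        gen_cfg.seed = config.seed
        log.info("generating cohort (n=%d, seed=%d)", gen_cfg.n, config.seed)
        gen = generate_cohort(gen_cfg)
        table = gen.table
        truth_path = outdir / "truth.json"
        truth_path.write_text(json.dumps({
            "subgroups": [
                {"name": s.name, "beta0": s.beta0, "beta1": s.beta1,
                 "conditions": [vars(c) for c in s.conditions]}
                for s in gen.truth.subgroups
            ],
            "sizes": np.bincount(gen.subgroup).tolist(),
        }, indent=1))
    else:
        table = CohortTable.read(config.input_csv)

    outcome = config.outcome or table.outcome_col
    exposure = config.exposure or table.exposure_col
    confounders = config.confounders if config.confounders is not None else table.confounders
    moderators = config.moderators if config.moderators is not None else table.moderators
    for col in [outcome, exposure] + confounders + moderators:
        if col not in table.df.columns:
            raise CohortError(f"config references missing column {col!r}")
    clash = {exposure} & (set(moderators) | set(confounders))
    if clash:
        raise CohortError(f"exposure {exposure!r} cannot also be a moderator/confounder")

    # --- stage: preprocess ------------------------------------------------
    table, report = complete_case_filter(table, [outcome, exposure] + confounders + moderators)
    (outdir / "exclusion_report.json").write_text(json.dumps(report.to_dict(), indent=1))
    log.info("complete cases: %d of %d (%.1f%%)", report.n_retained, report.n_initial,
             report.retained_pct)
    df = table.df
    binary_exposure = table.schema[exposure].kind == "binary"

    # --- stage: weighting -------------------------------------------------
    X = design_matrix(table, confounders)
    e = df[exposure].to_numpy(dtype=float)
    weighter = (BinaryPropensityWeighter() if binary_exposure else ContinuousGPSWeighter())
    weighter.fit(X, e)
    sw = weighter.weights_
    snapshot = df.copy()
    snapshot["stabilized_weight"] = sw
    snapshot.to_csv(outdir / "cohort_weighted.csv", index=False)
    table.write(outdir / "cohort.csv")
    balance = balance_report(table, sw, exposure=e, confounders=confounders)
    balance.to_csv(outdir / "balance.csv", index=False)
    positivity = positivity_diagnostics(weighter.fit_, sw)
    (outdir / "positivity.json").write_text(json.dumps(positivity, indent=1))

    # --- stage: tree ------------------------------------------------------
    ctl = config.controls
    tree = MOBLogisticTree(
        exposure=exposure, moderators=moderators,
        kinds={c: m.kind for c, m in table.schema.items()},
        alpha=ctl.alpha, minsize=ctl.minsize, maxdepth=ctl.maxdepth,
        bonferroni=ctl.bonferroni, trim=ctl.trim,
        max_nominal_levels=ctl.max_nominal_levels, robust=ctl.robust,
    )
    y = df[outcome].to_numpy(dtype=float)
    tree.fit(df, y, sample_weight=sw)
    tree.to_json(outdir / "tree.json")
    (outdir / "tree.txt").write_text(tree.format_tree() + "\n")
    tree.membership_frame(df).to_csv(outdir / "node_membership.csv", index=False)

    # --- stage: inference -------------------------------------------------
    delta = config.rescale_delta if not binary_exposure else None
    if delta is None and not binary_exposure:
        delta = 0.1
    effects = node_effects(
        tree, y, weights=sw, level=config.ci_level, exposure_values=e,
        rescale_delta=delta, bootstrap=binary_exposure,
        n_boot=config.n_boot, seed=config.seed,
    )
    eff_df = effects_table(effects)
    eff_df.to_csv(outdir / "effects.csv", index=False)
    cls_df = classification_table(tree, level=config.ci_level)
    cls_df.to_csv(outdir / "classification.csv", index=False)

    # --- manifest ---------------------------------------------------------
    outputs = sorted(p for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_complete_cases": int(len(df)),
        "exposure_kind": "binary" if binary_exposure else "continuous",
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return {
        "table": table,
        "weights": sw,
        "balance": balance,
        "positivity": positivity,
        "tree": tree,
        "effects": eff_df,
        "classification": cls_df,
        "exclusion": report,
        "manifest": manifest,
        "truth_file": str(truth_path) if truth_path else None,
    }
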