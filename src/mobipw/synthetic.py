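"""Seeded synthetic cohort generator with planted subgroup structure.

The generator emulates the statistical shape of a population-based survey
cohort linked to neighbourhood green-space exposure: a binary good/bad
self-rated-health outcome, one exposure per run (binary access/greenness
indicator or a continuous NDVI-like greenness value), a small set of
socio-demographic confounders that drive exposure assignment, and a battery
of ~40 mixed-type candidate moderator covariates.  A *planted truth* — a
shallow, mutually exclusive and exhaustive partition of the covariate space
with subgroup-specific logistic intercepts and exposure slopes — governs the
outcome model, so tree-recovery and calibration experiments have a known
ground truth.

Outcome model (conditional, logistic link) for a record in true subgroup g:

    logit P(Y=1) = beta0(g) + beta1(g) * E + sum_j outcome_strength_j * X_j

Exposure model: logistic in the confounders (binary exposure) or linear with
Gaussian noise clamped to a stated range (continuous exposure).

Random streams are split per column from the master seed, so adding or
removing one covariate never perturbs the draws of the others.
"""

from __future__ import annotations

import copy
import json
import zlib
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import CohortError, CohortTable, ColumnMeta

__all__ = [
    "CovariateSpec",
    "Condition",
    "Subgroup",
    "PlantedTruth",
    "ExposureModel",
    "GeneratorConfig",
    "GeneratedCohort",
    "generate_cohort",
    "make_kora_like_config",
    "inject_missing",
]

_CALIBRATION_SEED = 987_654_321  # internal quasi-sample used to tune intercepts
_CALIBRATION_N = 40_000


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass
class CovariateSpec:
    """One generated covariate.

    ``probs`` is the marginal probability vector for binary/ordinal/nominal
    kinds (binary: probability of level 1 may be given as a single float);
    ``mean``/``sd`` parameterize continuous covariates.  ``confounder_strength``
    is the covariate's additive contribution (per numeric code / per unit) to
    the exposure-assignment linear predictor; ``outcome_strength`` its
    contribution to the outcome log-odds.
    """

    name: str
    kind: str  # binary | ordinal | nominal | continuous
    probs: list[float] | None = None
    mean: float | None = None
    sd: float | None = None
    confounder_strength: float = 0.0
    outcome_strength: float = 0.0
    role: str = "moderator"  # moderator | confounder | other

    def __post_init__(self):
        if self.kind not in ("binary", "ordinal", "nominal", "continuous"):
            raise CohortError(f"covariate {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "continuous":
            if self.mean is None or self.sd is None or self.sd <= 0:
                raise CohortError(f"covariate {self.name!r}: continuous kind needs mean and sd > 0")
        else:
            if self.kind == "binary" and isinstance(self.probs, float):
                self.probs = [1.0 - self.probs, self.probs]
            if self.probs is None:
                raise CohortError(f"covariate {self.name!r}: categorical kind needs probs")
            p = np.asarray(self.probs, dtype=float)
            if p.ndim != 1 or len(p) < 2:
                raise CohortError(f"covariate {self.name!r}: need k >= 2 levels")
            if self.kind == "binary" and len(p) != 2:
                raise CohortError(f"covariate {self.name!r}: binary kind needs exactly 2 levels")
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
                raise CohortError(
                    f"covariate {self.name!r}: probs must be nonnegative and sum to 1 within 1e-12"
                )

    @property
    def n_levels(self) -> int:
        return 0 if self.kind == "continuous" else len(self.probs)


@dataclass
class Condition:
    """Atomic covariate condition; ops: eq, le, ge, in."""

    covariate: str
    op: str
    value: object

    def __post_init__(self):
        if self.op not in ("eq", "le", "ge", "in"):
            raise CohortError(f"condition on {self.covariate!r}: unknown op {self.op!r}")

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        col = df[self.covariate]
        if self.op == "eq":
            return (col == self.value).to_numpy()
        if self.op == "le":
            return (col <= self.value).to_numpy()
        if self.op == "ge":
            return (col >= self.value).to_numpy()
        return col.isin(list(self.value)).to_numpy()


@dataclass
class Subgroup:
    name: str
    conditions: list[Condition]
    beta0: float
    beta1: float

    def __post_init__(self):
        if len(self.conditions) > 3:
            raise CohortError(f"subgroup {self.name!r}: conjunction depth must be <= 3")

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(df), dtype=bool)
        for c in self.conditions:
            m &= c.mask(df)
        return m


@dataclass
class PlantedTruth:
    """True partition and per-subgroup (beta0, beta1) of the outcome model."""

    subgroups: list[Subgroup]

    def __post_init__(self):
        if not self.subgroups:
            raise CohortError("truth: needs at least one subgroup")

    def assign(self, df: pd.DataFrame) -> np.ndarray:
        """Subgroup index per record; errors unless the partition is a partition."""
        masks = np.stack([g.mask(df) for g in self.subgroups])
        hits = masks.sum(axis=0)
        if (hits != 1).any():
            bad = int(np.flatnonzero(hits != 1)[0])
            raise CohortError(
                f"truth: subgroups are not mutually exclusive and exhaustive "
                f"(record {bad} matches {int(hits[bad])} subgroups)"
            )
        return masks.argmax(axis=0)

    def shifted(self, delta0: float) -> "PlantedTruth":
        return PlantedTruth(
            [Subgroup(g.name, g.conditions, g.beta0 + delta0, g.beta1) for g in self.subgroups]
        )


@dataclass
class ExposureModel:
    """Confounded exposure-assignment model.

    binary:     E ~ Bernoulli(expit(intercept + sum_j strength_j X_j))
    continuous: E = clamp(intercept + sum_j strength_j X_j + N(0, noise_sd))

    Per-covariate strengths live on :class:`CovariateSpec.confounder_strength`.
    """

    kind: str  # binary | continuous
    intercept: float = 0.0
    noise_sd: float | None = None
    clamp: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind not in ("binary", "continuous"):
            raise CohortError(f"exposure_model.kind: unknown kind {self.kind!r}")
        if self.kind == "continuous":
            if self.noise_sd is None or self.noise_sd <= 0:
                raise CohortError("exposure_model.noise_sd: must be > 0 for continuous exposure")
            if self.clamp is not None and not self.clamp[0] < self.clamp[1]:
                raise CohortError("exposure_model.clamp: bounds must be ordered")


@dataclass
class GeneratorConfig:
    n: int
    covariates: list[CovariateSpec]
    exposure_model: ExposureModel
    truth: PlantedTruth
    exposure_name: str = "exposure"
    outcome_name: str = "good_health"
    missing_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise CohortError("config.n: must be >= 1")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise CohortError("config.covariates: duplicate covariate names")
        for col, r in self.missing_rates.items():
            if not 0.0 <= r <= 1.0:
                raise CohortError(f"config.missing_rates[{col!r}]: rate must be in [0, 1]")
        known = set(names) | {self.exposure_name, self.outcome_name}
        for g in self.truth.subgroups:
            for c in g.conditions:
                if c.covariate not in known:
                    raise CohortError(f"config.truth: unknown covariate {c.covariate!r}")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["exposure_model"]["clamp"] = (
            list(self.exposure_model.clamp) if self.exposure_model.clamp else None
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        covs = [CovariateSpec(**c) for c in d["covariates"]]
        em = dict(d["exposure_model"])
        if em.get("clamp") is not None:
            em["clamp"] = tuple(em["clamp"])
        truth = PlantedTruth(
            [
                Subgroup(
                    g["name"],
                    [Condition(**c) for c in g["conditions"]],
                    g["beta0"],
                    g["beta1"],
                )
                for g in d["truth"]["subgroups"]
            ]
        )
        return cls(
            n=d["n"],
            covariates=covs,
            exposure_model=ExposureModel(**em),
            truth=truth,
            exposure_name=d.get("exposure_name", "exposure"),
            outcome_name=d.get("outcome_name", "good_health"),
            missing_rates=d.get("missing_rates", {}),
            seed=d.get("seed", 0),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class GeneratedCohort:
    table: CohortTable
    truth: PlantedTruth
    subgroup: np.ndarray  # true subgroup index per record


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _rng_for(seed: int, stream: str) -> np.random.Generator:
    """Independent per-column stream: master seed + CRC32 of the stream name."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stream.encode())]))


def _draw_covariate(spec: CovariateSpec, n: int, rng: np.random.Generator) -> np.ndarray | pd.Series:
    if spec.kind == "continuous":
        return rng.normal(spec.mean, spec.sd, size=n)
    codes = rng.choice(spec.n_levels, size=n, p=np.asarray(spec.probs, dtype=float))
    if spec.kind == "nominal":
        return pd.Series([f"l{c}" for c in codes], dtype=str)
    return codes.astype(np.int64)


def _numeric_codes(values, spec: CovariateSpec) -> np.ndarray:
    """Numeric representation used in the exposure/outcome linear predictors."""
    if spec.kind == "nominal":
        # nominal levels contribute through their integer code; unordered for
        # the analysis but a convenient scalar channel for data generation
        return np.asarray([int(v[1:]) for v in values], dtype=float)
    return np.asarray(values, dtype=float)


def _linear_predictors(df: pd.DataFrame, covariates: list[CovariateSpec]):
    eta_e = np.zeros(len(df))
    eta_y = np.zeros(len(df))
    for spec in covariates:
        if spec.confounder_strength == 0.0 and spec.outcome_strength == 0.0:
            continue
        x = _numeric_codes(df[spec.name].to_numpy(), spec)
        eta_e += spec.confounder_strength * x
        eta_y += spec.outcome_strength * x
    return eta_e, eta_y


def generate_cohort(config: GeneratorConfig) -> GeneratedCohort:
    """Draw one cohort; identical configs (incl. seed) give identical tables."""
    config.validate()
    n, seed = config.n, config.seed

    data: dict[str, object] = {}
    for spec in config.covariates:
        data[spec.name] = _draw_covariate(spec, n, _rng_for(seed, f"cov:{spec.name}"))
    df = pd.DataFrame(data)

    eta_e, eta_y = _linear_predictors(df, config.covariates)

    em = config.exposure_model
    if em.kind == "binary":
        p = expit(em.intercept + eta_e)
        e = (_rng_for(seed, "exposure").random(n) < p).astype(np.int64)
    else:
        e = em.intercept + eta_e + _rng_for(seed, "exposure").normal(0.0, em.noise_sd, size=n)
        if em.clamp is not None:
            e = np.clip(e, em.clamp[0], em.clamp[1])
    df[config.exposure_name] = e

    g = config.truth.assign(df)
    beta0 = np.array([s.beta0 for s in config.truth.subgroups])[g]
    beta1 = np.array([s.beta1 for s in config.truth.subgroups])[g]
    p_y = expit(beta0 + beta1 * np.asarray(e, dtype=float) + eta_y)
    y = (_rng_for(seed, "outcome").random(n) < p_y).astype(np.int64)
    df[config.outcome_name] = y

    schema = {}
    for spec in config.covariates:
        levels = None if spec.kind == "continuous" else (
            [f"l{i}" for i in range(spec.n_levels)] if spec.kind == "nominal"
            else list(range(spec.n_levels))
        )
        schema[spec.name] = ColumnMeta(spec.role, spec.kind, levels)
    schema[config.exposure_name] = ColumnMeta(
        "exposure", "binary" if em.kind == "binary" else "continuous",
        [0, 1] if em.kind == "binary" else None,
    )
    schema[config.outcome_name] = ColumnMeta("outcome", "binary", [0, 1])

    table = CohortTable(df, schema)
    if any(r > 0 for r in config.missing_rates.values()):
        table = inject_missing(table, config.missing_rates, seed)
    return GeneratedCohort(table, config.truth, g)


def inject_missing(table: CohortTable, missing_rates: dict[str, float], seed: int) -> CohortTable:
    """Independently blank each cell with its column's rate (seeded)."""
    df = table.df.copy()
    for col, rate in missing_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise CohortError(f"missing rate for {col!r} must be in [0, 1], got {rate}")
        if rate == 0.0:
            continue
        mask = _rng_for(seed, f"missing:{col}").random(len(df)) < rate
        if df[col].dtype.kind in "iu":
            df[col] = df[col].astype(float)
        df.loc[mask, col] = np.nan
    return table.copy_with(df)


# ---------------------------------------------------------------------------
# named default configurations
# ---------------------------------------------------------------------------

def _confounder_battery(strength: float = 1.0) -> list[CovariateSpec]:
    """Eight study-style confounders; ``strength`` scales exposure+outcome effects."""
    s = strength
    return [
        CovariateSpec("age", "continuous", mean=62.7, sd=8.9,
                      confounder_strength=-0.015 * s, outcome_strength=-0.020 * s, role="confounder"),
        CovariateSpec("financial_situation", "ordinal", probs=[0.06, 0.20, 0.47, 0.27],
                      confounder_strength=0.35 * s, outcome_strength=0.30 * s, role="confounder"),
        CovariateSpec("home_owner", "binary", probs=[0.38, 0.62],
                      confounder_strength=0.35 * s, outcome_strength=0.20 * s, role="confounder"),
        CovariateSpec("urbanization", "ordinal", probs=[0.36, 0.43, 0.21],
                      confounder_strength=0.25 * s, outcome_strength=0.0, role="confounder"),
        CovariateSpec("vocational_education", "ordinal", probs=[0.25, 0.45, 0.30],
                      confounder_strength=0.15 * s, outcome_strength=0.10 * s, role="confounder"),
        CovariateSpec("employed", "binary", probs=[0.52, 0.48],
                      confounder_strength=0.10 * s, outcome_strength=0.10 * s, role="confounder"),
        CovariateSpec("partner_household", "binary", probs=[0.28, 0.72],
                      confounder_strength=0.05 * s, outcome_strength=0.15 * s, role="confounder"),
        CovariateSpec("discrimination_ethnicity", "binary", probs=[0.92, 0.08],
                      confounder_strength=-0.40 * s, outcome_strength=-0.50 * s, role="confounder"),
    ]


def _null_moderator_battery() -> list[CovariateSpec]:
    """38 null moderators: mixed binary / Likert-type ordinal / nominal kinds."""
    mods: list[CovariateSpec] = []
    binary_ps = [0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50, 0.55, 0.60, 0.65, 0.70, 0.52]
    for i, p in enumerate(binary_ps):
        mods.append(CovariateSpec(f"mod_bin_{i:02d}", "binary", probs=[1 - p, p]))
    likert5 = [
        [0.30, 0.30, 0.20, 0.15, 0.05],
        [0.10, 0.20, 0.30, 0.25, 0.15],
        [0.05, 0.15, 0.25, 0.30, 0.25],
        [0.40, 0.25, 0.15, 0.12, 0.08],
        [0.20, 0.20, 0.20, 0.20, 0.20],
        [0.15, 0.25, 0.35, 0.15, 0.10],
        [0.08, 0.12, 0.20, 0.30, 0.30],
        [0.25, 0.35, 0.20, 0.12, 0.08],
        [0.12, 0.18, 0.30, 0.25, 0.15],
        [0.33, 0.27, 0.20, 0.13, 0.07],
        [0.06, 0.14, 0.28, 0.32, 0.20],
        [0.22, 0.28, 0.26, 0.16, 0.08],
    ]
    for i, p in enumerate(likert5):
        mods.append(CovariateSpec(f"mod_likert_{i:02d}", "ordinal", probs=p))
    ordinal4 = [
        [0.10, 0.25, 0.40, 0.25],
        [0.30, 0.30, 0.25, 0.15],
        [0.18, 0.32, 0.32, 0.18],
        [0.45, 0.30, 0.15, 0.10],
        [0.08, 0.22, 0.42, 0.28],
        [0.26, 0.24, 0.26, 0.24],
    ]
    for i, p in enumerate(ordinal4):
        mods.append(CovariateSpec(f"mod_ord4_{i:02d}", "ordinal", probs=p))
    nominal = [
        [0.40, 0.35, 0.25],
        [0.20, 0.30, 0.50],
        [0.25, 0.25, 0.25, 0.25],
        [0.50, 0.20, 0.18, 0.12],
        [0.34, 0.33, 0.33],
        [0.15, 0.35, 0.30, 0.20],
    ]
    for i, p in enumerate(nominal):
        mods.append(CovariateSpec(f"mod_nom_{i:02d}", "nominal", probs=p))
    assert len(mods) == 38
    return mods


def _planted_moderators() -> list[CovariateSpec]:
    return [
        CovariateSpec("discrimination_disability", "binary", probs=[0.85, 0.15],
                      confounder_strength=-0.25),
        CovariateSpec("school_education", "ordinal", probs=[0.45, 0.30, 0.25]),
    ]


def _default_truth(exposure_kind: str) -> PlantedTruth:
    """Depth-2 planted partition: one intercept-contrast leaf (discrimination)
    and an education split carrying the slope contrast (leaf ORs 2.66 vs 0.91
    for binary exposure; per-0.1-unit ORs 1.35 vs 0.95 for continuous)."""
    if exposure_kind == "binary":
        b1 = (np.log(1.3), np.log(2.66), np.log(0.91))
    else:
        b1 = (10 * np.log(1.05), 10 * np.log(1.35), 10 * np.log(0.95))
    D, S = "discrimination_disability", "school_education"
    return PlantedTruth([
        Subgroup("discriminated", [Condition(D, "eq", 1)], float(logit(0.52)), float(b1[0])),
        Subgroup("basic_education", [Condition(D, "eq", 0), Condition(S, "le", 0)],
                 float(logit(0.68)), float(b1[1])),
        Subgroup("higher_education", [Condition(D, "eq", 0), Condition(S, "ge", 1)],
                 float(logit(0.78)), float(b1[2])),
    ])


def _constant_truth(beta0: float, beta1: float) -> PlantedTruth:
    return PlantedTruth([Subgroup("all", [], beta0, beta1)])


_KORA_TARGETS = {
    # exposure_kind -> (model kind, marginal target(s))
    "quality": ("binary", 774 / 2534),
    "greenness": ("binary", 2008 / 2534),
    "ndvi_300m": ("continuous", (0.47, 0.09, (0.16, 0.73))),
    "ndvi_1000m": ("continuous", (0.50, 0.09, (0.27, 0.71))),
}


def _calibration_frame(covariates: list[CovariateSpec]) -> pd.DataFrame:
    data = {}
    for spec in covariates:
        rng = _rng_for(_CALIBRATION_SEED, f"cov:{spec.name}")
        data[spec.name] = _draw_covariate(spec, _CALIBRATION_N, rng)
    return pd.DataFrame(data)


def make_kora_like_config(
    exposure_kind: str,
    n: int = 2534,
    seed: int = 0,
    truth: str = "planted",
    confounding_scale: float = 1.0,
    beta1_constant: float | None = None,
) -> GeneratorConfig:
    """Named default configuration matching the study's printed marginals.

    See :func:`_make_kora_like_parts` for the calibration details; the
    calibrated parts are cached across calls (they do not depend on ``n`` or
    ``seed``) and deep-copied into each returned config.
    """
    covariates, em, planted = _kora_parts_cached(
        exposure_kind, truth, confounding_scale, beta1_constant
    )
    return GeneratorConfig(
        n=n,
        covariates=copy.deepcopy(covariates),
        exposure_model=copy.deepcopy(em),
        truth=copy.deepcopy(planted),
        exposure_name="exposure",
        outcome_name="good_health",
        seed=seed,
    )


@lru_cache(maxsize=32)
def _kora_parts_cached(exposure_kind, truth, confounding_scale, beta1_constant):
    return _make_kora_like_parts(exposure_kind, truth, confounding_scale, beta1_constant)


def _make_kora_like_parts(
    exposure_kind: str,
    truth: str = "planted",
    confounding_scale: float = 1.0,
    beta1_constant: float | None = None,
):
    """Calibrated building blocks of the survey-like default configuration.

    ``exposure_kind``: one of ``quality`` (binary, prevalence 0.305),
    ``greenness`` (binary, 0.792), ``ndvi_300m`` / ``ndvi_1000m`` (continuous,
    mean 0.47 / 0.50, SD 0.09, clamped to the printed min/max).

    ``truth``: ``planted`` (default depth-2 partition), ``constant`` (single
    (beta0, beta1) everywhere — no parameter instability), or ``null``
    (constant with beta1 = 0, for weighting-debias experiments).

    Intercepts (exposure model, and a common outcome log-odds offset) are
    calibrated numerically on a fixed internal quasi-sample so that the
    generated marginals hit the targets: exposure prevalence / mean-SD per
    kind, and a marginal good-outcome rate of 0.76.
    """
    if exposure_kind not in _KORA_TARGETS:
        raise CohortError(
            f"unknown exposure_kind {exposure_kind!r}; expected one of {sorted(_KORA_TARGETS)}"
        )
    model_kind, target = _KORA_TARGETS[exposure_kind]

    covariates = _confounder_battery(confounding_scale) + _planted_moderators() + _null_moderator_battery()
    if model_kind == "continuous":
        # exposure-model contributions switch from log-odds to NDVI units;
        # 0.07 maps the battery to a confounder-driven exposure SD near 0.03
        # (about a tenth of the exposure variance), leaving room for noise
        for spec in covariates:
            spec.confounder_strength *= 0.07

    if truth == "planted":
        planted = _default_truth(model_kind)
    elif truth == "constant":
        b1 = beta1_constant if beta1_constant is not None else (
            np.log(1.38) if model_kind == "binary" else 10 * np.log(1.05))
        planted = _constant_truth(float(logit(0.76)), float(b1))
    elif truth == "null":
        planted = _constant_truth(float(logit(0.76)), 0.0)
    else:
        raise CohortError(f"unknown truth kind {truth!r}")

    cal = _calibration_frame(covariates)
    eta_e, eta_y = _linear_predictors(cal, covariates)

    if model_kind == "binary":
        prevalence = float(target)

        def gap(b):
            return expit(b + eta_e).mean() - prevalence

        intercept = brentq(gap, -15, 15, xtol=1e-10)
        em = ExposureModel("binary", intercept=float(intercept))
        rng = _rng_for(_CALIBRATION_SEED, "exposure")
        e_cal = (rng.random(_CALIBRATION_N) < expit(intercept + eta_e)).astype(float)
    else:
        mean_t, sd_t, clamp = target
        var_eta = float(np.var(eta_e))
        if var_eta >= sd_t**2:
            raise CohortError("confounder contributions exceed the target exposure variance")
        noise_sd = float(np.sqrt(sd_t**2 - var_eta))
        intercept = float(mean_t - eta_e.mean())
        em = ExposureModel("continuous", intercept=intercept, noise_sd=noise_sd, clamp=clamp)
        rng = _rng_for(_CALIBRATION_SEED, "exposure")
        e_cal = np.clip(intercept + eta_e + rng.normal(0, noise_sd, _CALIBRATION_N), *clamp)

    # common outcome offset -> marginal good rate 0.76
    cal_e = cal.copy()
    cal_e["exposure"] = e_cal
    g = planted.assign(cal_e)
    beta0 = np.array([s.beta0 for s in planted.subgroups])[g]
    beta1 = np.array([s.beta1 for s in planted.subgroups])[g]
    base = beta0 + beta1 * e_cal + eta_y

    def ygap(d):
        return expit(base + d).mean() - 0.76

    delta0 = brentq(ygap, -10, 10, xtol=1e-10)

    return covariates, em, planted.shifted(float(delta0))
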