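"""Derivation of analysis variables: dichotomizations and complete-case filtering.

The recodes follow the study's rules exactly:

* five-level self-rated health -> binary good (very good, good) vs bad
  (moderate, bad, very bad);
* access to high-quality public green space -> positive only when the
  participant reports access AND rates the spaces as high quality AND as well
  maintained ("strongly agree" on both five-point items); everyone else,
  including participants without access, is negative;
* four-level neighbourhood greenness -> very green vs less green (the three
  lower categories combined).

Level labels are matched case-insensitively after trimming whitespace.
Missing values in any source item propagate to a missing derived value (the
analysis is complete-case; no imputation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortError, CohortTable, ColumnMeta

__all__ = [
    "HEALTH_LEVELS",
    "AGREEMENT_LEVELS",
    "GREENNESS_LEVELS",
    "ExclusionReport",
    "dichotomize_outcome",
    "derive_quality_exposure",
    "dichotomize_greenness",
    "complete_case_filter",
]

HEALTH_LEVELS = ("very good", "good", "moderate", "bad", "very bad")
_GOOD_HEALTH = {"very good", "good"}
AGREEMENT_LEVELS = (
    "strongly agree",
    "rather agree",
    "neither agree nor disagree",
    "rather disagree",
    "strongly disagree",
)
GREENNESS_LEVELS = ("very green", "a little green", "hardly green", "not green at all")


def _norm(value):
    if pd.isna(value):
        return None
    return str(value).strip().lower()


def _recode(series: pd.Series, mapping: dict[str, int], what: str) -> pd.Series:
    out = np.full(len(series), np.nan)
    for i, v in enumerate(series):
        nv = _norm(v)
        if nv is None:
            continue
        if nv not in mapping:
            raise CohortError(f"{what}: unknown level {v!r}")
        out[i] = mapping[nv]
    return pd.Series(out, index=series.index)


def dichotomize_outcome(
    table: CohortTable, column: str = "self_rated_health", target: str = "good_health"
) -> CohortTable:
    """Binary good/bad self-rated health (1 = good); counts are conserved."""
    mapping = {lvl: int(lvl in _GOOD_HEALTH) for lvl in HEALTH_LEVELS}
    df = table.df.copy()
    df[target] = _recode(df[column], mapping, f"outcome column {column!r}")
    schema = dict(table.schema)
    if column in schema:
        schema[column] = ColumnMeta("other", schema[column].kind, schema[column].levels)
    schema[target] = ColumnMeta("outcome", "binary", [0, 1])
    return CohortTable(df, schema)


def derive_quality_exposure(
    table: CohortTable,
    access: str = "green_access",
    quality: str = "green_quality",
    maintained: str = "green_maintained",
    target: str = "high_quality_access",
) -> CohortTable:
    """Binary access-to-high-quality-green-space exposure (1 = high quality).

    Positive iff access == yes and both follow-up items == "strongly agree".
    A missing value in any of the three items makes the derived exposure
    missing (it is resolved by the complete-case filter, never defaulted).
    """
    df = table.df.copy()
    acc = _recode(df[access], {"yes": 1, "no": 0}, f"access column {access!r}")
    agree = {lvl: int(lvl == "strongly agree") for lvl in AGREEMENT_LEVELS}
    qual = _recode(df[quality], agree, f"quality column {quality!r}")
    maint = _recode(df[maintained], agree, f"maintenance column {maintained!r}")

    out = np.full(len(df), np.nan)
    missing = acc.isna() | qual.isna() | maint.isna()
    # participants without access are negative even if follow-ups are blank
    no_access = acc == 0
    out[no_access.to_numpy()] = 0.0
    ok = ~missing & ~no_access
    out[ok.to_numpy()] = (qual[ok] * maint[ok]).to_numpy()
    df[target] = out
    schema = dict(table.schema)
    for c in (access, quality, maintained):
        if c in schema:
            schema[c] = ColumnMeta("other", schema[c].kind, schema[c].levels)
    schema[target] = ColumnMeta("exposure", "binary", [0, 1])
    return CohortTable(df, schema)


def dichotomize_greenness(
    table: CohortTable, column: str = "neighborhood_greenness", target: str = "very_green"
) -> CohortTable:
    """Binary neighbourhood greenness (1 = very green, 0 = less green)."""
    mapping = {lvl: int(lvl == "very green") for lvl in GREENNESS_LEVELS}
    df = table.df.copy()
    df[target] = _recode(df[column], mapping, f"greenness column {column!r}")
    schema = dict(table.schema)
    if column in schema:
        schema[column] = ColumnMeta("other", schema[column].kind, schema[column].levels)
    schema[target] = ColumnMeta("exposure", "binary", [0, 1])
    return CohortTable(df, schema)


@dataclass
class ExclusionReport:
    """Bookkeeping of a complete-case restriction (or any n-in / n-out step)."""

    n_initial: int
    n_retained: int
    columns: list[str] = field(default_factory=list)
    missing_per_column: dict[str, int] = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return self.n_initial - self.n_retained

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_initial if self.n_initial else float("nan")

    @property
    def retained_pct(self) -> float:
        """Retained share in percent, rounded to 1 decimal as reported."""
        return round(100.0 * self.retained_fraction, 1)

    def to_dict(self) -> dict:
        return {
            "n_initial": self.n_initial,
            "n_retained": self.n_retained,
            "n_excluded": self.n_excluded,
            "retained_fraction": self.retained_fraction,
            "retained_pct": self.retained_pct,
            "columns": self.columns,
            "missing_per_column": self.missing_per_column,
        }


def complete_case_filter(
    table: CohortTable, columns: list[str] | None = None
) -> tuple[CohortTable, ExclusionReport]:
    """Keep only records with no missing value in ``columns``.

    ``columns`` defaults to every analysis column (outcome, exposure,
    confounders, moderators).  Idempotent.
    """
    if columns is None:
        columns = (
            [table.outcome_col, table.exposure_col] + table.confounders + table.moderators
        )
    if not columns:
        raise CohortError("complete_case_filter: empty column list")
    missing_cols = [c for c in columns if c not in table.df.columns]
    if missing_cols:
        raise CohortError(f"complete_case_filter: unknown columns {missing_cols}")

    sub = table.df[columns]
    keep = sub.notna().all(axis=1)
    report = ExclusionReport(
        n_initial=len(table.df),
        n_retained=int(keep.sum()),
        columns=list(columns),
        missing_per_column={c: int(sub[c].isna().sum()) for c in columns},
    )
    return table.copy_with(table.df.loc[keep].reset_index(drop=True)), report
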