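"""Tabular cohort container with column-role metadata.

A :class:`CohortTable` is a plain :class:`pandas.DataFrame` plus a schema that
records, for every column, its analysis *role* (outcome / exposure /
confounder / moderator / other) and its statistical *kind* (binary / ordinal /
nominal / continuous).  The schema travels with the CSV as a JSON sidecar so
that downstream stages (weighting, tree growth) know how to treat each column
without re-inferring types.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

ROLES = ("outcome", "exposure", "confounder", "moderator", "other")
KINDS = ("binary", "ordinal", "nominal", "continuous")


class CohortError(ValueError):
    """Invalid cohort table, schema, or configuration."""


@dataclass
class ColumnMeta:
    role: str
    kind: str
    levels: list | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise CohortError(f"unknown column role {self.role!r}; must be one of {ROLES}")
        if self.kind not in KINDS:
            raise CohortError(f"unknown column kind {self.kind!r}; must be one of {KINDS}")


@dataclass
class CohortTable:
    df: pd.DataFrame
    schema: dict[str, ColumnMeta] = field(default_factory=dict)

    def __post_init__(self):
        missing = set(self.schema) - set(self.df.columns)
        if missing:
            raise CohortError(f"schema refers to columns not in the table: {sorted(missing)}")

    # -- role accessors ----------------------------------------------------
    def _cols_with_role(self, role: str) -> list[str]:
        return [c for c, m in self.schema.items() if m.role == role]

    @property
    def outcome_col(self) -> str:
        cols = self._cols_with_role("outcome")
        if len(cols) != 1:
            raise CohortError(f"expected exactly one outcome column, found {cols}")
        return cols[0]

    @property
    def exposure_col(self) -> str:
        cols = self._cols_with_role("exposure")
        if len(cols) != 1:
            raise CohortError(f"expected exactly one exposure column, found {cols}")
        return cols[0]

    @property
    def confounders(self) -> list[str]:
        return self._cols_with_role("confounder")

    @property
    def moderators(self) -> list[str]:
        return self._cols_with_role("moderator")

    @property
    def n(self) -> int:
        return len(self.df)

    def kind(self, column: str) -> str:
        return self.schema[column].kind

    def copy_with(self, df: pd.DataFrame) -> "CohortTable":
        """New table sharing this schema (restricted to surviving columns)."""
        schema = {c: m for c, m in self.schema.items() if c in df.columns}
        return CohortTable(df, schema)

    # -- IO ----------------------------------------------------------------
    def write(self, csv_path: str | Path) -> None:
        """Write the cohort as UTF-8 CSV plus a ``.schema.json`` sidecar."""
        csv_path = Path(csv_path)
        self.df.to_csv(csv_path, index=False)
        sidecar = {
            c: {"role": m.role, "kind": m.kind, "levels": m.levels}
            for c, m in self.schema.items()
        }
        _sidecar_path(csv_path).write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read(cls, csv_path: str | Path) -> "CohortTable":
        csv_path = Path(csv_path)
        raw = json.loads(_sidecar_path(csv_path).read_text())
        schema = {c: ColumnMeta(d["role"], d["kind"], d.get("levels")) for c, d in raw.items()}
        # nominal columns must stay strings even if their labels look numeric
        dtypes = {c: str for c, m in schema.items() if m.kind == "nominal"}
        df = pd.read_csv(csv_path, dtype=dtypes)
        return cls(df, schema)


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_name(csv_path.stem + ".schema.json")
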