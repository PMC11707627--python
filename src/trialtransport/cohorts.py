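"""Subject-level cohort tables for trial-to-target transport analyses.

A :class:`CohortTable` wraps a pandas DataFrame of one subject per row with a
role tag: ``trial`` tables carry a randomized arm, an event/censoring time in
years and an event indicator; ``target`` tables carry covariates only.
Covariates may be missing (``NaN`` in the frame, empty field on disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRIAL = "trial"
TARGET = "target"

#: reserved (non-covariate) column names in a trial table
OUTCOME_COLUMNS = ("arm", "time", "event")

CONTINUOUS = "continuous"
BINARY = "binary"
CATEGORICAL = "categorical"


class SchemaError(ValueError):
    """Raised when a cohort table violates its declared schema."""


@dataclass
class CohortTable:
    """Subject-level records with a role tag.

    Parameters
    ----------
    data
        One subject per row. Trial-role tables must contain ``arm`` (0 =
        standard, 1 = intensive), ``time`` (years, > 0) and ``event`` (0/1).
        All other columns are covariates.
    role
        ``"trial"`` or ``"target"``.
    population_id
        Free-text label for the population (e.g. ``"VHA"``, ``"KPSC"``).
    schema
        Mapping covariate name -> kind (``continuous`` | ``binary`` |
        ``categorical``). Inferred from dtypes when omitted.
    """

    data: pd.DataFrame
    role: str
    population_id: str = ""
    schema: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in (TRIAL, TARGET):
            raise SchemaError(f"role must be 'trial' or 'target', got {self.role!r}")
        self.data = self.data.reset_index(drop=True)
        if self.role == TRIAL:
            missing = [c for c in OUTCOME_COLUMNS if c not in self.data.columns]
            if missing:
                raise SchemaError(f"trial table lacks outcome columns: {missing}")
            arm = self.data["arm"]
            if not arm.isin([0, 1]).all():
                raise SchemaError("arm must be 0 (standard) or 1 (intensive)")
            ev = self.data["event"]
            if not ev.isin([0, 1]).all():
                raise SchemaError("event must be 0 or 1")
            if (self.data["time"] <= 0).any():
                raise SchemaError("time must be strictly positive")
        else:
            present = [c for c in OUTCOME_COLUMNS if c in self.data.columns]
            if present:
                raise SchemaError(f"target table must not carry outcome columns: {present}")
        if not self.schema:
            self.schema = infer_schema(self.data[self.covariate_names])
        else:
            unknown = set(self.schema) - set(self.data.columns)
            if unknown:
                raise SchemaError(f"schema names absent from data: {sorted(unknown)}")

    # ------------------------------------------------------------------
    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in OUTCOME_COLUMNS and c != "id"]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data[self.covariate_names]

    @property
    def n(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "CohortTable":
        """Row subset preserving role, label and schema."""
        return CohortTable(
            self.data.loc[np.asarray(mask)].reset_index(drop=True),
            role=self.role,
            population_id=self.population_id,
            schema=dict(self.schema),
        )

    def with_data(self, data: pd.DataFrame) -> "CohortTable":
        return CohortTable(data, role=self.role, population_id=self.population_id,
                           schema=dict(self.schema))

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        """Write one subject per row; missing cells become empty fields."""
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, role: str, population_id: str = "",
                 schema: dict[str, str] | None = None) -> "CohortTable":
        df = pd.read_csv(path)
        return cls(df, role=role, population_id=population_id, schema=schema or {})


def infer_schema(covariates: pd.DataFrame) -> dict[str, str]:
    """Classify covariates as continuous, binary or categorical by content."""
    schema: dict[str, str] = {}
    for name in covariates.columns:
        col = covariates[name].dropna()
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            schema[name] = CATEGORICAL
        elif set(pd.unique(col)) <= {0, 1, 0.0, 1.0}:
            schema[name] = BINARY
        else:
            schema[name] = CONTINUOUS
    return schema
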