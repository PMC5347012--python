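"""Cohort and follow-up table I/O.

Cohort files are plain CSV, UTF-8, one baseline row per subject:
``subject_id, group, age, sex, education, icv`` followed optionally by
``suvr`` and ``apoe_e4_count``, then one column per schema feature.
Follow-up files are long format: ``subject_id, month, diagnosis, mmse,
cdr_sob, vital_status``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import ROISchema

GROUPS = ("HC", "SMD", "MCI", "AD")

REQUIRED_META = ["subject_id", "group", "age", "sex", "education", "icv"]
OPTIONAL_META = ["suvr", "apoe_e4_count"]


class SchemaError(ValueError):
    """A required column is absent or mismatched against the schema."""


class IntegrityError(ValueError):
    """Table-level invariant violated (duplicate ids, bad values)."""


@dataclass
class CohortTable:
    """Validated per-subject baseline table.

    ``data`` holds one row per subject with metadata columns first and
    feature columns in schema order after them.  Extra columns present
    in the source file (for example hidden simulation truth labels,
    prefixed ``truth_``) are preserved but never enter feature matrices.
    """

    data: pd.DataFrame
    schema: ROISchema

    def __post_init__(self) -> None:
        ids = self.data["subject_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique().tolist())
            raise IntegrityError(f"duplicate subject_id values: {dupes}")
        missing = [c for c in self.schema.names if c not in self.data.columns]
        if missing:
            raise SchemaError(f"cohort table missing feature columns: {missing[:5]}")
        bad_group = set(self.data["group"]) - set(GROUPS)
        if bad_group:
            raise IntegrityError(f"unknown group labels: {sorted(bad_group)}")
        icv = self.data["icv"].to_numpy(float)
        if not np.all(np.isfinite(icv)) or np.any(icv <= 0):
            raise IntegrityError("icv must be finite and positive for every subject")
        feats = self.data[self.schema.names].to_numpy(float)
        if not np.all(np.isfinite(feats)):
            r, c = np.argwhere(~np.isfinite(feats))[0]
            raise IntegrityError(
                "non-finite feature value at subject "
                f"{self.data['subject_id'].iloc[r]!r}, column {self.schema.names[c]!r}"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> list[str]:
        return self.data["subject_id"].astype(str).tolist()

    def subset(self, groups) -> "CohortTable":
        mask = self.data["group"].isin(set(groups))
        return CohortTable(self.data.loc[mask].reset_index(drop=True), self.schema)


@dataclass
class FeatureMatrix:
    """Subjects-by-features array with row ids and column names."""

    values: np.ndarray
    row_ids: list[str]
    columns: list[str]
    icv: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[0] != len(self.row_ids):
            raise ValueError("row_ids length does not match matrix")
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column names do not match matrix width")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "FeatureMatrix":
        icv = None if self.icv is None else self.icv.copy()
        return FeatureMatrix(self.values.copy(), list(self.row_ids), list(self.columns), icv)


def read_cohort_table(path, schema: ROISchema) -> CohortTable:
    """Read and validate a cohort CSV against ``schema``.

    Column names are matched case-sensitively.  Raises
    :class:`SchemaError` naming the first missing required column,
    and a parse error with row/column context for non-numeric cells.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    for col in REQUIRED_META:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path.name}")
    for col in schema.names:
        if col not in df.columns:
            raise SchemaError(f"missing feature column {col!r} in {path.name}")
    numeric_cols = ["age", "icv"] + schema.names
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise IntegrityError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, "
                f"row {row} of {path.name}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna())[0])
            raise IntegrityError(
                f"missing value in column {col!r}, row {row} of {path.name}"
            )
        df[col] = coerced
    return CohortTable(df, schema)


def write_cohort_table(cohort: CohortTable, path) -> None:
    """Write a cohort table as CSV; inverse of :func:`read_cohort_table`."""
    meta = [c for c in cohort.data.columns if c not in cohort.schema.names]
    cols = meta + cohort.schema.names
    cohort.data[cols].to_csv(path, index=False)


def build_feature_matrix(cohort: CohortTable, schema: ROISchema,
                         include_groups) -> FeatureMatrix:
    """Assemble the analysis matrix for the requested groups.

    One row per selected subject in input order; exactly one column per
    schema feature, in schema order.  Carries ICV alongside for the
    preprocessing stage.
    """
    include_groups = set(include_groups)
    if not include_groups:
        raise ValueError("empty group selection")
    missing = include_groups - set(cohort.data["group"].unique())
    if missing:
        raise ValueError(f"groups not present in cohort: {sorted(missing)}")
    sel = cohort.data[cohort.data["group"].isin(include_groups)]
    return FeatureMatrix(
        values=sel[schema.names].to_numpy(float),
        row_ids=sel["subject_id"].astype(str).tolist(),
        columns=list(schema.names),
        icv=sel["icv"].to_numpy(float),
    )


FOLLOWUP_COLUMNS = ["subject_id", "month", "diagnosis", "mmse", "cdr_sob", "vital_status"]


def read_followup_table(path) -> pd.DataFrame:
    """Read a long-format follow-up CSV and check its visit structure."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in FOLLOWUP_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"follow-up table missing columns: {missing}")
    for sid, grp in df.groupby("subject_id"):
        months = grp["month"].to_numpy()
        if not np.all(np.diff(months) > 0):
            raise IntegrityError(f"visit months not strictly increasing for {sid!r}")
        if months[0] != 0:
            raise IntegrityError(f"baseline visit (month 0) absent for {sid!r}")
    return df


def write_followup_table(df: pd.DataFrame, path) -> None:
    df[FOLLOWUP_COLUMNS].to_csv(path, index=False)
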