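"""Reading and validating cohort tables from delimited text files."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import COLUMNS

__all__ = ["read_cohort_csv", "ValidationReport"]

_REQUIRED = set(COLUMNS) - {"subject_id"}
_NUMERIC = ["age", "diabetes_duration", "bmi", "hba1c", "resistin",
            "g1", "g2", "follow_up"]
_BINARY = ["smoker", "insulin_therapy", "antihypertensive",
           "antidyslipidemia", "event"]


@dataclass
class ValidationReport:
    n_rows: int
    n_cohorts: int
    missing_per_column: dict[str, int] = field(default_factory=dict)
    extra_columns: list[str] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)


def read_cohort_csv(path) -> tuple[pd.DataFrame, ValidationReport]:
    """Load a per-subject cohort table, validating schema and domains.

    Empty cells load as missing.  Raises on absent required columns,
    unparseable numeric cells (reported with row and column), nonpositive
    resistin, negative follow-up, or allele counts outside {0, 1, 2}.
    Extra columns are tolerated and listed in the validation report.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing_cols = sorted(_REQUIRED - set(raw.columns))
    if missing_cols:
        raise ValueError(f"missing required columns: {missing_cols}")
    extra = sorted(set(raw.columns) - set(COLUMNS))

    table = pd.DataFrame(index=raw.index)
    if "subject_id" in raw.columns:
        table["subject_id"] = raw["subject_id"]
    else:
        table["subject_id"] = [f"row-{i:05d}" for i in raw.index]
    table["cohort"] = raw["cohort"].astype(str)
    table["sex"] = raw["sex"].astype(str).str.lower()
    bad_sex = ~table["sex"].isin(["male", "female"])
    if bad_sex.any():
        raise ValueError(f"unrecognized sex values at rows "
                         f"{list(raw.index[bad_sex][:10])}")
    for col in _NUMERIC + _BINARY:
        vals = pd.to_numeric(raw[col], errors="coerce")
        unparseable = vals.isna() & raw[col].notna()
        if unparseable.any():
            r = int(raw.index[unparseable][0])
            raise ValueError(f"unparseable value {raw[col][r]!r} "
                             f"at row {r}, column {col!r}")
        table[col] = vals
    for col in _BINARY:
        bad = ~table[col].dropna().isin([0, 1])
        if bad.any():
            raise ValueError(f"column {col!r} must be 0/1")
        table[col] = table[col].astype("Int64").astype(float)
    if (table["resistin"].dropna() <= 0).any():
        rows = list(table.index[table["resistin"] <= 0][:10])
        raise ValueError(f"resistin must be > 0; offending rows: {rows}")
    if (table["follow_up"].dropna() < 0).any():
        raise ValueError("follow_up must be >= 0")
    for col in ("g1", "g2"):
        bad = ~table[col].dropna().isin([0, 1, 2])
        if bad.any():
            raise ValueError(f"{col}: allele counts outside {{0,1,2}}")
    table["event"] = table["event"].astype(int)
    table = table[COLUMNS]

    report = ValidationReport(
        n_rows=int(len(table)),
        n_cohorts=int(table["cohort"].nunique()),
        missing_per_column={c: int(table[c].isna().sum()) for c in COLUMNS
                            if table[c].isna().any()},
        extra_columns=extra,
    )
    if extra:
        report.messages.append(f"ignored extra columns: {extra}")
    return table, report
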