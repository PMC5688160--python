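"""Subject-by-variable cohort tables with per-variable type declarations.

A cohort table is a pandas DataFrame (subjects as rows, variables as
columns) plus a declaration of each variable's kind — ``numerical`` or
``categorical`` — which drives the choice of pairwise statistic downstream.
Missing cells are NaN internally; on disk they are empty strings (or any
of the configured missing markers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

NUMERICAL = "numerical"
CATEGORICAL = "categorical"
KINDS = (NUMERICAL, CATEGORICAL)

#: Cell values treated as missing when reading a cohort CSV.
DEFAULT_MISSING_MARKERS = ("", "NA")


class CohortError(ValueError):
    """Malformed cohort data or metadata."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one variable: its unique name and its kind."""

    name: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise CohortError(
                f"variable {self.name!r}: unknown kind {self.kind!r}; "
                f"expected one of {KINDS}"
            )


@dataclass
class CohortTable:
    """Subjects × variables with kind declarations and missing cells.

    Parameters
    ----------
    data:
        DataFrame with one column per variable. Numerical columns are
        float (NaN = missing); categorical columns are object dtype with
        string levels (NaN = missing).
    variables:
        One :class:`VariableSpec` per column, in column order.
    """

    data: pd.DataFrame
    variables: list[VariableSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CohortError(f"duplicate variable names: {dupes}")
        if list(self.data.columns) != names:
            raise CohortError("metadata variable order does not match table columns")
        if len(names) < 2:
            raise CohortError("a cohort table needs at least 2 variables")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def kinds(self) -> dict[str, str]:
        return {v.name: v.kind for v in self.variables}

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()


def read_cohort(
    path: str | Path,
    metadata_path: str | Path,
    missing_markers: Iterable[str] = DEFAULT_MISSING_MARKERS,
) -> CohortTable:
    """Read a cohort CSV and its variable-metadata CSV.

    The metadata file must have columns ``name`` and ``kind``; every data
    column must be declared there. Cells matching a missing marker become
    NaN. A non-numeric cell in a numerical column raises :class:`CohortError`
    naming the offending row and column.
    """
    markers = list(missing_markers)
    meta = pd.read_csv(metadata_path, dtype=str, keep_default_na=False)
    if "name" not in meta.columns or "kind" not in meta.columns:
        raise CohortError("metadata must have 'name' and 'kind' columns")
    specs = {row["name"]: VariableSpec(row["name"], row["kind"]) for _, row in meta.iterrows()}

    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=markers, index_col=0)
    undeclared = [c for c in raw.columns if c not in specs]
    if undeclared:
        raise CohortError(f"columns missing from metadata: {undeclared}")

    cols: dict[str, pd.Series] = {}
    for name in raw.columns:
        col = raw[name]
        if specs[name].kind == NUMERICAL:
            parsed = pd.to_numeric(col, errors="coerce")
            bad = parsed.isna() & col.notna()
            if bad.any():
                row = bad.idxmax()
                raise CohortError(
                    f"non-numeric value {col[row]!r} in numerical column "
                    f"{name!r} at row {row!r}"
                )
            cols[name] = parsed.astype(float)
        else:
            cols[name] = col.astype(object)
    data = pd.DataFrame(cols, index=raw.index)
    variables = [specs[c] for c in data.columns]
    return CohortTable(data=data, variables=variables)


def write_cohort(
    table: CohortTable,
    path: str | Path,
    metadata_path: str | Path,
    block_labels: Mapping[str, object] | None = None,
) -> None:
    """Write the cohort as CSV (empty string = missing) plus metadata CSV."""
    table.data.to_csv(path, na_rep="", index_label="subject")
    meta = pd.DataFrame(
        {
            "name": [v.name for v in table.variables],
            "kind": [v.kind for v in table.variables],
        }
    )
    if block_labels is not None:
        meta["block_label"] = [block_labels[v.name] for v in table.variables]
    meta.to_csv(metadata_path, index=False)
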