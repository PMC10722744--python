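"""Dummy-encoding of prepared cohort variables into model design matrices."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, VariableSpec


def spec_map(specs: Sequence[VariableSpec]) -> dict[str, VariableSpec]:
    return {s.name: s for s in specs}


def column_name(var: str, level: str | None) -> str:
    return var if level is None else f"{var}__{level}"


def dummy_encode(
    table: CohortTable,
    specs: Sequence[VariableSpec],
    variables: Sequence[str],
    drop_reference: bool = True,
) -> tuple[pd.DataFrame, list[tuple[str, str | None]], dict[str, str]]:
    """Encode ``variables`` into a numeric design matrix.

    Categorical variables become 0/1 indicator columns, with the first
    declared level dropped as the reference when ``drop_reference``;
    continuous variables pass through as floats. Returns the matrix, the
    ``(variable, level)`` identity of each column (level None = continuous),
    and each categorical variable's reference level.

    Missing cells are not allowed here: run the preparation recodes
    (missing-as-category / categorization) first.
    """
    by_name = spec_map(specs)
    cols: dict[str, np.ndarray] = {}
    info: list[tuple[str, str | None]] = []
    refs: dict[str, str] = {}
    for var in variables:
        if var not in by_name:
            raise KeyError(f"variable {var!r} not in dictionary")
        spec = by_name[var]
        col = table.data[var]
        if col.isna().any():
            raise ValueError(
                f"variable {var!r} has missing cells; apply the preparation "
                "recodes before encoding"
            )
        if spec.is_categorical:
            levels = list(spec.levels)
            start = 1 if drop_reference else 0
            if drop_reference:
                refs[var] = levels[0]
            for lv in levels[start:]:
                cols[column_name(var, lv)] = (col == lv).to_numpy(dtype=float)
                info.append((var, lv))
        else:
            cols[var] = pd.to_numeric(col).to_numpy(dtype=float)
            info.append((var, None))
    X = pd.DataFrame(cols, index=table.data.index)
    return X, info, refs


def drop_constant_columns(
    X: pd.DataFrame, info: list[tuple[str, str | None]]
) -> tuple[pd.DataFrame, list[tuple[str, str | None]], list[str]]:
    """Remove zero-variance columns (e.g. unobserved levels)."""
    keep, dropped = [], []
    for j, c in enumerate(X.columns):
        if np.ptp(X[c].to_numpy()) > 0:
            keep.append(j)
        else:
            dropped.append(c)
    return X.iloc[:, keep], [info[j] for j in keep], dropped
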