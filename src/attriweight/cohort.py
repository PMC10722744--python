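"""Cohort tables, variable dictionaries, and variable-preparation recodes.

The in-memory currency of the package is a :class:`CohortTable` — a
participant × variable grid of baseline survey answers plus per-wave binary
participation indicators — together with a list of :class:`VariableSpec`
entries describing each variable's type, context theme, levels and role.

Variable preparation follows the convention of participation-model building
in longitudinal cohorts: item missingness in categorical variables is
recoded into an explicit ``"missing"`` level (so no participant is dropped),
and continuous variables are cut into interval categories before penalized
screening.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The seven context themes used to group baseline variables.
THEMES: tuple[str, ...] = (
    "sociodemographic",
    "pregnancy_history",
    "conception_history",
    "prenatal_care",
    "lifestyle_health_care_use",
    "mental_health_social_support",
    "substance_use",
)

#: Label used for the explicit missing category.
MISSING_LEVEL = "missing"

#: Roles a variable can take in the analysis.
ROLES = ("candidate", "demographic", "id", "wave")

_WAVE_COL_RE = re.compile(r"^wave_(?P<label>.+)_participation$")


class SchemaError(ValueError):
    """A data column and the variable dictionary disagree."""


class ValidationError(ValueError):
    """A cell value violates its variable's declared levels."""


@dataclass(frozen=True)
class VariableSpec:
    """Metadata for one baseline variable.

    Parameters
    ----------
    name : str
        Column name in the cohort table.
    theme : str
        One of the seven context themes in :data:`THEMES`.
    vtype : {"categorical", "continuous"}
    levels : tuple of str, optional
        Ordered level labels; required for categorical variables.
    role : {"candidate", "demographic", "id", "wave"}
        ``demographic`` variables are also candidates for selection but
        additionally enter the balance table.
    has_missing_category : bool
        Whether ``"missing"`` is one of the levels.
    cutpoints : tuple of float, optional
        Breakpoints used when a continuous variable was categorized.
    """

    name: str
    theme: str
    vtype: str
    levels: tuple[str, ...] | None = None
    role: str = "candidate"
    has_missing_category: bool = False
    cutpoints: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.theme not in THEMES:
            raise SchemaError(
                f"variable {self.name!r}: unknown theme {self.theme!r}; "
                f"expected one of {THEMES}"
            )
        if self.vtype not in ("categorical", "continuous"):
            raise SchemaError(
                f"variable {self.name!r}: vtype must be 'categorical' or "
                f"'continuous', got {self.vtype!r}"
            )
        if self.role not in ROLES:
            raise SchemaError(f"variable {self.name!r}: unknown role {self.role!r}")
        if self.vtype == "categorical":
            if self.levels is None or len(self.levels) < 2:
                raise SchemaError(
                    f"categorical variable {self.name!r} needs >= 2 levels"
                )
            if len(set(self.levels)) != len(self.levels):
                raise SchemaError(f"variable {self.name!r}: duplicate levels")
            n_missing = sum(1 for lv in self.levels if lv == MISSING_LEVEL)
            if self.has_missing_category and n_missing != 1:
                raise SchemaError(
                    f"variable {self.name!r}: has_missing_category set but "
                    f"'missing' appears {n_missing} times in levels"
                )
            if not self.has_missing_category and n_missing:
                raise SchemaError(
                    f"variable {self.name!r}: 'missing' level present but "
                    "has_missing_category not set"
                )
        else:
            if self.levels is not None:
                raise SchemaError(
                    f"continuous variable {self.name!r} must not declare levels"
                )

    @property
    def is_categorical(self) -> bool:
        return self.vtype == "categorical"

    @property
    def nonmissing_levels(self) -> tuple[str, ...]:
        """Declared levels excluding the explicit missing category."""
        if self.levels is None:
            return ()
        return tuple(lv for lv in self.levels if lv != MISSING_LEVEL)


@dataclass
class CohortTable:
    """Participant × variable grid plus per-wave participation indicators.

    ``data`` is indexed by participant id (opaque strings, unique) with one
    column per baseline variable; missing answers are NaN. ``waves`` shares
    the index and holds one 0/1 integer column per follow-up wave
    (1 = continued, 0 = lost to follow-up); no missing values allowed.
    """

    data: pd.DataFrame
    waves: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.waves is None or len(self.waves) == 0:
            self.waves = pd.DataFrame(index=self.data.index)
        if not self.data.index.is_unique:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate participant_id {dup!r}")
        if not self.waves.index.equals(self.data.index):
            raise ValidationError("waves index does not match data index")
        for col in self.waves.columns:
            vals = self.waves[col]
            if vals.isna().any():
                raise ValidationError(f"wave column {col!r} has missing values")
            if not set(np.unique(vals)).issubset({0, 1}):
                raise ValidationError(f"wave column {col!r} is not 0/1")
        self.waves = self.waves.astype(int)

    @property
    def n_participants(self) -> int:
        return len(self.data)

    @property
    def wave_labels(self) -> list[str]:
        return list(self.waves.columns)

    def participation(self, wave: str) -> pd.Series:
        """0/1 participation indicator for ``wave``."""
        if wave not in self.waves.columns:
            raise KeyError(
                f"unknown wave {wave!r}; available: {list(self.waves.columns)}"
            )
        return self.waves[wave]

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), self.waves.copy())


def validate_cohort(table: CohortTable, specs: Sequence[VariableSpec]) -> None:
    """Check that every data column matches its dictionary entry.

    Raises :class:`SchemaError` for undeclared columns and
    :class:`ValidationError` for out-of-level categorical cells.
    """
    by_name = {s.name: s for s in specs}
    for col in table.data.columns:
        if col not in by_name:
            raise SchemaError(f"data column {col!r} has no dictionary entry")
        spec = by_name[col]
        if spec.is_categorical:
            vals = table.data[col].dropna()
            allowed = set(spec.levels)
            bad = vals[~vals.astype(str).isin(allowed)]
            if len(bad):
                rid, val = bad.index[0], bad.iloc[0]
                raise ValidationError(
                    f"column {col!r}, participant {rid!r}: value {val!r} "
                    f"not in declared levels {spec.levels}"
                )


# ---------------------------------------------------------------------------
# I/O: delimited text with a companion variable dictionary
# ---------------------------------------------------------------------------

def write_cohort(
    table: CohortTable,
    specs: Sequence[VariableSpec],
    table_path: str | Path,
    dictionary_path: str | Path,
) -> None:
    """Write the cohort table and its variable dictionary as CSV.

    Missing cells are written as empty fields. Wave indicator columns are
    named ``wave_<label>_participation``.
    """
    out = table.data.copy()
    for wave in table.waves.columns:
        out[f"wave_{wave}_participation"] = table.waves[wave].values
    out.index.name = "participant_id"
    out.to_csv(table_path, na_rep="")

    rows = []
    for s in specs:
        rows.append(
            {
                "name": s.name,
                "theme": s.theme,
                "vtype": s.vtype,
                "levels": "|".join(s.levels) if s.levels else "",
                "role": s.role,
                "cutpoints": "|".join(str(c) for c in s.cutpoints)
                if s.cutpoints
                else "",
            }
        )
    pd.DataFrame(rows).to_csv(dictionary_path, index=False)


def read_cohort(
    table_path: str | Path, dictionary_path: str | Path
) -> tuple[CohortTable, list[VariableSpec]]:
    """Read a cohort CSV plus variable dictionary; validate on the way in.

    Both the empty string and the literal token ``NA`` are accepted as
    missing markers in the data file.
    """
    table_path, dictionary_path = Path(table_path), Path(dictionary_path)
    for p in (table_path, dictionary_path):
        if not p.exists():
            raise FileNotFoundError(str(p))

    ddf = pd.read_csv(dictionary_path, dtype=str, keep_default_na=False)
    for req in ("name", "theme", "vtype"):
        if req not in ddf.columns:
            raise SchemaError(f"variable dictionary lacks column {req!r}")
    specs: list[VariableSpec] = []
    for _, row in ddf.iterrows():
        levels = tuple(row["levels"].split("|")) if row.get("levels") else None
        cutpoints = (
            tuple(float(c) for c in row["cutpoints"].split("|"))
            if row.get("cutpoints")
            else None
        )
        specs.append(
            VariableSpec(
                name=row["name"],
                theme=row["theme"],
                vtype=row["vtype"],
                levels=levels,
                role=row.get("role") or "candidate",
                has_missing_category=bool(levels) and MISSING_LEVEL in levels,
                cutpoints=cutpoints,
            )
        )
    by_name = {s.name: s for s in specs}

    raw = pd.read_csv(
        table_path,
        dtype=str,
        keep_default_na=False,
        na_values=["", "NA"],
        index_col="participant_id",
    )
    raw.index = raw.index.astype(str)

    wave_cols = {}
    data_cols = []
    for col in raw.columns:
        m = _WAVE_COL_RE.match(col)
        if m:
            wave_cols[m.group("label")] = raw[col].astype(float).astype(int)
        else:
            data_cols.append(col)

    data = raw[data_cols].copy()
    for col in data_cols:
        spec = by_name.get(col)
        if spec is None:
            raise SchemaError(f"data column {col!r} has no dictionary entry")
        if not spec.is_categorical:
            data[col] = pd.to_numeric(data[col])
    waves = pd.DataFrame(wave_cols, index=data.index)
    table = CohortTable(data, waves)
    validate_cohort(table, specs)
    return table, specs


# ---------------------------------------------------------------------------
# Variable-preparation recodes
# ---------------------------------------------------------------------------

def recode_missing_as_category(
    table: CohortTable, specs: Sequence[VariableSpec]
) -> tuple[CohortTable, list[VariableSpec]]:
    """Turn item missingness in categorical variables into a ``"missing"`` level.

    A ``"missing"`` level is appended only to variables that actually have
    missing cells; non-missing cells are never altered. Continuous variables
    pass through untouched (use :func:`categorize_continuous` first if the
    downstream model needs them categorical).
    """
    new_table = table.copy()
    new_specs: list[VariableSpec] = []
    for spec in specs:
        if not spec.is_categorical or spec.name not in new_table.data.columns:
            new_specs.append(spec)
            continue
        col = new_table.data[spec.name]
        if col.isna().any():
            new_table.data[spec.name] = col.fillna(MISSING_LEVEL)
            if not spec.has_missing_category:
                spec = replace(
                    spec,
                    levels=spec.levels + (MISSING_LEVEL,),
                    has_missing_category=True,
                )
        new_specs.append(spec)
    return new_table, new_specs


def recode_missing_single(
    table: CohortTable, spec: VariableSpec
) -> tuple[CohortTable, VariableSpec]:
    """Missing-category recode of a single categorical variable."""
    if not spec.is_categorical:
        raise TypeError(
            f"recode_missing applies to categorical variables; "
            f"{spec.name!r} is continuous"
        )
    new_table, new_specs = recode_missing_as_category(table, [spec])
    return new_table, new_specs[0]


def _interval_labels(cutpoints: Sequence[float]) -> list[str]:
    cps = [f"{c:g}" for c in cutpoints]
    labels = [f"lt_{cps[0]}"]
    labels += [f"{a}_to_{b}" for a, b in zip(cps[:-1], cps[1:])]
    labels.append(f"ge_{cps[-1]}")
    return labels


def categorize_continuous(
    table: CohortTable,
    spec: VariableSpec,
    cutpoints: Sequence[float] | None = None,
    n_quantile_bins: int = 5,
) -> tuple[CohortTable, VariableSpec]:
    """Cut a continuous variable into interval categories.

    Intervals are half-open ``[a, b)`` with the final interval closed on the
    right, so a value exactly at a cutpoint falls in the upper interval.
    When ``cutpoints`` is omitted they default to interior quantiles
    (quintiles for ``n_quantile_bins=5``) of the observed values. Missing
    cells stay missing (recode them afterwards if needed).
    """
    if not spec.is_categorical and spec.vtype != "continuous":
        raise TypeError(f"unknown vtype for {spec.name!r}")
    if spec.is_categorical:
        raise TypeError(f"{spec.name!r} is already categorical")
    x = pd.to_numeric(table.data[spec.name])
    if cutpoints is None:
        qs = np.linspace(0, 1, n_quantile_bins + 1)[1:-1]
        cutpoints = sorted(set(np.nanquantile(x.values.astype(float), qs)))
        if not cutpoints:
            cutpoints = [float(np.nanmedian(x.values.astype(float)))]
    cutpoints = [float(c) for c in cutpoints]
    if any(b <= a for a, b in zip(cutpoints[:-1], cutpoints[1:])):
        raise ValueError(
            f"cutpoints for {spec.name!r} must be strictly increasing: {cutpoints}"
        )
    labels = _interval_labels(cutpoints)
    # right=False: x == cutpoint goes to the upper interval
    idx = np.digitize(x.values.astype(float), cutpoints, right=False)
    coded = pd.Series(
        [labels[i] if not np.isnan(v) else np.nan for i, v in zip(idx, x.values)],
        index=x.index,
        dtype=object,
    )
    new_table = table.copy()
    new_table.data[spec.name] = coded
    new_spec = VariableSpec(
        name=spec.name,
        theme=spec.theme,
        vtype="categorical",
        levels=tuple(labels),
        role=spec.role,
        cutpoints=tuple(cutpoints),
    )
    return new_table, new_spec


def prepare_for_modelling(
    table: CohortTable,
    specs: Sequence[VariableSpec],
    variables: Iterable[str] | None = None,
    n_quantile_bins: int = 5,
) -> tuple[CohortTable, list[VariableSpec]]:
    """Full preparation pass: categorize continuous variables, then recode
    missingness into explicit categories.

    Returns a new table/spec list in which every candidate variable is
    categorical with no missing cells — the form the penalized screening and
    the participation models consume.
    """
    varset = set(variables) if variables is not None else None
    work = table.copy()
    out_specs: list[VariableSpec] = []
    for spec in specs:
        if spec.role in ("id", "wave") or (
            varset is not None and spec.name not in varset
        ):
            out_specs.append(spec)
            continue
        if spec.vtype == "continuous":
            work, spec = categorize_continuous(
                work, spec, n_quantile_bins=n_quantile_bins
            )
        out_specs.append(spec)
    return recode_missing_as_category(work, out_specs)
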