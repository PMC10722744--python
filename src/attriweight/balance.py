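"""Covariate balance between continuers and drop-outs.

The performance criterion for non-response weights: the absolute
standardized difference of each baseline demographic variable between the
participants who continued at a wave and those who did not, with and
without weights. A difference below 10% is conventionally negligible.

For a continuous variable,

    d = (m1 - m2) / sqrt((s1^2 + s2^2) / 2),

reported as |d| x 100%. Each level of a categorical variable is treated as
a dichotomy, and the variable is summarized by the maximum |d| over its
levels. In the default weighted comparison the continuer group is weighted
by the (truncated) stabilized weights p̄/p̂ and the drop-out group by the
mirror weights (1-p̄)/(1-p̂), so both groups are reweighted toward the
baseline distribution and a saturated participation model balances them
exactly. A responders-only mode (drop-outs unweighted) is available for
sensitivity checks; per-variable complete cases only throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, VariableSpec
from .weighting import WeightSet, refit_for_wave

__all__ = [
    "BalanceReport",
    "standardized_difference_continuous",
    "standardized_difference_categorical",
    "balance_table",
    "multiwave_balance",
]

NEGLIGIBLE_PCT = 10.0


def _weighted_mean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    wsum = w.sum()
    m = float((w * x).sum() / wsum)
    n = len(x)
    if n < 2:
        return m, 0.0
    v = float((w * (x - m) ** 2).sum() / wsum) * n / (n - 1)
    return m, v


def standardized_difference_continuous(
    x, group, weights: Mapping | pd.Series | None = None,
    weights_lost: Mapping | pd.Series | None = None,
) -> float:
    """Signed standardized difference of a continuous variable.

    ``group`` is 1 for continuers, 0 for drop-outs. ``weights`` (optional)
    apply to the continuer group; ``weights_lost`` (optional) to the
    drop-out group. Missing values are dropped per variable (complete
    cases). Returns d as a signed fraction; multiply by 100 for the
    conventional percent scale.
    """
    x = pd.Series(x).astype(float)
    group = pd.Series(group).reindex(x.index).astype(int)
    keep = x.notna()
    x, group = x[keep], group[keep]
    if group.nunique() < 2:
        raise ValueError("both groups (continued / lost) must be non-empty")

    x1, x0 = x[group == 1], x[group == 0]
    if weights is not None:
        w1 = pd.Series(weights).reindex(x1.index).astype(float)
        if w1.isna().any():
            raise ValueError("weights missing for some continuers")
        m1, v1 = _weighted_mean_var(x1.to_numpy(), w1.to_numpy())
    else:
        m1, v1 = float(x1.mean()), float(x1.var(ddof=1))
    if weights_lost is not None:
        w0 = pd.Series(weights_lost).reindex(x0.index).astype(float)
        if w0.isna().any():
            raise ValueError("weights missing for some drop-outs")
        m0, v0 = _weighted_mean_var(x0.to_numpy(), w0.to_numpy())
    else:
        m0, v0 = float(x0.mean()), float(x0.var(ddof=1))

    denom = np.sqrt((v1 + v0) / 2)
    if denom == 0:
        if np.isclose(m1, m0):
            return 0.0
        raise ValueError("zero pooled variance with unequal means")
    return float((m1 - m0) / denom)


def standardized_difference_categorical(
    x, group, weights: Mapping | pd.Series | None = None,
    weights_lost: Mapping | pd.Series | None = None,
) -> float:
    """Max over levels of the dichotomous standardized difference.

    Each observed level is scored as a binary indicator:
    d_l = (p1 - p0) / sqrt((p1(1-p1) + p0(1-p0)) / 2); the variable-level
    statistic is max_l |d_l| (unsigned). Levels absent in both groups are
    skipped.
    """
    x = pd.Series(x).astype(object)
    group = pd.Series(group).reindex(x.index).astype(int)
    keep = x.notna()
    x, group = x[keep], group[keep]
    if group.nunique() < 2:
        raise ValueError("both groups (continued / lost) must be non-empty")
    levels = pd.unique(x)
    best = 0.0
    for lv in levels:
        ind = (x == lv).astype(float)
        d = standardized_difference_continuous(
            ind, group, weights=weights, weights_lost=weights_lost
        )
        best = max(best, abs(d))
    return float(best)


@dataclass
class BalanceReport:
    """Standardized differences (as |d| percent) per variable per scheme."""

    wave: str
    table: pd.DataFrame  # index: variable; columns: unweighted + schemes
    threshold_pct: float = NEGLIGIBLE_PCT

    @property
    def schemes(self) -> list[str]:
        return list(self.table.columns)

    def max_abs(self, scheme: str = "unweighted") -> float:
        return float(self.table[scheme].max())

    def mean_abs(self, scheme: str = "unweighted") -> float:
        return float(self.table[scheme].mean())

    def flagged(self, scheme: str = "unweighted") -> list[str]:
        col = self.table[scheme]
        return list(col.index[col >= self.threshold_pct])

    def summary(self) -> dict:
        return {
            "wave": self.wave,
            "schemes": {
                s: {
                    "max_abs_pct": round(self.max_abs(s), 1),
                    "mean_abs_pct": round(self.mean_abs(s), 1),
                    "flagged_ge_10pct": self.flagged(s),
                }
                for s in self.schemes
            },
        }

    def to_csv(self, path) -> None:
        self.table.round(1).to_csv(path, index_label="variable")


def balance_table(
    table: CohortTable,
    specs: Sequence[VariableSpec],
    wave: str,
    weight_sets: Mapping[str, WeightSet] | None = None,
    demographic_list: Sequence[str] | None = None,
    mode: str = "both_groups",
) -> BalanceReport:
    """Unweighted and weighted |d|% for each demographic variable.

    ``demographic_list`` defaults to the dictionary's demographic-role
    variables. One weighted column is produced per entry of
    ``weight_sets`` (scheme name -> WeightSet), using each scheme's
    analysis-facing (truncated) weights. ``mode`` controls the weighted
    comparison: ``"both_groups"`` (default) weights continuers by p̄/p̂ and
    drop-outs by the mirror (1-p̄)/(1-p̂) — exactly balancing under a
    saturated model; ``"responders_only"`` leaves drop-outs unweighted.
    """
    if mode not in ("both_groups", "responders_only"):
        raise ValueError(f"unknown balance mode {mode!r}")
    by_name = {s.name: s for s in specs}
    if demographic_list is None:
        demographic_list = [s.name for s in specs if s.role == "demographic"]
    unknown = [v for v in demographic_list if v not in by_name]
    if unknown:
        raise KeyError(f"demographic variables not in dictionary: {unknown}")
    group = table.participation(wave)
    if group.min() == group.max():
        raise ValueError(
            f"wave {wave!r} has no variation in participation; balance undefined"
        )
    weight_sets = weight_sets or {}

    rows = {}
    for var in demographic_list:
        spec = by_name[var]
        fn = (
            standardized_difference_categorical
            if spec.is_categorical
            else standardized_difference_continuous
        )
        x = table.data[var]
        entry = {"unweighted": abs(fn(x, group)) * 100}
        for scheme, ws in weight_sets.items():
            wl = ws.dropout_weights if mode == "both_groups" else None
            entry[scheme] = abs(fn(x, group, weights=ws.weights, weights_lost=wl)) * 100
        rows[var] = entry
    df = pd.DataFrame.from_dict(rows, orient="index")
    return BalanceReport(wave=wave, table=df)


def multiwave_balance(
    table: CohortTable,
    specs: Sequence[VariableSpec],
    selected_variables: Sequence[str],
    waves: Sequence[str] | None = None,
    demographic_list: Sequence[str] | None = None,
    truncation: tuple[float, float] = (0.5, 99.5),
    scheme_name: str = "weighted",
    mode: str = "both_groups",
) -> tuple[dict[str, BalanceReport], pd.DataFrame]:
    """Refit the selected model at every wave and tabulate balance.

    Returns per-wave reports plus a long-format frame
    (variable, wave, scheme, abs_std_diff_pct) suitable for the dot-plot of
    balance across follow-up waves.
    """
    waves = list(waves) if waves is not None else table.wave_labels
    reports: dict[str, BalanceReport] = {}
    long_rows = []
    for wave in waves:
        _, ws = refit_for_wave(
            selected_variables, table, specs, wave, truncation=truncation
        )
        rep = balance_table(
            table,
            specs,
            wave,
            weight_sets={scheme_name: ws},
            demographic_list=demographic_list,
            mode=mode,
        )
        reports[wave] = rep
        for var, row in rep.table.iterrows():
            for scheme in rep.table.columns:
                long_rows.append(
                    {
                        "variable": var,
                        "wave": wave,
                        "scheme": scheme,
                        "abs_std_diff_pct": row[scheme],
                    }
                )
    return reports, pd.DataFrame(long_rows)


def plot_balance(report: BalanceReport, ax=None):
    """Dot plot of |d|% by variable and scheme with the 10% reference line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.35 * len(report.table) + 1.5))
    ypos = np.arange(len(report.table))
    for i, scheme in enumerate(report.schemes):
        ax.scatter(report.table[scheme], ypos, label=scheme, zorder=3)
    ax.axvline(report.threshold_pct, color="red", ls=":", lw=1)
    ax.set_yticks(ypos)
    ax.set_yticklabels(report.table.index)
    ax.set_xlabel("absolute standardized difference (%)")
    ax.set_title(f"wave {report.wave}")
    ax.legend()
    return ax
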