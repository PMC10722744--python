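"""Model/Results facade for participation modelling.

`ParticipationModel` is built from a prepared cohort table plus either a
curated variable list or the penalized theme-wise screening procedure;
`.fit()` returns a `ParticipationResults` carrying the ML logistic
estimates with standard errors, discrimination/calibration diagnostics, the
weight pipeline, balance diagnostics and a `summary()` table — the same
shape a statsmodels user expects from a fitted GLM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import assessment, balance, weighting
from .cohort import CohortTable, VariableSpec, prepare_for_modelling
from .selection import (
    SelectedModel,
    SelectionTrace,
    apriori_select,
    fit_logistic,
    lasso_select,
)
from .simulate import DEFAULT_APRIORI_VARIABLES


class ParticipationModel:
    """Logistic model of continued participation at one follow-up wave.

    Parameters
    ----------
    table, specs
        A *prepared* cohort (continuous candidates categorized, missingness
        recoded into explicit categories) and its dictionary; use
        ``prepare=True`` to run the preparation here.
    wave
        The follow-up wave whose participation indicator is the outcome.
    variables
        The predictor set. Use the constructors
        :meth:`from_curated_list` / :meth:`from_lasso_selection` for the two
        selection arms.
    """

    def __init__(
        self,
        table: CohortTable,
        specs: Sequence[VariableSpec],
        wave: str,
        variables: Sequence[str],
        prepare: bool = False,
        method: str = "custom",
    ):
        if prepare:
            table, specs = prepare_for_modelling(table, specs)
        self.table = table
        self.specs = list(specs)
        self.wave = wave
        self.variables = list(variables)
        self.method = method
        self._traces: dict[str, SelectionTrace] | None = None
        self._preselected: SelectedModel | None = None

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_curated_list(
        cls,
        table: CohortTable,
        specs: Sequence[VariableSpec],
        wave: str,
        curated_list: Sequence[str] | None = None,
        prepare: bool = False,
    ) -> "ParticipationModel":
        """Knowledge-based arm: the supplied list is used verbatim."""
        if curated_list is None:
            curated_list = [
                v for v in DEFAULT_APRIORI_VARIABLES
                if any(s.name == v for s in specs)
            ] or None
            if curated_list is None:
                raise ValueError("no curated list supplied and no default applies")
        variables = apriori_select(specs, curated_list)
        return cls(table, specs, wave, variables, prepare=prepare, method="apriori")

    @classmethod
    def from_lasso_selection(
        cls,
        table: CohortTable,
        specs: Sequence[VariableSpec],
        wave: str,
        k_folds: int = 10,
        alpha: float = 0.05,
        seed: int = 0,
        prepare: bool = False,
    ) -> "ParticipationModel":
        """Data-driven arm: theme-wise LASSO + ROC-gated forward selection."""
        if prepare:
            table, specs = prepare_for_modelling(table, specs)
        selected, traces = lasso_select(
            table, specs, wave, k_folds=k_folds, alpha=alpha, seed=seed
        )
        obj = cls(table, specs, wave, selected.variables, method="lasso")
        obj._traces = traces
        obj._preselected = selected
        return obj

    # -- fitting -----------------------------------------------------------
    def fit(self) -> "ParticipationResults":
        if self.variables:
            model, sm_res = fit_logistic(
                self.table, self.specs, self.variables, self.wave, method=self.method
            )
        else:
            model, sm_res = self._preselected, None
        return ParticipationResults(self, model, sm_res)


@dataclass
class ParticipationResults:
    """Fitted participation model with diagnostics and the weight pipeline."""

    model: ParticipationModel
    selected: SelectedModel
    _sm_results: object | None = None

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        names = ["const"] + [
            k for k in self.selected.coefficients
        ]
        vals = [self.selected.intercept] + list(self.selected.coefficients.values())
        return pd.Series(vals, index=names, name="coef")

    @property
    def bse(self) -> pd.Series | None:
        if self._sm_results is None:
            return None
        return pd.Series(
            np.asarray(self._sm_results.bse), index=self.params.index, name="se"
        )

    @property
    def traces(self) -> dict[str, SelectionTrace] | None:
        return self.model._traces

    # -- prediction & diagnostics -----------------------------------------
    def predict(self, table: CohortTable | None = None) -> pd.Series:
        return self.selected.predict_proba(table or self.model.table)

    def discrimination(self) -> assessment.DiscriminationReport:
        y = self.model.table.participation(self.model.wave).to_numpy()
        return assessment.auroc(self.predict().to_numpy(), y)

    def calibration(self, n_bins: int = 10, smoother_span: float = 0.75):
        probs = self.predict().to_numpy()
        y = self.model.table.participation(self.model.wave).to_numpy()
        stat, df, p = assessment.hosmer_lemeshow(probs, y, n_bins=n_bins)
        mean_pred, obs = assessment.mean_calibration(probs, y)
        curve = assessment.calibration_curve(probs, y, smoother_span=smoother_span)
        return assessment.CalibrationReport(
            hl_statistic=stat,
            hl_df=df,
            hl_p=p,
            mean_calibration=mean_pred,
            observed_rate=obs,
            curve_points=tuple(map(tuple, curve)),
        )

    # -- weights & balance --------------------------------------------------
    def weights(
        self, truncation: tuple[float, float] | None = (0.5, 99.5)
    ) -> weighting.WeightSet:
        p_hat = self.predict()
        ws = weighting.stabilized_weights(
            p_hat, self.model.table.participation(self.model.wave), wave=self.model.wave
        )
        if truncation is not None:
            ws = weighting.truncate_weights(ws, *truncation)
        return ws

    def balance(
        self,
        demographic_list: Sequence[str] | None = None,
        truncation: tuple[float, float] | None = (0.5, 99.5),
    ) -> balance.BalanceReport:
        return balance.balance_table(
            self.model.table,
            self.model.specs,
            self.model.wave,
            weight_sets={self.model.method: self.weights(truncation)},
            demographic_list=demographic_list,
        )

    def refit(self, wave: str) -> "ParticipationResults":
        """Same variable set, re-estimated against another wave's outcome."""
        m = ParticipationModel(
            self.model.table,
            self.model.specs,
            wave,
            self.model.variables,
            method=self.model.method,
        )
        return m.fit()

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        lines = []
        disc = self.discrimination()
        cal = self.calibration()
        ws = self.weights()
        lines.append("Participation model (" + self.model.method + " arm)")
        lines.append("=" * 64)
        lines.append(
            f"outcome wave: {self.model.wave}    n = {self.model.table.n_participants}"
            f"    continuing: {cal.observed_rate:.1%}"
        )
        lines.append(f"predictors: {len(self.model.variables)} variables")
        lines.append("-" * 64)
        params = self.params
        bse = self.bse
        lines.append(f"{'term':<40}{'coef':>10}{'se':>10}")
        for name in params.index:
            se = f"{bse[name]:>10.3f}" if bse is not None else f"{'':>10}"
            lines.append(f"{name:<40}{params[name]:>10.3f}{se}")
        lines.append("-" * 64)
        lines.append(
            f"AUROC {disc.auroc:.2f} (95% CI {disc.ci_low:.2f}-{disc.ci_high:.2f})"
        )
        lines.append(
            f"Hosmer-Lemeshow chi2 = {cal.hl_statistic:.2f}, "
            f"df = {cal.hl_df}, p = {cal.hl_p:.3f}"
        )
        lines.append(
            f"mean calibration {cal.mean_calibration:.3f} vs observed "
            f"{cal.observed_rate:.3f}"
        )
        s = ws.summary()
        b, a = s["before_truncation"], s.get("after_truncation")
        lines.append(
            f"stabilized weights: mean {b['mean']:.2f} (SD {b['sd']:.2f}), "
            f"range {b['min']:.2f}-{b['max']:.2f}"
        )
        if a:
            lines.append(
                f"after truncation:   mean {a['mean']:.2f} (SD {a['sd']:.2f}), "
                f"range {a['min']:.2f}-{a['max']:.2f}; "
                f"{s['n_altered']} weights altered"
            )
        return "\n".join(lines)
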