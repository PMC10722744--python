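"""Variable selection for the participation model.

Two arms are supported, mirroring common practice when building
non-response weights for a longitudinal cohort:

* a **curated (a-priori) arm**: investigators supply the variable list and
  no data-driven filtering happens — the artifact only validates the names
  and fits the logistic participation model on them;
* a **penalized screening arm**: within each of the seven context themes an
  L1-penalized (LASSO) logistic regression with 10-fold cross-validation
  screens candidates; variables are ranked by their largest standardized
  dummy coefficient; a forward pass starting from the top three adds one
  variable at a time and keeps going while the model AUROC improves
  significantly (paired DeLong test); theme winners are pooled into one
  final LASSO whose surviving variables enter an unpenalized logistic fit.

The stopping rule excludes the first variable whose addition does not
significantly change the ROC (two-sided p > alpha) and stops there.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import assessment
from ._design import column_name, drop_constant_columns, dummy_encode, spec_map
from .cohort import CohortTable, VariableSpec

logger = logging.getLogger(__name__)

__all__ = [
    "SelectedModel",
    "SelectionTrace",
    "LassoFit",
    "apriori_select",
    "fit_logistic",
    "fit_cv_lasso_logistic",
    "rank_variables_by_coefficient",
    "forward_auc_selection",
    "combine_and_finalize",
    "lasso_select",
]


@dataclass
class SelectedModel:
    """A chosen variable set with fitted unpenalized logistic coefficients."""

    variables: list[str]
    wave: str
    intercept: float
    coefficients: dict[str, float]
    design: list[tuple[str, str | None]]
    reference_levels: dict[str, str]
    method: str = "unspecified"

    def __post_init__(self) -> None:
        vals = [self.intercept, *self.coefficients.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite coefficient in SelectedModel")

    # -- prediction --------------------------------------------------------
    def linear_predictor(self, table: CohortTable) -> np.ndarray:
        eta = np.full(table.n_participants, self.intercept, dtype=float)
        seen_warn: set[str] = set()
        known: dict[str, set[str]] = {}
        for var, lv in self.design:
            if lv is not None:
                known.setdefault(var, set()).add(lv)
        for var, levels in known.items():
            ref = self.reference_levels.get(var)
            col = table.data[var]
            ok = levels | ({ref} if ref else set())
            bad = ~col.astype(str).isin(ok) & col.notna()
            if bad.any() and var not in seen_warn:
                warnings.warn(
                    f"variable {var!r}: {int(bad.sum())} unseen level value(s) "
                    "mapped to the reference level"
                )
                seen_warn.add(var)
        for var, lv in self.design:
            beta = self.coefficients[column_name(var, lv)]
            if lv is None:
                eta += beta * pd.to_numeric(table.data[var]).to_numpy(dtype=float)
            else:
                eta += beta * (table.data[var] == lv).to_numpy(dtype=float)
        return eta

    def predict_proba(self, table: CohortTable) -> pd.Series:
        return pd.Series(
            expit(self.linear_predictor(table)), index=table.data.index, name="p_hat"
        )

    # -- serialization -----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "variables": self.variables,
            "wave": self.wave,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "design": [[v, lv] for v, lv in self.design],
            "reference_levels": self.reference_levels,
            "method": self.method,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SelectedModel":
        with open(path) as fh:
            p = json.load(fh)
        p["design"] = [tuple(d) for d in p["design"]]
        return cls(**p)


@dataclass
class SelectionTrace:
    """Record of one theme's screening and forward-selection path."""

    theme: str
    penalized_coefficients: dict[str, float] = field(default_factory=dict)
    ranking: list[str] = field(default_factory=list)
    steps: list[dict] = field(default_factory=list)  # variable, auroc, p
    stopping_step: int | None = None
    winners: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "theme": self.theme,
            "penalized_coefficients": self.penalized_coefficients,
            "ranking": self.ranking,
            "steps": self.steps,
            "stopping_step": self.stopping_step,
            "winners": self.winners,
        }


@dataclass
class LassoFit:
    """Penalized coefficients at the CV-selected penalty (standardized scale)."""

    coefficients: pd.Series  # indexed by design column name
    intercept: float
    C: float  # sklearn inverse regularization strength at the optimum
    variables: list[str]
    design: list[tuple[str, str | None]]
    dropped_columns: list[str] = field(default_factory=list)

    def by_variable_max_abs(self) -> dict[str, float]:
        score: dict[str, float] = {}
        for (var, lv) in self.design:
            c = abs(self.coefficients[column_name(var, lv)])
            score[var] = max(score.get(var, 0.0), c)
        return score


# ---------------------------------------------------------------------------
# Curated arm
# ---------------------------------------------------------------------------

def apriori_select(
    specs: Sequence[VariableSpec], curated_list: Sequence[str]
) -> list[str]:
    """Validate and return the investigator-curated variable list verbatim.

    No data-driven filtering is applied — the curation is the selection.
    """
    if not curated_list:
        raise ValueError("curated list is empty: a participation model needs >= 1 predictor")
    names = {s.name for s in specs}
    unknown = [v for v in curated_list if v not in names]
    if unknown:
        raise KeyError(f"curated variables not in dictionary: {unknown}")
    return list(curated_list)


# ---------------------------------------------------------------------------
# Unpenalized logistic fit (the participation model itself)
# ---------------------------------------------------------------------------

def fit_logistic(
    table: CohortTable,
    specs: Sequence[VariableSpec],
    variables: Sequence[str],
    outcome_wave: str,
    method: str = "unspecified",
):
    """ML logistic fit of wave participation on the given variables.

    Returns ``(SelectedModel, statsmodels_results_or_None)``. On
    non-convergence or perfect separation the fit falls back to a
    ridge-stabilized logistic regression (small L2 penalty) with a warning;
    the second return value is then None.
    """
    import statsmodels.api as sm

    y = table.participation(outcome_wave).to_numpy()
    if y.min() == y.max():
        raise ValueError(f"outcome for wave {outcome_wave!r} is constant")
    X, info, refs = dummy_encode(table, specs, variables)
    X, info, dropped = drop_constant_columns(X, info)
    if dropped:
        logger.warning("dropped constant design columns: %s", dropped)

    Xc = sm.add_constant(X.to_numpy(), has_constant="add")
    sm_res = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=100)
        params = np.asarray(res.params)
        if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 50:
            raise RuntimeError("unstable ML fit")
        sm_res = res
        intercept, betas = float(params[0]), params[1:]
    except Exception:
        warnings.warn(
            "ML logistic fit unstable (possible separation); using a "
            "ridge-stabilized fit"
        )
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(penalty="l2", C=100.0, max_iter=2000)
        lr.fit(X.to_numpy(), y)
        intercept, betas = float(lr.intercept_[0]), lr.coef_[0]

    model = SelectedModel(
        variables=list(variables),
        wave=outcome_wave,
        intercept=intercept,
        coefficients={
            column_name(v, lv): float(b) for (v, lv), b in zip(info, betas)
        },
        design=list(info),
        reference_levels=refs,
        method=method,
    )
    return model, sm_res


# ---------------------------------------------------------------------------
# Penalized screening arm
# ---------------------------------------------------------------------------

def fit_cv_lasso_logistic(
    table: CohortTable,
    specs: Sequence[VariableSpec],
    variables: Sequence[str],
    outcome_wave: str,
    k_folds: int = 10,
    seed: int = 0,
    n_penalties: int = 12,
) -> LassoFit:
    """L1-penalized logistic regression with stratified k-fold CV.

    Dummy-encoded predictors are centered and scaled to unit variance
    before penalization so coefficient magnitudes are comparable across
    variables; the penalty minimizing mean cross-validated deviance
    (log loss) is selected. Fold assignment is deterministic given ``seed``.
    """
    from sklearn.linear_model import LogisticRegressionCV
    from sklearn.model_selection import StratifiedKFold

    y = table.participation(outcome_wave).to_numpy()
    if y.min() == y.max():
        raise ValueError(f"outcome for wave {outcome_wave!r} is constant")
    X, info, _ = dummy_encode(table, specs, variables)
    X, info, dropped = drop_constant_columns(X, info)
    if dropped:
        logger.warning("constant predictors dropped before LASSO: %s", dropped)
    Xs = X.to_numpy()
    Xs = (Xs - Xs.mean(axis=0)) / Xs.std(axis=0)

    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    clf = LogisticRegressionCV(
        Cs=np.logspace(-3, 1.5, n_penalties),
        cv=cv,
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",
        refit=True,
        max_iter=500,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Xs, y)
    coefs = pd.Series(clf.coef_[0], index=X.columns)
    return LassoFit(
        coefficients=coefs,
        intercept=float(clf.intercept_[0]),
        C=float(clf.C_[0]),
        variables=[v for v in variables if any(var == v for var, _ in info)],
        design=list(info),
        dropped_columns=dropped,
    )


def rank_variables_by_coefficient(
    lasso_fit: LassoFit, specs: Sequence[VariableSpec]
) -> list[str]:
    """Order variables by their largest absolute penalized dummy coefficient.

    A multi-level categorical variable is scored by the max |coefficient|
    over its levels (a single influential level keeps the whole variable).
    Variables whose every coefficient is zero are excluded; ties break by
    dictionary order.
    """
    dict_order = {s.name: i for i, s in enumerate(specs)}
    scores = lasso_fit.by_variable_max_abs()
    ranked = [v for v in scores if scores[v] > 0]
    ranked.sort(key=lambda v: (-scores[v], dict_order.get(v, np.inf)))
    return ranked


def forward_auc_selection(
    table: CohortTable,
    specs: Sequence[VariableSpec],
    ranked_vars: Sequence[str],
    outcome_wave: str,
    alpha: float = 0.05,
    theme: str = "",
    penalized_coefficients: dict[str, float] | None = None,
) -> tuple[list[str], SelectionTrace]:
    """ROC-gated forward inclusion along a coefficient ranking.

    Starts from the top three ranked variables (all of them when fewer),
    then adds the next-ranked variable one at a time, comparing the new
    model's AUROC with the previous one by the paired DeLong test. The
    first addition whose ROC is *not* significantly different (p > alpha)
    is excluded and the pass stops there.
    """
    if not ranked_vars:
        raise ValueError("ranked variable list is empty")
    trace = SelectionTrace(
        theme=theme,
        ranking=list(ranked_vars),
        penalized_coefficients=dict(penalized_coefficients or {}),
    )
    y = table.participation(outcome_wave).to_numpy()

    current = list(ranked_vars[: min(3, len(ranked_vars))])
    model, _ = fit_logistic(table, specs, current, outcome_wave)
    scores = model.predict_proba(table).to_numpy()
    auc = assessment.auroc(scores, y).auroc
    trace.steps.append({"variable": ",".join(current), "auroc": auc, "p": None})

    for step, var in enumerate(ranked_vars[len(current):], start=1):
        cand = current + [var]
        cand_model, _ = fit_logistic(table, specs, cand, outcome_wave)
        cand_scores = cand_model.predict_proba(table).to_numpy()
        cand_auc = assessment.auroc(cand_scores, y).auroc
        _, p = assessment.delong_paired_test(cand_scores, scores, y)
        trace.steps.append({"variable": var, "auroc": cand_auc, "p": p})
        if p > alpha:
            trace.stopping_step = step
            break
        current, scores = cand, cand_scores
    else:
        trace.stopping_step = len(trace.steps) - 1

    trace.winners = current
    return current, trace


def combine_and_finalize(
    table: CohortTable,
    specs: Sequence[VariableSpec],
    per_theme_winners: dict[str, list[str]] | Sequence[str],
    outcome_wave: str,
    k_folds: int = 10,
    seed: int = 0,
) -> SelectedModel:
    """Pool theme winners into one LASSO; keep survivors; fit unpenalized.

    The pooled LASSO re-tunes its penalty by cross-validation. Variables
    with at least one nonzero level coefficient are retained and passed to
    an unpenalized ML logistic fit, which is the final participation model.
    An all-zero pooled fit falls back to an intercept-only model.
    """
    if isinstance(per_theme_winners, dict):
        union: list[str] = []
        for winners in per_theme_winners.values():
            union.extend(v for v in winners if v not in union)
    else:
        union = list(dict.fromkeys(per_theme_winners))
    if not union:
        raise ValueError("no candidate winners to combine")

    pooled = fit_cv_lasso_logistic(
        table, specs, union, outcome_wave, k_folds=k_folds, seed=seed
    )
    scores = pooled.by_variable_max_abs()
    retained = [v for v in union if scores.get(v, 0.0) > 0]
    if not retained:
        warnings.warn("pooled LASSO shrank every coefficient to zero; "
                      "falling back to an intercept-only model")
        y = table.participation(outcome_wave)
        p = y.mean()
        return SelectedModel(
            variables=[],
            wave=outcome_wave,
            intercept=float(np.log(p / (1 - p))),
            coefficients={},
            design=[],
            reference_levels={},
            method="lasso",
        )
    model, _ = fit_logistic(table, specs, retained, outcome_wave, method="lasso")
    return model


def lasso_select(
    table: CohortTable,
    specs: Sequence[VariableSpec],
    outcome_wave: str,
    k_folds: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
    candidate_roles: tuple[str, ...] = ("candidate", "demographic"),
) -> tuple[SelectedModel, dict[str, SelectionTrace]]:
    """The full theme-wise screening pipeline.

    Per theme: CV LASSO -> coefficient ranking -> ROC-gated forward pass.
    Theme winners are pooled and finalized by :func:`combine_and_finalize`.
    """
    traces: dict[str, SelectionTrace] = {}
    winners: dict[str, list[str]] = {}
    themes = list(dict.fromkeys(s.theme for s in specs if s.role in candidate_roles))
    for ti, theme in enumerate(themes):
        theme_vars = [
            s.name for s in specs if s.theme == theme and s.role in candidate_roles
        ]
        if not theme_vars:
            continue
        lasso = fit_cv_lasso_logistic(
            table, specs, theme_vars, outcome_wave, k_folds=k_folds, seed=seed + ti
        )
        ranked = rank_variables_by_coefficient(lasso, specs)
        if not ranked:
            traces[theme] = SelectionTrace(theme=theme, stopping_step=0)
            winners[theme] = []
            continue
        w, trace = forward_auc_selection(
            table,
            specs,
            ranked,
            outcome_wave,
            alpha=alpha,
            theme=theme,
            penalized_coefficients={
                k: float(v) for k, v in lasso.coefficients.items() if v != 0
            },
        )
        traces[theme] = trace
        winners[theme] = w

    model = combine_and_finalize(
        table, specs, winners, outcome_wave, k_folds=k_folds, seed=seed + 1000
    )
    return model, traces
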