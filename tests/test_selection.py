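"""Both selection arms: curated list, and LASSO + ROC-gated forward pass."""

import numpy as np
import pandas as pd
import pytest

from attriweight import CohortTable, VariableSpec
from attriweight.selection import (
    LassoFit,
    apriori_select,
    combine_and_finalize,
    fit_cv_lasso_logistic,
    forward_auc_selection,
    rank_variables_by_coefficient,
)
from attriweight.simulate import DEFAULT_APRIORI_VARIABLES

from conftest import TRUE_DRIVERS


def _binary_cohort(rng, n, n_vars, effects, wave="w", prevalence=None):
    """Independent binary candidates with a logistic outcome."""
    data, specs = {}, []
    eta = np.zeros(n)
    for j in range(n_vars):
        p = prevalence[j] if prevalence else 0.5
        x = (rng.random(n) < p).astype(int)
        name = f"v{j:02d}"
        data[name] = np.where(x == 1, "yes", "no")
        specs.append(
            VariableSpec(
                name=name, theme="sociodemographic", vtype="categorical",
                levels=("no", "yes"),
            )
        )
        eta = eta + effects.get(name, 0.0) * x
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    df = pd.DataFrame(data, index=[f"p{i}" for i in range(n)])
    waves = pd.DataFrame({wave: y}, index=df.index)
    return CohortTable(df, waves), specs


class TestApriori:
    def test_default_curated_list_has_18_variables(self, default_cohort):
        _, specs, _ = default_cohort
        selected = apriori_select(specs, DEFAULT_APRIORI_VARIABLES)
        assert len(selected) == 18
        assert selected == list(DEFAULT_APRIORI_VARIABLES)

    def test_typo_is_named_in_error(self, default_cohort):
        _, specs, _ = default_cohort
        with pytest.raises(KeyError, match="edcuation"):
            apriori_select(specs, ["edcuation", "income"])

    def test_empty_list_rejected(self, default_cohort):
        _, specs, _ = default_cohort
        with pytest.raises(ValueError, match="empty"):
            apriori_select(specs, [])


class TestCvLasso:
    def test_pure_noise_shrinks_to_zero(self):
        rng = np.random.default_rng(2)
        table, specs = _binary_cohort(rng, 500, 20, effects={})
        fit = fit_cv_lasso_logistic(
            table, specs, [s.name for s in specs], "w", seed=2
        )
        assert fit.coefficients.abs().max() <= 0.05

    def test_strong_predictor_dominates(self):
        """Majority over seeds: the true log-odds-1.5 signal ranks first."""
        wins = 0
        for seed in range(7):
            rng = np.random.default_rng(1000 + seed)
            table, specs = _binary_cohort(rng, 2000, 20, effects={"v00": 1.5})
            fit = fit_cv_lasso_logistic(
                table, specs, [s.name for s in specs], "w", seed=seed
            )
            scores = fit.by_variable_max_abs()
            wins += max(scores, key=scores.get) == "v00"
        assert wins >= 4

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        table, specs = _binary_cohort(rng, 600, 8, effects={"v01": 0.8})
        f1 = fit_cv_lasso_logistic(table, specs, [s.name for s in specs], "w", seed=9)
        f2 = fit_cv_lasso_logistic(table, specs, [s.name for s in specs], "w", seed=9)
        assert f1.C == f2.C
        pd.testing.assert_series_equal(f1.coefficients, f2.coefficients)

    def test_constant_outcome_rejected(self):
        rng = np.random.default_rng(6)
        table, specs = _binary_cohort(rng, 100, 3, effects={})
        table.waves["w"] = 1
        table = CohortTable(table.data, table.waves)
        with pytest.raises(ValueError, match="constant"):
            fit_cv_lasso_logistic(table, specs, [s.name for s in specs], "w")


class TestRanking:
    def _fit(self, coef_map, variables, design):
        return LassoFit(
            coefficients=pd.Series(coef_map),
            intercept=0.0, C=1.0, variables=variables, design=design,
        )

    def test_max_rule_over_levels(self):
        fit = self._fit(
            {"A__x": 0.9, "A__y": 0.1, "B__x": -0.5},
            ["A", "B"], [("A", "x"), ("A", "y"), ("B", "x")],
        )
        specs = [
            VariableSpec(name=n, theme="sociodemographic", vtype="categorical",
                         levels=("r", "x", "y"))
            for n in ("A", "B")
        ]
        assert rank_variables_by_coefficient(fit, specs) == ["A", "B"]

    def test_all_zero_gives_empty_ranking(self):
        fit = self._fit({"A__x": 0.0}, ["A"], [("A", "x")])
        specs = [VariableSpec(name="A", theme="sociodemographic",
                              vtype="categorical", levels=("r", "x"))]
        assert rank_variables_by_coefficient(fit, specs) == []

    def test_tie_breaks_by_dictionary_order(self):
        fit = self._fit(
            {"B__x": 0.5, "A__x": -0.5},
            ["B", "A"], [("B", "x"), ("A", "x")],
        )
        specs = [
            VariableSpec(name=n, theme="sociodemographic", vtype="categorical",
                         levels=("r", "x"))
            for n in ("A", "B")  # dictionary order: A before B
        ]
        assert rank_variables_by_coefficient(fit, specs) == ["A", "B"]


class TestForwardSelection:
    def test_three_candidates_means_no_comparisons(self):
        rng = np.random.default_rng(8)
        table, specs = _binary_cohort(rng, 400, 3, effects={"v00": 1.0})
        winners, trace = forward_auc_selection(
            table, specs, ["v00", "v01", "v02"], "w"
        )
        assert winners == ["v00", "v01", "v02"]
        assert len(trace.steps) == 1 and trace.steps[0]["p"] is None

    def test_noise_fourth_variable_excluded(self):
        """Majority over seeds: a null 4th-ranked variable stops the pass."""
        stops = 0
        for seed in range(7):
            rng = np.random.default_rng(2000 + seed)
            table, specs = _binary_cohort(
                rng, 3351, 5,
                effects={"v00": 0.9, "v01": 0.7, "v02": 0.5},
            )
            winners, trace = forward_auc_selection(
                table, specs, ["v00", "v01", "v02", "v03", "v04"], "w"
            )
            if winners == ["v00", "v01", "v02"]:
                stops += 1
        assert stops >= 4

    def test_signal_fourth_variable_admitted(self):
        """Majority over seeds: a true log-odds-1.0 variable gets in."""
        admitted = 0
        for seed in range(7):
            rng = np.random.default_rng(3000 + seed)
            table, specs = _binary_cohort(
                rng, 3351, 4,
                effects={"v00": 0.9, "v01": 0.8, "v02": 0.7, "v03": 1.0},
            )
            winners, _ = forward_auc_selection(
                table, specs, ["v00", "v01", "v02", "v03"], "w"
            )
            admitted += "v03" in winners
        assert admitted >= 4

    def test_winners_are_prefix_of_ranking(self, lasso_results):
        for theme, trace in lasso_results.traces.items():
            if trace.winners:
                assert trace.winners == trace.ranking[: len(trace.winners)]

    def test_trace_records_every_step(self, lasso_results):
        for trace in lasso_results.traces.values():
            if not trace.ranking:
                continue
            assert trace.stopping_step is not None
            aucs = [s["auroc"] for s in trace.steps]
            assert all(0.45 <= a <= 1.0 for a in aucs)


class TestCombine:
    def test_disjoint_strong_signals_both_retained(self):
        kept = 0
        for seed in range(5):
            rng = np.random.default_rng(4000 + seed)
            table, specs = _binary_cohort(
                rng, 2000, 10, effects={"v00": 1.2, "v07": 1.2}
            )
            model = combine_and_finalize(
                table, specs, {"t1": ["v00", "v03"], "t2": ["v07", "v05"]},
                "w", seed=seed,
            )
            kept += {"v00", "v07"} <= set(model.variables)
        assert kept >= 3

    def test_all_noise_falls_back_to_intercept_only(self):
        rng = np.random.default_rng(40000)
        table, specs = _binary_cohort(rng, 400, 6, effects={})
        with pytest.warns(UserWarning, match="intercept-only"):
            model = combine_and_finalize(
                table, specs, ["v00", "v01", "v02"], "w", seed=0
            )
        assert model.variables == []
        p = table.waves["w"].mean()
        assert model.intercept == pytest.approx(np.log(p / (1 - p)), abs=1e-9)


class TestEndToEnd:
    def test_true_predictors_recovered_across_seeds(self, recovery_runs):
        """The five real dropout drivers survive the whole pipeline >= 80%."""
        hits = sum(
            TRUE_DRIVERS <= set(model.variables) for model, _ in recovery_runs
        )
        assert hits / len(recovery_runs) >= 0.8

    def test_selected_model_size_is_plausible(self, recovery_runs):
        # roughly two dozen retained variables, never the full dictionary
        for model, _ in recovery_runs:
            assert 5 <= len(model.variables) <= 45
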