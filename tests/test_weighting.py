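"""Stabilized weights, truncation, and later-wave refits."""

import numpy as np
import pandas as pd
import pytest

from attriweight import ParticipationModel, stabilized_weights, truncate_weights
from attriweight.selection import SelectedModel, fit_logistic
from attriweight.weighting import predict_probabilities, refit_for_wave


def _series(vals, prefix="p"):
    return pd.Series(vals, index=[f"{prefix}{i}" for i in range(len(vals))])


class TestPredict:
    def test_intercept_only_gives_half(self, mini_cohort):
        table, _ = mini_cohort
        m = SelectedModel(
            variables=[], wave="3y", intercept=0.0, coefficients={},
            design=[], reference_levels={}, method="test",
        )
        p = predict_probabilities(m, table)
        assert (p == 0.5).all()

    def test_two_predictor_closed_form(self, mini_cohort):
        table, _ = mini_cohort
        table = table.copy()
        table.data["colour"] = table.data["colour"].fillna("red")
        table.data["age"] = table.data["age"].fillna(30.0)
        m = SelectedModel(
            variables=["colour", "age"], wave="3y", intercept=-1.0,
            coefficients={"colour__green": 0.7, "colour__blue": -0.3, "age": 0.05},
            design=[("colour", "green"), ("colour", "blue"), ("age", None)],
            reference_levels={"colour": "red"}, method="test",
        )
        p = predict_probabilities(m, table)
        # participant p1: green, age 31.5
        eta = -1.0 + 0.7 + 0.05 * 31.5
        assert p["p1"] == pytest.approx(1 / (1 + np.exp(-eta)), abs=1e-12)
        # participant p0: red (reference), age 25
        eta0 = -1.0 + 0.05 * 25.0
        assert p["p0"] == pytest.approx(1 / (1 + np.exp(-eta0)), abs=1e-12)

    def test_monotone_in_positive_coefficient(self, mini_cohort):
        table, _ = mini_cohort
        table = table.copy()
        table.data["age"] = [20.0, 25.0, 30.0, 35.0, 40.0]
        m = SelectedModel(
            variables=["age"], wave="3y", intercept=0.0,
            coefficients={"age": 0.1}, design=[("age", None)],
            reference_levels={}, method="test",
        )
        p = predict_probabilities(m, table)
        assert (np.diff(p.to_numpy()) > 0).all()

    def test_unseen_level_maps_to_reference_with_warning(self, mini_cohort):
        table, _ = mini_cohort
        table = table.copy()
        table.data["colour"] = ["red", "magenta", "red", "blue", "green"]
        m = SelectedModel(
            variables=["colour"], wave="3y", intercept=0.0,
            coefficients={"colour__green": 1.0, "colour__blue": 2.0},
            design=[("colour", "green"), ("colour", "blue")],
            reference_levels={"colour": "red"}, method="test",
        )
        with pytest.warns(UserWarning, match="unseen"):
            p = m.predict_proba(table)
        assert p["p1"] == p["p0"]  # magenta treated as reference


class TestStabilized:
    def test_weights_are_one_when_phat_equals_pbar(self):
        part = _series([1, 1, 1, 0])
        p_hat = _series([0.75] * 4)
        ws = stabilized_weights(p_hat, part)
        assert np.allclose(ws.sw, 1.0)

    def test_saturated_two_strata_hand_case(self):
        # stratum A: n=4, 2 respond, p_hat=0.5; stratum B: n=4, all respond, p_hat=1
        p_hat = _series([0.5] * 4 + [1.0] * 4)
        part = _series([1, 1, 0, 0, 1, 1, 1, 1])
        ws = stabilized_weights(p_hat, part)
        assert ws.p_bar == 0.75
        w = ws.weights.to_numpy()
        assert np.allclose(sorted(w), [0.75] * 4 + [1.5] * 2)
        assert w.mean() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_probabilities_rejected(self):
        with pytest.raises(ValueError, match="ridge"):
            stabilized_weights(_series([0.0, 0.5]), _series([1, 0]))
        with pytest.raises(ValueError, match="ridge"):
            # p_hat = 1 for an actual drop-out explodes the mirror weight
            stabilized_weights(_series([1.0, 0.5]), _series([0, 1]))

    def test_mean_near_one_on_default_cohort(self, prepared_default):
        ptable, pspecs = prepared_default
        pm = ParticipationModel.from_curated_list(ptable, pspecs, "3y")
        ws = pm.fit().weights(truncation=None)
        assert ws.weights.mean() == pytest.approx(1.0, abs=0.02)

    def test_stabilized_variance_below_unstabilized(self, prepared_default):
        ptable, pspecs = prepared_default
        pm = ParticipationModel.from_curated_list(ptable, pspecs, "3y")
        ws = pm.fit().weights(truncation=None)
        raw = 1.0 / ws.p_hat.loc[ws.responders]
        assert ws.weights.var() < raw.var()


class TestTruncation:
    def test_constant_vector_unchanged(self):
        ws = stabilized_weights(_series([0.6] * 10), _series([1] * 6 + [0] * 4))
        t = truncate_weights(ws)
        assert t.n_altered == 0
        assert np.allclose(t.sw_truncated, t.sw)

    def test_altered_count_matches_sort_and_count_oracle(self):
        rng = np.random.default_rng(17)
        p_hat = _series(rng.uniform(0.05, 0.95, 1000))
        part = _series((rng.random(1000) < p_hat).astype(int))
        ws = stabilized_weights(p_hat, part)
        t = truncate_weights(ws, 0.5, 99.5)
        w = np.sort(ws.sw.to_numpy())
        low, high = np.percentile(w, [0.5, 99.5], method="linear")
        oracle = int(((w < low) | (w > high)).sum())
        assert t.n_altered == oracle
        assert set(t.altered_ids) == set(
            ws.sw.index[(ws.sw < low) | (ws.sw > high)]
        )

    def test_truncation_is_idempotent_and_bounded(self):
        rng = np.random.default_rng(23)
        p_hat = _series(rng.beta(2, 5, 500).clip(0.02, 0.98))
        part = _series((rng.random(500) < p_hat).astype(int))
        ws = stabilized_weights(p_hat, part)
        t1 = truncate_weights(ws)
        assert t1.sw_truncated.max() <= ws.sw.max()
        assert t1.sw_truncated.min() >= ws.sw.min()
        low, high = t1.bounds
        assert ((t1.sw_truncated >= low) & (t1.sw_truncated <= high)).all()
        t2 = truncate_weights(
            stabilized_weights(t1.sw_truncated * 0 + p_hat, part)
        )
        # re-truncating the already-truncated vector changes nothing
        retr = t1.sw_truncated.clip(lower=low, upper=high)
        assert np.allclose(retr, t1.sw_truncated)

    def test_one_sided_truncation(self):
        rng = np.random.default_rng(29)
        p_hat = _series(rng.uniform(0.05, 0.95, 400))
        part = _series((rng.random(400) < 0.6).astype(int))
        ws = stabilized_weights(p_hat, part)
        t = truncate_weights(ws, low_pct=0.0, high_pct=99.5)
        assert t.sw_truncated.min() == ws.sw.min()

    def test_invalid_percentiles(self):
        ws = stabilized_weights(_series([0.5, 0.6]), _series([1, 0]))
        with pytest.raises(ValueError):
            truncate_weights(ws, 99.5, 0.5)


class TestRefit:
    def test_refit_same_wave_is_idempotent(self, prepared_default, lasso_results):
        ptable, pspecs = prepared_default
        sel = lasso_results.selected
        m1, _ = refit_for_wave(sel.variables, ptable, pspecs, "3y", truncation=None)
        assert m1.coefficients == pytest.approx(sel.coefficients, rel=1e-6)

    def test_refit_auroc_stable_across_waves(self, prepared_default, lasso_results):
        """Same dropout mechanism at every wave: discrimination holds up."""
        from attriweight.assessment import auroc

        ptable, pspecs = prepared_default
        sel = lasso_results.selected
        aucs = []
        for wave in ("3y", "5y"):
            m, ws = refit_for_wave(sel.variables, ptable, pspecs, wave)
            y = ptable.participation(wave).to_numpy()
            aucs.append(auroc(ws.p_hat.to_numpy(), y).auroc)
        assert abs(aucs[0] - aucs[1]) < 0.05

    def test_refit_tracks_changed_mechanism(self):
        """When a later wave's dropout flips sign, the refit follows it."""
        import statsmodels.api as sm
        from attriweight import (
            GeneratorConfig,
            TrueModel,
            generate_baseline,
            simulate_participation,
        )
        from conftest import SMALL_ALLOCATION

        cfg = GeneratorConfig(
            n_participants=30_000, theme_allocation=SMALL_ALLOCATION,
            missing_rate_range=(0.0, 0.0), seed=31,
            wave_labels=("w1",), continuation_targets=(0.6,),
        )
        table, specs = generate_baseline(cfg)
        pos = TrueModel(
            effects={"maternal_age": {"type": "continuous", "slope": 0.5, "missing": 0.0}},
            targets=(0.6,), wave_labels=("w1",),
        )
        neg = TrueModel(
            effects={"maternal_age": {"type": "continuous", "slope": -0.5, "missing": 0.0}},
            targets=(0.6,), wave_labels=("w2",),
        )
        t1 = simulate_participation(table, pos, seed=1)
        t2 = simulate_participation(table, neg, seed=2)
        both = t1.copy()
        both.waves["w2"] = t2.waves["w2"]
        from attriweight.cohort import CohortTable, prepare_for_modelling

        both = CohortTable(both.data, both.waves)
        ptable, pspecs = prepare_for_modelling(both, specs)
        m1, _ = refit_for_wave(["maternal_age"], ptable, pspecs, "w1", truncation=None)
        m2, _ = refit_for_wave(["maternal_age"], ptable, pspecs, "w2", truncation=None)
        # highest age bracket: strongly positive under w1, strongly negative under w2
        top_key = [k for k in m1.coefficients if k.startswith("maternal_age__ge")][0]
        assert m1.coefficients[top_key] > 0.5
        assert m2.coefficients[top_key] < -0.5
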