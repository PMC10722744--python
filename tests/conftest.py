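"""Shared fixtures: hand-built mini cohorts and the default synthetic run.

Expensive artifacts (the default n=3,351 cohort, its prepared form and the
LASSO-selected participation model) are session-scoped so the many tests
that exercise them pay the cost once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from attriweight import (
    CohortTable,
    GeneratorConfig,
    ParticipationModel,
    VariableSpec,
    generate_cohort,
    prepare_for_modelling,
)

DEFAULT_SEED = 7

#: The five variables carrying nonzero dropout effects in the default scenario.
TRUE_DRIVERS = {
    "education",
    "income",
    "maternal_age",
    "depression_score",
    "cigarettes_per_day",
}

#: Compact dictionary that still contains all five driver variables.
SMALL_ALLOCATION = {
    "sociodemographic": 5,
    "pregnancy_history": 1,
    "conception_history": 1,
    "prenatal_care": 1,
    "lifestyle_health_care_use": 1,
    "mental_health_social_support": 2,
    "substance_use": 2,
}


@pytest.fixture
def mini_cohort():
    """Five participants, one categorical + one continuous variable, one wave."""
    specs = [
        VariableSpec(
            name="colour",
            theme="sociodemographic",
            vtype="categorical",
            levels=("red", "green", "blue"),
        ),
        VariableSpec(name="age", theme="sociodemographic", vtype="continuous"),
    ]
    data = pd.DataFrame(
        {
            "colour": ["red", "green", np.nan, "blue", np.nan],
            "age": [25.0, 31.5, 29.0, np.nan, 40.0],
        },
        index=pd.Index([f"p{i}" for i in range(5)], name="participant_id"),
    )
    waves = pd.DataFrame({"3y": [1, 0, 1, 1, 0]}, index=data.index)
    return CohortTable(data, waves), specs


@pytest.fixture(scope="session")
def default_cohort():
    """The default study scenario: n=3,351, 127 variables, 4 waves."""
    table, specs, truth = generate_cohort(GeneratorConfig(seed=DEFAULT_SEED))
    return table, specs, truth


@pytest.fixture(scope="session")
def prepared_default(default_cohort):
    table, specs, _ = default_cohort
    return prepare_for_modelling(table, specs)


@pytest.fixture(scope="session")
def lasso_results(prepared_default):
    """LASSO-selected participation model fitted at the first follow-up."""
    ptable, pspecs = prepared_default
    pm = ParticipationModel.from_lasso_selection(
        ptable, pspecs, "3y", seed=DEFAULT_SEED
    )
    return pm.fit()


@pytest.fixture(scope="session")
def recovery_runs():
    """End-to-end LASSO selections over eight fixed seeds (frozen regression)."""
    from attriweight.selection import lasso_select

    out = []
    for seed in range(1, 9):
        table, specs, truth = generate_cohort(GeneratorConfig(seed=seed))
        ptable, pspecs = prepare_for_modelling(table, specs)
        model, traces = lasso_select(ptable, pspecs, "3y", seed=seed)
        out.append((model, traces))
    return out
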