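"""Synthetic multi-wave pregnancy-cohort generator.

Real baseline data from the motivating cohort are not public, so every
downstream stage (variable preparation, penalized screening, participation
models, weights, balance diagnostics) is exercised on synthetic cohorts that
mimic the statistical structure the analysis assumes:

* ~3,351 participants and 127 mixed categorical/continuous baseline
  variables grouped into seven context themes;
* within-theme correlation induced by one shared latent factor per theme;
* item missingness at per-variable rates up to 4.4%;
* covariate-driven monotone dropout across four follow-up waves
  (labelled 3y/5y/8y/covid), with the marginal continuation rate at the
  first follow-up calibrated to 59.4% and later waves to 55/50/45% of the
  baseline sample.

The dropout mechanism (the "true model") is stored verbatim alongside the
generated table so tests can do parameter recovery and oracle checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import MISSING_LEVEL, THEMES, CohortTable, VariableSpec

DEFAULT_WAVE_LABELS = ("3y", "5y", "8y", "covid")
#: Marginal continuation targets (fraction of the baseline sample) per wave.
DEFAULT_CONTINUATION_TARGETS = (0.594, 0.55, 0.50, 0.45)

#: Variables per theme in the default dictionary (sums to 127).
DEFAULT_THEME_ALLOCATION = {
    "sociodemographic": 24,
    "pregnancy_history": 15,
    "conception_history": 12,
    "prenatal_care": 14,
    "lifestyle_health_care_use": 22,
    "mental_health_social_support": 22,
    "substance_use": 18,
}

# name, theme, vtype, level labels + marginal probs (categorical) or
# (location, scale) (continuous), role
_NAMED_VARIABLES: list[dict] = [
    # --- sociodemographic -------------------------------------------------
    dict(name="education", theme="sociodemographic", vtype="categorical",
         levels=("less_than_high_school", "high_school", "some_college",
                 "university"),
         probs=(0.06, 0.22, 0.33, 0.39), role="demographic"),
    dict(name="income", theme="sociodemographic", vtype="categorical",
         levels=("lt_40k", "40_to_60k", "60_to_80k", "80_to_100k", "ge_100k"),
         probs=(0.13, 0.17, 0.21, 0.21, 0.28), role="demographic"),
    dict(name="home_ownership", theme="sociodemographic", vtype="categorical",
         levels=("rent", "own"), probs=(0.27, 0.73), role="demographic"),
    dict(name="ethnicity", theme="sociodemographic", vtype="categorical",
         levels=("group_a", "group_b", "group_c", "group_d"),
         probs=(0.72, 0.12, 0.09, 0.07), role="demographic"),
    dict(name="maternal_age", theme="sociodemographic", vtype="continuous",
         loc=31.0, scale=4.4, role="demographic"),
    dict(name="paternal_age", theme="sociodemographic", vtype="continuous",
         loc=33.2, scale=5.1, role="demographic"),
    dict(name="marital_status", theme="sociodemographic", vtype="categorical",
         levels=("married_or_common_law", "single", "other"),
         probs=(0.90, 0.07, 0.03), role="demographic"),
    dict(name="household_size", theme="sociodemographic", vtype="continuous",
         loc=3.1, scale=1.0, role="demographic"),
    dict(name="new_canadian", theme="sociodemographic", vtype="categorical",
         levels=("no", "yes"), probs=(0.84, 0.16), role="demographic"),
    dict(name="food_insecurity", theme="sociodemographic", vtype="categorical",
         levels=("no", "yes"), probs=(0.93, 0.07), role="demographic"),
    # --- pregnancy history ------------------------------------------------
    dict(name="parity", theme="pregnancy_history", vtype="categorical",
         levels=("nulliparous", "one", "two_plus"),
         probs=(0.52, 0.33, 0.15), role="demographic"),
    dict(name="previous_pregnancies", theme="pregnancy_history",
         vtype="continuous", loc=1.1, scale=1.2),
    dict(name="adverse_outcome_history", theme="pregnancy_history",
         vtype="categorical", levels=("no", "yes"), probs=(0.69, 0.31)),
    dict(name="maternal_preterm_birth", theme="pregnancy_history",
         vtype="categorical", levels=("no", "yes"), probs=(0.91, 0.09)),
    # --- conception history -----------------------------------------------
    dict(name="conception_aid_use", theme="conception_history",
         vtype="categorical", levels=("no", "yes"), probs=(0.89, 0.11)),
    dict(name="trying_to_conceive", theme="conception_history",
         vtype="categorical", levels=("no", "yes"), probs=(0.25, 0.75)),
    dict(name="fertility_treatments", theme="conception_history",
         vtype="categorical", levels=("none", "one", "multiple"),
         probs=(0.91, 0.06, 0.03)),
    # --- prenatal care ----------------------------------------------------
    dict(name="prenatal_visits", theme="prenatal_care", vtype="continuous",
         loc=11.0, scale=3.0),
    dict(name="first_prenatal_visit_week", theme="prenatal_care",
         vtype="continuous", loc=9.0, scale=3.2),
    dict(name="dental_visit_past_year", theme="prenatal_care",
         vtype="categorical", levels=("no", "yes"), probs=(0.33, 0.67)),
    dict(name="difficulty_obtaining_care", theme="prenatal_care",
         vtype="categorical", levels=("no", "yes"), probs=(0.94, 0.06)),
    # --- lifestyle / health-care use ---------------------------------------
    dict(name="fruit_veg_servings", theme="lifestyle_health_care_use",
         vtype="continuous", loc=4.2, scale=1.8),
    dict(name="provider_visit_after_pregnancy",
         theme="lifestyle_health_care_use", vtype="categorical",
         levels=("no", "yes"), probs=(0.08, 0.92)),
    # --- mental health / social support -------------------------------------
    dict(name="depression_score", theme="mental_health_social_support",
         vtype="continuous", loc=4.5, scale=3.4, role="demographic"),
    dict(name="anxiety_score", theme="mental_health_social_support",
         vtype="continuous", loc=35.0, scale=9.0, role="demographic"),
    dict(name="perceived_stress", theme="mental_health_social_support",
         vtype="continuous", loc=13.0, scale=5.5),
    dict(name="social_support", theme="mental_health_social_support",
         vtype="continuous", loc=76.0, scale=12.0),
    dict(name="physical_component_score",
         theme="mental_health_social_support", vtype="continuous",
         loc=48.0, scale=8.0, role="demographic"),
    dict(name="mental_illness_history", theme="mental_health_social_support",
         vtype="categorical", levels=("no", "yes"), probs=(0.74, 0.26)),
    dict(name="partner_support", theme="mental_health_social_support",
         vtype="categorical", levels=("yes", "no"), probs=(0.95, 0.05)),
    # --- smoking / drug / alcohol -------------------------------------------
    dict(name="cigarettes_per_day", theme="substance_use",
         vtype="categorical", levels=("none", "lt_5", "5_to_10", "gt_10"),
         probs=(0.86, 0.06, 0.05, 0.03)),
    dict(name="alcohol_drinks_per_day", theme="substance_use",
         vtype="categorical", levels=("none", "lt_1", "ge_1"),
         probs=(0.55, 0.33, 0.12)),
    dict(name="drug_use_days_per_week", theme="substance_use",
         vtype="categorical", levels=("none", "lt_1", "ge_1"),
         probs=(0.90, 0.06, 0.04)),
    dict(name="smoking_history", theme="substance_use", vtype="categorical",
         levels=("never", "ever"), probs=(0.66, 0.34), role="demographic"),
    dict(name="drug_alcohol_dependence_history", theme="substance_use",
         vtype="categorical", levels=("no", "yes"), probs=(0.92, 0.08)),
]

#: Default curated list for the knowledge-based selection arm (18 variables).
DEFAULT_APRIORI_VARIABLES = (
    "education", "ethnicity", "food_insecurity", "home_ownership", "income",
    "maternal_age", "paternal_age", "marital_status", "household_size",
    "new_canadian", "adverse_outcome_history", "parity", "conception_aid_use",
    "difficulty_obtaining_care", "physical_component_score", "social_support",
    "mental_illness_history", "drug_alcohol_dependence_history",
)


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Settings for the synthetic cohort generator.

    ``missing_rate_range`` bounds the per-variable item-missingness
    probability (drawn uniformly per variable). ``within_theme_correlation``
    is the loading of each variable on its theme's shared latent factor.
    """

    n_participants: int = 3351
    theme_allocation: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_THEME_ALLOCATION)
    )
    missing_rate_range: tuple[float, float] = (0.0, 0.044)
    wave_labels: tuple[str, ...] = DEFAULT_WAVE_LABELS
    continuation_targets: tuple[float, ...] = DEFAULT_CONTINUATION_TARGETS
    within_theme_correlation: float = 0.4
    monotone: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigError("n_participants must be >= 2")
        unknown = set(self.theme_allocation) - set(THEMES)
        if unknown:
            raise ConfigError(f"unknown themes in allocation: {sorted(unknown)}")
        lo, hi = self.missing_rate_range
        if not (0 <= lo <= hi < 1):
            raise ConfigError("missing_rate_range must satisfy 0 <= lo <= hi < 1")
        if len(self.wave_labels) != len(self.continuation_targets):
            raise ConfigError("one continuation target per wave label required")
        for t in self.continuation_targets:
            if not 0 < t < 1:
                raise ConfigError(f"continuation target {t} outside (0,1)")
        if not 0 <= self.within_theme_correlation < 1:
            raise ConfigError("within_theme_correlation must be in [0,1)")

    @property
    def n_variables(self) -> int:
        return sum(self.theme_allocation.values())


@dataclass
class TrueModel:
    """The dropout mechanism used to simulate participation.

    ``effects`` maps variable name to either
    ``{"type": "categorical", "levels": {level: beta}, "missing": beta}`` or
    ``{"type": "continuous", "slope": beta, "missing": beta}`` where the
    slope applies to the variable standardized by its observed mean/SD.
    ``targets`` are the marginal continuation fractions (of the baseline
    sample) per wave; the per-wave intercept is found by bisection so the
    expected marginal rate matches the target. Alternatively fix
    ``intercepts`` directly and leave ``targets`` as None.
    """

    effects: dict[str, dict] = field(default_factory=dict)
    targets: tuple[float, ...] | None = DEFAULT_CONTINUATION_TARGETS
    intercepts: tuple[float, ...] | None = None
    wave_labels: tuple[str, ...] = DEFAULT_WAVE_LABELS
    calibrated_intercepts: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.targets is None and self.intercepts is None:
            raise ConfigError("TrueModel needs targets or intercepts")
        if self.targets is not None and len(self.targets) != len(self.wave_labels):
            raise ConfigError("one target per wave label required")
        if self.intercepts is not None and len(self.intercepts) != len(
            self.wave_labels
        ):
            raise ConfigError("one intercept per wave label required")

    @property
    def variables(self) -> list[str]:
        return list(self.effects)

    def to_json(self, path) -> None:
        payload = {
            "effects": self.effects,
            "targets": list(self.targets) if self.targets else None,
            "intercepts": list(self.intercepts) if self.intercepts else None,
            "wave_labels": list(self.wave_labels),
            "calibrated_intercepts": list(self.calibrated_intercepts),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TrueModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            effects=p["effects"],
            targets=tuple(p["targets"]) if p["targets"] else None,
            intercepts=tuple(p["intercepts"]) if p["intercepts"] else None,
            wave_labels=tuple(p["wave_labels"]),
            calibrated_intercepts=list(p.get("calibrated_intercepts", [])),
        )


def default_true_model(
    targets: Sequence[float] = DEFAULT_CONTINUATION_TARGETS,
    wave_labels: Sequence[str] = DEFAULT_WAVE_LABELS,
) -> TrueModel:
    """Default covariate-driven dropout scenario.

    Five baseline variables carry nonzero effects — education, income and
    maternal age (sociodemographic), depression score (mental health) and
    cigarettes per day (substance use) — with magnitudes set so the
    unweighted maximum absolute standardized difference across the
    demographic variables sits in the 25–30% band at n = 3,351.
    """
    effects = {
        "education": {
            "type": "categorical",
            "levels": {
                "less_than_high_school": -0.46,
                "high_school": -0.20,
                "some_college": 0.04,
                "university": 0.28,
            },
            "missing": 0.0,
        },
        "income": {
            "type": "categorical",
            "levels": {
                "lt_40k": -0.46,
                "40_to_60k": -0.20,
                "60_to_80k": 0.00,
                "80_to_100k": 0.14,
                "ge_100k": 0.31,
            },
            "missing": 0.0,
        },
        "maternal_age": {"type": "continuous", "slope": 0.20, "missing": 0.0},
        "depression_score": {"type": "continuous", "slope": -0.22, "missing": 0.0},
        "cigarettes_per_day": {
            "type": "categorical",
            "levels": {"none": 0.10, "lt_5": -0.30, "5_to_10": -0.55, "gt_10": -0.80},
            "missing": 0.0,
        },
    }
    return TrueModel(
        effects=effects, targets=tuple(targets), wave_labels=tuple(wave_labels)
    )


# ---------------------------------------------------------------------------
# Baseline generation
# ---------------------------------------------------------------------------

def _probs_to_thresholds(probs: Sequence[float]) -> np.ndarray:
    from scipy.stats import norm

    cum = np.cumsum(probs)[:-1]
    return norm.ppf(np.clip(cum, 1e-12, 1 - 1e-12))


def generate_baseline(
    config: GeneratorConfig,
) -> tuple[CohortTable, list[VariableSpec]]:
    """Generate the baseline survey table (no participation yet).

    Mixed categorical (2–6 levels) and continuous variables; each variable
    loads on its theme's shared standard-normal factor with loading
    ``within_theme_correlation``; item missingness is injected completely at
    random per variable. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    rho = config.within_theme_correlation
    noise_sd = np.sqrt(1 - rho**2)

    theme_factors = {t: rng.standard_normal(n) for t in THEMES}

    named_by_theme: dict[str, list[dict]] = {t: [] for t in THEMES}
    for v in _NAMED_VARIABLES:
        named_by_theme[v["theme"]].append(v)

    columns: dict[str, np.ndarray | list] = {}
    specs: list[VariableSpec] = []

    for theme in THEMES:
        alloc = config.theme_allocation.get(theme, 0)
        named = named_by_theme[theme][:alloc]
        n_filler = alloc - len(named)
        plan = list(named)
        for j in range(n_filler):
            if rng.random() < 0.6:
                k = int(rng.integers(2, 7))
                raw = rng.dirichlet(np.full(k, 4.0))
                plan.append(
                    dict(
                        name=f"{theme}_q{j + 1:02d}",
                        theme=theme,
                        vtype="categorical",
                        levels=tuple(f"l{i + 1}" for i in range(k)),
                        probs=tuple(raw),
                        role="candidate",
                    )
                )
            else:
                plan.append(
                    dict(
                        name=f"{theme}_q{j + 1:02d}",
                        theme=theme,
                        vtype="continuous",
                        loc=0.0,
                        scale=1.0,
                        role="candidate",
                    )
                )

        for v in plan:
            latent = rho * theme_factors[theme] + noise_sd * rng.standard_normal(n)
            if v["vtype"] == "continuous":
                columns[v["name"]] = v["loc"] + v["scale"] * latent
                specs.append(
                    VariableSpec(
                        name=v["name"],
                        theme=theme,
                        vtype="continuous",
                        role=v.get("role", "candidate"),
                    )
                )
            else:
                thresholds = _probs_to_thresholds(v["probs"])
                idx = np.searchsorted(thresholds, latent, side="right")
                levels = tuple(v["levels"])
                columns[v["name"]] = np.asarray(levels, dtype=object)[idx]
                specs.append(
                    VariableSpec(
                        name=v["name"],
                        theme=theme,
                        vtype="categorical",
                        levels=levels,
                        role=v.get("role", "candidate"),
                    )
                )

    ids = [f"p{i + 1:05d}" for i in range(n)]
    data = pd.DataFrame(columns, index=pd.Index(ids, name="participant_id"))

    # item missingness, completely at random per variable
    lo, hi = config.missing_rate_range
    for spec in specs:
        rate = rng.uniform(lo, hi)
        if rate > 0:
            mask = rng.random(n) < rate
            if mask.any():
                col = data[spec.name].astype(object if spec.is_categorical else float)
                col[mask] = np.nan
                data[spec.name] = col

    return CohortTable(data), specs


# ---------------------------------------------------------------------------
# Participation simulation
# ---------------------------------------------------------------------------

def linear_predictor(table: CohortTable, model: TrueModel) -> np.ndarray:
    """Covariate part of the dropout logit (no intercept).

    Missing cells contribute the effect's dedicated ``missing`` term;
    continuous values are standardized by their observed mean/SD.
    """
    eta = np.zeros(table.n_participants)
    for name, eff in model.effects.items():
        if name not in table.data.columns:
            raise ConfigError(f"true model references unknown variable {name!r}")
        col = table.data[name]
        miss = col.isna().to_numpy()
        if eff["type"] == "categorical":
            lev = eff["levels"]
            mapped = col.map(lev).astype(float).to_numpy()
            vals = np.where(miss, eff.get("missing", 0.0), np.nan_to_num(mapped))
        else:
            x = pd.to_numeric(col).to_numpy(dtype=float)
            mu = np.nanmean(x)
            sd = np.nanstd(x)
            z = (x - mu) / (sd if sd > 0 else 1.0)
            vals = np.where(miss, eff.get("missing", 0.0), eff["slope"] * np.nan_to_num(z))
        eta = eta + vals
    return eta


def _calibrate_intercept(
    eta: np.ndarray, at_risk: np.ndarray, target: float, n_total: int, tol: float = 1e-4
) -> float:
    """Bisection for the intercept c with (1/n) Σ_{at risk} expit(c+η) = target."""

    def rate(c: float) -> float:
        return float(expit(c + eta[at_risk]).sum()) / n_total

    frac_at_risk = at_risk.sum() / n_total
    if target >= frac_at_risk or target <= 0:
        raise ConfigError(
            f"continuation target {target} unreachable: only "
            f"{frac_at_risk:.3f} of the sample is still at risk"
        )
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        r = rate(mid)
        if abs(r - target) < tol:
            return mid
        if r < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_participation(
    table: CohortTable,
    model: TrueModel,
    seed: int = 0,
    monotone: bool = True,
) -> CohortTable:
    """Draw per-wave participation indicators from the dropout model.

    Indicators are Bernoulli(expit(intercept + η)) draws; under monotone
    attrition (the default) a participant lost at wave k stays lost at all
    later waves and the per-wave intercept is calibrated against the
    still-at-risk subset so the *marginal* continuation fraction of the
    baseline sample hits the wave's target.
    """
    rng = np.random.default_rng(seed)
    eta = linear_predictor(table, model)
    n = table.n_participants

    waves = {}
    at_risk = np.ones(n, dtype=bool)
    model.calibrated_intercepts = []
    for k, label in enumerate(model.wave_labels):
        if model.targets is not None:
            c = _calibrate_intercept(eta, at_risk, model.targets[k], n)
        else:
            c = float(model.intercepts[k])
        model.calibrated_intercepts.append(c)
        p = expit(c + eta)
        draw = (rng.random(n) < p).astype(int)
        if monotone:
            draw = draw * at_risk.astype(int)
            at_risk = draw.astype(bool)
        waves[label] = draw

    out = table.copy()
    out.waves = pd.DataFrame(waves, index=table.data.index)
    return CohortTable(out.data, out.waves)


def generate_cohort(
    config: GeneratorConfig | None = None,
    true_model: TrueModel | None = None,
) -> tuple[CohortTable, list[VariableSpec], TrueModel]:
    """Baseline + participation in one call: the default study scenario."""
    config = config or GeneratorConfig()
    if true_model is None:
        true_model = default_true_model(
            targets=config.continuation_targets, wave_labels=config.wave_labels
        )
    table, specs = generate_baseline(config)
    table = simulate_participation(
        table, true_model, seed=config.seed + 1, monotone=config.monotone
    )
    return table, specs, true_model
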