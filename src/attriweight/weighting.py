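"""Stabilized inverse-probability-of-participation weights.

Given a fitted participation model, every baseline participant gets a
predicted probability p̂ᵢ of continuing to the wave in question. The
stabilized weight is swᵢ = p̄ / p̂ᵢ with p̄ the observed marginal
continuation proportion; participants unlikely to continue receive larger
weights, and stabilization keeps the mean near 1 with smaller variance than
the raw 1/p̂ weights. Weights are percentile-truncated (default 0.5th and
99.5th) to limit the influence of extreme weights; analyses consume the
responders' subset of the (truncated) weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, VariableSpec
from .selection import SelectedModel, fit_logistic

__all__ = [
    "WeightSet",
    "predict_probabilities",
    "stabilized_weights",
    "truncate_weights",
    "refit_for_wave",
]


@dataclass
class WeightSet:
    """Predicted probabilities and stabilized weights for one wave.

    ``p_hat``/``sw`` cover *all* baseline participants; ``weights`` exposes
    the analysis-facing vector (truncated where available) restricted to the
    responders of the wave.
    """

    wave: str
    p_hat: pd.Series
    participation: pd.Series
    p_bar: float
    sw: pd.Series
    sw_truncated: pd.Series | None = None
    bounds: tuple[float, float] | None = None
    truncation_pcts: tuple[float, float] | None = None
    altered_ids: list = field(default_factory=list)
    sw_lost: pd.Series | None = None
    sw_lost_truncated: pd.Series | None = None

    @property
    def n_altered(self) -> int:
        return len(self.altered_ids)

    @property
    def responders(self) -> pd.Index:
        return self.participation.index[self.participation == 1]

    @property
    def weights(self) -> pd.Series:
        w = self.sw_truncated if self.sw_truncated is not None else self.sw
        return w.loc[self.responders]

    @property
    def non_responders(self) -> pd.Index:
        return self.participation.index[self.participation == 0]

    @property
    def dropout_weights(self) -> pd.Series:
        """Stabilized weights of the lost-to-follow-up group, (1-p̄)/(1-p̂).

        These reweight the drop-outs toward the baseline distribution, the
        mirror image of ``weights`` for the continuers; used by the balance
        diagnostics when both groups are weighted.
        """
        w = self.sw_lost_truncated if self.sw_lost_truncated is not None else self.sw_lost
        return w.loc[self.non_responders]

    def summary(self) -> dict:
        def _stats(w: pd.Series) -> dict:
            return {
                "mean": float(w.mean()),
                "sd": float(w.std(ddof=1)),
                "min": float(w.min()),
                "max": float(w.max()),
            }

        out = {
            "wave": self.wave,
            "p_bar": self.p_bar,
            "n": int(len(self.sw)),
            "n_responders": int(len(self.responders)),
            "before_truncation": _stats(self.sw.loc[self.responders]),
        }
        if self.sw_truncated is not None:
            out["after_truncation"] = _stats(self.sw_truncated.loc[self.responders])
            out["bounds"] = list(self.bounds)
            out["n_altered"] = self.n_altered
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "p_hat": self.p_hat,
                "participation": self.participation,
                "sw": self.sw,
            }
        )
        if self.sw_truncated is not None:
            df["sw_truncated"] = self.sw_truncated
            df["altered_flag"] = df.index.isin(self.altered_ids).astype(int)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="participant_id")

    def summary_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def predict_probabilities(model: SelectedModel, table: CohortTable) -> pd.Series:
    """Predicted probability of continuing for every baseline participant."""
    return model.predict_proba(table)


def stabilized_weights(
    p_hat: pd.Series, participation: pd.Series, wave: str = ""
) -> WeightSet:
    """Form swᵢ = p̄/p̂ᵢ for all participants.

    p̄ is the observed continuation proportion for the wave. Degenerate
    probabilities that would produce infinite weights are refused — p̂ = 0
    for anyone, or p̂ = 1 for an actual drop-out (whose mirror weight
    (1-p̄)/(1-p̂) would blow up): refit with the ridge-stabilized option.
    A saturated model may legitimately predict p̂ = 1 in an all-responding
    stratum; those responders get weight p̄.
    """
    p_hat = pd.Series(p_hat).astype(float)
    participation = pd.Series(participation).reindex(p_hat.index).astype(int)
    if ((p_hat <= 0) | (p_hat > 1)).any() or (
        (p_hat >= 1) & (participation == 0)
    ).any():
        raise ValueError(
            "predicted probabilities produce infinite weights (p_hat = 0, or "
            "p_hat = 1 for a drop-out); use a ridge-stabilized participation "
            "fit for separated data"
        )
    p_bar = float(participation.mean())
    sw = p_bar / p_hat
    sw.name = "sw"
    with np.errstate(divide="ignore"):
        sw_lost = pd.Series(
            np.where(p_hat < 1, (1 - p_bar) / (1 - p_hat), np.inf),
            index=p_hat.index,
            name="sw_lost",
        )
    return WeightSet(
        wave=wave,
        p_hat=p_hat,
        participation=participation,
        p_bar=p_bar,
        sw=sw,
        sw_lost=sw_lost,
    )


def truncate_weights(
    weight_set: WeightSet,
    low_pct: float = 0.5,
    high_pct: float = 99.5,
) -> WeightSet:
    """Clamp weights to empirical percentile bounds.

    Bounds are linear-interpolation quantiles of the full (all-participant)
    stabilized-weight vector; weights strictly outside the bounds are set to
    the bound and flagged. One-sided truncation: pass ``low_pct=0``.
    Truncation is idempotent.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    w = weight_set.sw.to_numpy(dtype=float)
    low, high = np.percentile(w, [low_pct, high_pct], method="linear")
    altered = weight_set.sw.index[(w < low) | (w > high)]
    truncated = weight_set.sw.clip(lower=low, upper=high)
    truncated.name = "sw_truncated"
    lost_trunc = None
    if weight_set.sw_lost is not None:
        wl = weight_set.sw_lost.to_numpy(dtype=float)
        finite = wl[np.isfinite(wl)]  # p_hat=1 responders carry +inf mirrors
        llow, lhigh = np.percentile(finite, [low_pct, high_pct], method="linear")
        lost_trunc = weight_set.sw_lost.clip(lower=llow, upper=lhigh)
        lost_trunc.name = "sw_lost_truncated"
    return WeightSet(
        wave=weight_set.wave,
        p_hat=weight_set.p_hat,
        participation=weight_set.participation,
        p_bar=weight_set.p_bar,
        sw=weight_set.sw,
        sw_truncated=truncated,
        bounds=(float(low), float(high)),
        truncation_pcts=(low_pct, high_pct),
        altered_ids=list(altered),
        sw_lost=weight_set.sw_lost,
        sw_lost_truncated=lost_trunc,
    )


def refit_for_wave(
    variables: Sequence[str] | SelectedModel,
    table: CohortTable,
    specs: Sequence[VariableSpec],
    wave_label: str,
    truncation: tuple[float, float] | None = (0.5, 99.5),
) -> tuple[SelectedModel, WeightSet]:
    """Re-fit the selected variable set against a later wave's outcome.

    The variable set chosen at the first assessed follow-up is kept; only
    the logistic coefficients are re-estimated against the new wave's
    participation indicator, and the full weight pipeline (stabilization,
    optional truncation) is re-run.
    """
    if isinstance(variables, SelectedModel):
        variables = variables.variables
    model, _ = fit_logistic(table, specs, list(variables), wave_label, method="refit")
    p_hat = predict_probabilities(model, table)
    ws = stabilized_weights(p_hat, table.participation(wave_label), wave=wave_label)
    if truncation is not None:
        ws = truncate_weights(ws, *truncation)
    return model, ws
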