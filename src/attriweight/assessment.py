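"""Discrimination and calibration diagnostics for participation models.

Discrimination is summarized by the area under the ROC curve (the
C-statistic), computed as the Mann–Whitney probability that a randomly
chosen continuer scores above a randomly chosen drop-out, with ties counted
half. Confidence intervals and the paired comparison of two models scored on
the same participants use DeLong's structural-components estimator for
correlated ROC curves.

Calibration combines the Hosmer–Lemeshow chi-square over predicted-risk
decile bins, mean calibration (average predicted risk vs the observed event
rate — equal by the score equation for an ML logistic fit with intercept on
its training data), and a lowess-smoothed calibration curve against the
ideal 45° line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DiscriminationReport",
    "CalibrationReport",
    "auroc",
    "delong_paired_test",
    "hosmer_lemeshow",
    "mean_calibration",
    "calibration_curve",
]


@dataclass(frozen=True)
class DiscriminationReport:
    """AUROC with a DeLong 95% confidence interval."""

    auroc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
        }


@dataclass(frozen=True)
class CalibrationReport:
    hl_statistic: float
    hl_df: int
    hl_p: float
    mean_calibration: float
    observed_rate: float
    curve_points: tuple = field(default=())

    def to_dict(self) -> dict:
        return {
            "hl_statistic": self.hl_statistic,
            "hl_df": self.hl_df,
            "hl_p": self.hl_p,
            "mean_calibration": self.mean_calibration,
            "observed_rate": self.observed_rate,
        }


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    uniq = set(np.unique(labels))
    if not uniq.issubset({0, 1}):
        raise ValueError("labels must be 0/1")
    if uniq != {0, 1}:
        raise ValueError("both classes must be present")
    return labels


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components V10 (cases) and V01 (controls).

    The AUC equals the mean of either component vector; their empirical
    variances/covariances give the sampling variance of the AUC.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return auc, v10, v01


def auroc(scores, labels) -> DiscriminationReport:
    """AUROC with a DeLong-variance normal 95% CI (clipped to [0, 1])."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if len(scores) != len(labels):
        raise ValueError("scores and labels differ in length")
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.975)
    return DiscriminationReport(
        auroc=float(auc),
        ci_low=float(max(0.0, auc - z * se)),
        ci_high=float(min(1.0, auc + z * se)),
        n_cases=m,
        n_controls=n,
    )


def delong_paired_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """DeLong's paired test for two correlated AUCs on the same sample.

    Returns ``(z, p)`` with a two-sided p-value. When the variance of the
    difference is zero (e.g. identical scores), the result is ``(0, 1)`` if
    the AUCs agree and ``(±inf, 0)`` otherwise.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_binary(labels)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("scores_a, scores_b and labels must share length")
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)

    def _var(u, v):
        return (
            (np.cov(u[0], v[0])[0, 1] / m if m > 1 else 0.0)
            + (np.cov(u[1], v[1])[0, 1] / n if n > 1 else 0.0)
        )

    var_a = _var((v10_a, v01_a), (v10_a, v01_a))
    var_b = _var((v10_b, v01_b), (v10_b, v01_b))
    cov_ab = _var((v10_a, v01_a), (v10_b, v01_b))
    var_diff = var_a + var_b - 2 * cov_ab
    diff = auc_a - auc_b
    if var_diff <= 1e-16:
        if abs(diff) < 1e-12:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    z = diff / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def hosmer_lemeshow(
    probs, labels, n_bins: int = 10
) -> tuple[float, int, float]:
    """Hosmer–Lemeshow goodness-of-fit over predicted-risk quantile bins.

    Bins are deciles of predicted risk (ties assigned to the lower bin);
    bins whose expected count is degenerate (0 or the whole bin) are merged
    into their neighbor with a warning. Returns ``(statistic, df, p)`` with
    ``df = n_effective_bins - 2``.
    """
    probs = np.asarray(probs, dtype=float)
    labels = _check_binary(labels)
    if np.any((probs <= 0) | (probs >= 1)):
        raise ValueError("probs must lie strictly inside (0, 1)")
    qs = np.quantile(probs, np.linspace(0, 1, n_bins + 1)[1:-1])
    # ties to the lower bin: value equal to an edge stays below it
    bin_idx = np.searchsorted(qs, probs, side="left")

    groups = []
    for b in range(n_bins):
        sel = bin_idx == b
        if sel.sum() == 0:
            continue
        groups.append(
            {
                "n": int(sel.sum()),
                "obs": float(labels[sel].sum()),
                "exp": float(probs[sel].sum()),
            }
        )
    # merge degenerate bins (expected 0 or expected = n) into a neighbor
    i = 0
    while i < len(groups) and len(groups) > 1:
        g = groups[i]
        if g["exp"] <= 1e-12 or g["n"] - g["exp"] <= 1e-12:
            j = i - 1 if i > 0 else i + 1
            warnings.warn(
                "Hosmer-Lemeshow: merging a degenerate risk bin into its neighbor"
            )
            for k in ("n", "obs", "exp"):
                groups[j][k] += g[k]
            del groups[i]
            i = 0
        else:
            i += 1

    stat = 0.0
    for g in groups:
        stat += (g["obs"] - g["exp"]) ** 2 / g["exp"]
        stat += ((g["n"] - g["obs"]) - (g["n"] - g["exp"])) ** 2 / (g["n"] - g["exp"])
    df = max(len(groups) - 2, 1)
    p = float(stats.chi2.sf(stat, df))
    return float(stat), int(df), p


def mean_calibration(probs, labels) -> tuple[float, float]:
    """Average predicted risk and the observed event rate.

    For a maximum-likelihood logistic fit with an intercept, evaluated on
    its own training data, the two are equal by the score equation.
    """
    probs = np.asarray(probs, dtype=float)
    labels = _check_binary(labels)
    return float(probs.mean()), float(labels.mean())


def calibration_curve(
    probs, labels, smoother_span: float = 0.75, n_grid: int = 50
) -> np.ndarray:
    """Lowess-smoothed observed outcome vs predicted risk.

    Returns an array of ``(predicted, observed_smoothed)`` pairs on an
    evenly spaced grid over the range of ``probs``, clipped to [0, 1]. The
    ideal calibration line is the diagonal; plot both to judge fit.
    Degenerate (constant) predictions collapse to a single point.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    probs = np.asarray(probs, dtype=float)
    labels = _check_binary(labels)
    if len(probs) < 50:
        raise ValueError("calibration_curve needs >= 50 observations")
    if np.ptp(probs) < 1e-12:
        warnings.warn("constant predicted risks: calibration curve degenerates")
        return np.array([[float(probs[0]), float(labels.mean())]])
    # smooth at the data points, then interpolate onto an even grid
    # (robust to heavily tied predictions, where direct grid evaluation fails)
    with np.errstate(invalid="ignore"):
        fitted = lowess(labels.astype(float), probs, frac=smoother_span, it=0)
    grid = np.linspace(probs.min(), probs.max(), n_grid)
    smoothed = np.interp(grid, fitted[:, 0], fitted[:, 1])
    return np.column_stack([grid, np.clip(smoothed, 0.0, 1.0)])


def plot_calibration(
    probs, labels, ax=None, smoother_span: float = 0.75, label: str | None = None
):
    """Calibration plot: lowess curve, ideal diagonal, AUC annotation."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    pts = calibration_curve(probs, labels, smoother_span=smoother_span)
    rep = auroc(probs, labels)
    ax.plot([0, 1], [0, 1], ls="--", color="grey", label="ideal")
    ax.plot(pts[:, 0], pts[:, 1], color="C0", label=label or "model")
    ax.set_xlabel("predicted probability of continuing")
    ax.set_ylabel("observed proportion continuing")
    ax.set_title(f"AUC = {rep.auroc:.2f} (95% CI {rep.ci_low:.2f}-{rep.ci_high:.2f})")
    ax.legend()
    return ax
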