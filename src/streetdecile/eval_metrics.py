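"""Decile-allocation evaluation: the full metric battery.

All metrics compare observed vs predicted LSOA deciles (never postcode
labels): exact and ±1/±2 allocation accuracy, mean absolute error,
Kendall's tau-b, Pearson's r, linearly weighted Cohen's kappa, the
10×10 allocation (contingency) matrix, and the extremes-separation
analysis that asks how well the continuous LSOA scores distinguish the
observed worst-off (decile 1) from best-off (decile 10) areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

__all__ = [
    "MetricReport",
    "ExtremesReport",
    "allocation_metrics",
    "rank_metrics",
    "weighted_kappa",
    "allocation_matrix",
    "extremes_separation",
    "compute_metric_report",
]


@dataclass(frozen=True)
class MetricReport:
    """One outcome's allocation performance over n scored LSOAs."""

    acc0: float
    acc1: float
    acc2: float
    mae: float
    tau: float
    r: float
    kappa: float
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.acc0 <= self.acc1 <= self.acc2 <= 1:
            raise ValueError("allocation accuracies must satisfy acc0 <= acc1 <= acc2 in [0,1]")
        if self.mae < 0:
            raise ValueError("mae must be non-negative")

    def to_dict(self) -> dict:
        return {
            "acc0": self.acc0, "acc1": self.acc1, "acc2": self.acc2,
            "mae": self.mae, "tau": self.tau, "r": self.r,
            "kappa": self.kappa, "n": self.n,
        }


@dataclass
class ExtremesReport:
    """Separation of the observed extreme deciles on the score axis."""

    distributions: dict[int, np.ndarray]  # true decile -> mean_z values
    worst_off_misclassification: float
    best_off_misclassification: float
    threshold: float
    rule: str


def _check_deciles(observed, predicted, n_classes: int = 10) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=int)
    pred = np.asarray(predicted, dtype=int)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-D vectors")
    for name, v in (("observed", obs), ("predicted", pred)):
        if np.any((v < 1) | (v > n_classes)):
            raise ValueError(f"{name} deciles must lie in 1..{n_classes}")
    return obs, pred


def allocation_metrics(observed, predicted) -> tuple[float, float, float, float]:
    """(acc0, acc1, acc2, mae): accuracy at error margins 0/±1/±2 and MAE."""
    obs, pred = _check_deciles(observed, predicted)
    err = np.abs(obs - pred)
    return (
        float(np.mean(err == 0)),
        float(np.mean(err <= 1)),
        float(np.mean(err <= 2)),
        float(err.mean()),
    )


def rank_metrics(observed, predicted) -> tuple[float, float]:
    """(Kendall tau-b, Pearson r) on the integer decile vectors.

    tau-b is the tie-corrected variant — decile vectors are heavily tied.
    A constant vector makes Pearson r undefined and raises, rather than
    returning a silent 0.
    """
    obs, pred = _check_deciles(observed, predicted)
    if len(obs) < 2:
        raise ValueError("need n >= 2 for rank metrics")
    if obs.std() == 0 or pred.std() == 0:
        raise ValueError("Pearson r undefined for a constant decile vector")
    tau = stats.kendalltau(obs, pred, variant="b").statistic
    r = stats.pearsonr(obs, pred).statistic
    return float(tau), float(r)


def weighted_kappa(observed, predicted, n_classes: int = 10) -> float:
    """Cohen's kappa with linear weights w_ij = 1 - |i-j|/(K-1)."""
    obs, pred = _check_deciles(observed, predicted, n_classes)
    return float(
        cohen_kappa_score(obs, pred, labels=np.arange(1, n_classes + 1), weights="linear")
    )


def allocation_matrix(observed, predicted, n_classes: int = 10) -> np.ndarray:
    """10×10 counts; entry (i, j) = LSOAs observed in decile i+1, predicted j+1."""
    obs, pred = _check_deciles(observed, predicted, n_classes)
    mat = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(mat, (obs - 1, pred - 1), 1)
    return mat


def compute_metric_report(observed, predicted) -> MetricReport:
    """The full battery in one call."""
    acc0, acc1, acc2, mae = allocation_metrics(observed, predicted)
    tau, r = rank_metrics(observed, predicted)
    kappa = weighted_kappa(observed, predicted)
    return MetricReport(acc0, acc1, acc2, mae, tau, r, kappa, n=len(np.asarray(observed)))


def extremes_separation(
    lsoa_scores: pd.DataFrame,
    observed_deciles: pd.Series,
    rule: str = "midpoint",
    predicted_deciles: pd.Series | None = None,
) -> ExtremesReport:
    """How separable are the observed worst-off and best-off deciles?

    Groups the LSOA mean scores by their observed decile.  Under the
    default rule the threshold is the midpoint of the decile-1 and
    decile-10 score medians; a worst-off LSOA is misclassified when its
    score falls on the best-off side of the threshold, and symmetrically
    for best-off LSOAs.  ``rule="predicted_decile"`` instead counts
    worst-off LSOAs predicted into the upper half (decile > 5) and
    best-off LSOAs into the lower half; it requires predicted deciles.
    """
    scores = pd.Series(
        lsoa_scores["mean_z"].to_numpy(), index=lsoa_scores["lsoa_id"].to_numpy()
    )
    deciles = observed_deciles.reindex(scores.index)
    if deciles.isna().any():
        missing = deciles.index[deciles.isna()][0]
        raise KeyError(f"no observed decile for scored LSOA {missing!r}")
    deciles = deciles.astype(int)
    distributions = {
        int(d): scores[deciles == d].to_numpy() for d in sorted(deciles.unique())
    }
    for extreme in (1, 10):
        if extreme not in distributions or len(distributions[extreme]) == 0:
            raise ValueError(f"no LSOA observed in extreme decile {extreme}")
    lo, hi = distributions[1], distributions[10]

    if rule == "midpoint":
        med_lo, med_hi = np.median(lo), np.median(hi)
        threshold = 0.5 * (med_lo + med_hi)
        if med_hi >= med_lo:  # higher score = better-off (the trained orientation)
            worst = float(np.mean(lo > threshold))
            best = float(np.mean(hi <= threshold))
        else:
            worst = float(np.mean(lo < threshold))
            best = float(np.mean(hi >= threshold))
    elif rule == "predicted_decile":
        if predicted_deciles is None:
            raise ValueError("rule 'predicted_decile' needs predicted_deciles")
        pred = predicted_deciles.reindex(scores.index).astype(int)
        threshold = 5.5
        worst = float(np.mean(pred[deciles == 1] > 5))
        best = float(np.mean(pred[deciles == 10] <= 5))
    else:
        raise ValueError(f"unknown extremes rule {rule!r}")
    return ExtremesReport(
        distributions=distributions,
        worst_off_misclassification=worst,
        best_off_misclassification=best,
        threshold=float(threshold),
        rule=rule,
    )
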