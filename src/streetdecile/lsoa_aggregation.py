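"""Postcode scores → LSOA predicted deciles.

The prediction protocol averages the *pre-sigmoid* postcode outputs z
within each LSOA (restricted to a scored subset, e.g. one CV fold's test
postcodes) and converts the LSOA means to decile categories by an
equal-frequency rank cut over the scored LSOAs — the same cut rule used
to build the observed decile labels, so the predicted decile marginal is
uniform by construction and invariant to any monotone recalibration of
the scores.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .ordinal_net import binomial_class_probs
from .synthetic_city import compute_deciles
from scipy.special import expit

__all__ = ["aggregate_lsoa", "scores_to_deciles"]


def aggregate_lsoa(
    postcode_scores: pd.DataFrame,
    geography: pd.DataFrame,
    subset: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Mean z per LSOA over the scored subset of postcodes.

    Parameters
    ----------
    postcode_scores:
        DataFrame with columns ``postcode_id`` and ``z``.
    geography:
        DataFrame with columns ``postcode_id`` and ``lsoa_id``.
    subset:
        Postcodes to include (default: all scored postcodes).  LSOAs with
        no member in the subset are omitted, not zero-filled.

    Returns a DataFrame with columns ``lsoa_id``, ``mean_z``,
    ``n_postcodes_used``.
    """
    scores = postcode_scores
    if subset is not None:
        subset = list(subset)
        if len(subset) == 0:
            raise ValueError("subset of postcodes is empty")
        scores = scores[scores["postcode_id"].isin(set(subset))]
        missing = set(subset) - set(scores["postcode_id"])
        if missing:
            raise KeyError(f"no score for postcode {sorted(missing)[0]!r}")
    if scores.empty:
        raise ValueError("no postcode scores to aggregate")
    merged = scores.merge(
        geography[["postcode_id", "lsoa_id"]], on="postcode_id", how="left"
    )
    orphans = merged["lsoa_id"].isna()
    if orphans.any():
        pc = merged.loc[orphans, "postcode_id"].iloc[0]
        raise KeyError(f"postcode {pc!r} has no geography entry")
    out = (
        merged.groupby("lsoa_id", sort=True)["z"]
        .agg(mean_z="mean", n_postcodes_used="size")
        .reset_index()
    )
    out["n_postcodes_used"] = out["n_postcodes_used"].astype(int)
    return out


def scores_to_deciles(
    lsoa_scores: pd.DataFrame,
    method: str = "rank",
    n_classes: int = 10,
) -> pd.DataFrame:
    """Convert LSOA mean scores to predicted deciles 1..10.

    Higher mean_z means higher predicted wellbeing, hence a higher
    decile (decile 1 = worst-off).  The default rank-based cut applies
    the same equal-frequency tie/remainder rule as the observed-decile
    construction.  ``method="argmax"`` instead takes the mode of the
    binomial class distribution at sigmoid(mean_z); it does not preserve
    the uniform decile marginal and exists for sensitivity checks.
    """
    if len(lsoa_scores) < n_classes:
        raise ValueError(
            f"need at least {n_classes} scored LSOAs, got {len(lsoa_scores)}"
        )
    scores = pd.Series(
        lsoa_scores["mean_z"].to_numpy(), index=lsoa_scores["lsoa_id"].to_numpy()
    )
    if method == "rank":
        deciles = compute_deciles(scores, higher_is_better=True, n_bins=n_classes)
    elif method == "argmax":
        probs = binomial_class_probs(expit(scores.to_numpy()), n_classes)
        deciles = pd.Series(np.argmax(probs, axis=1) + 1, index=scores.index)
    else:
        raise ValueError(f"unknown conversion method {method!r}")
    out = lsoa_scores.copy()
    out["predicted_decile"] = deciles.to_numpy()
    return out
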