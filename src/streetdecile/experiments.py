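"""Cross-validation and cross-city transfer experiments.

`run_crossval` reproduces the evaluation protocol: five-fold splits at
the postcode level, per-fold training, pre-sigmoid LSOA averaging of the
held-out postcodes, per-fold decile conversion, and pooled metrics.  A
grouped split at the LSOA level is offered as well, because a postcode
split lets label information from an LSOA straddle folds.

`run_transfer` measures domain transfer: train on a source city, then
(a) apply the weights directly to a target city, (b) fine-tune on small
fractions of target postcodes, and (c) train from scratch on the target
training pool, all evaluated on a shared held-out set of target
postcodes disjoint from every training/fine-tuning subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lsoa_aggregation, ordinal_net
from .eval_metrics import (
    ExtremesReport,
    MetricReport,
    allocation_matrix,
    compute_metric_report,
    extremes_separation,
)
from .ordinal_net import ModelParams, TrainConfig
from .synthetic_city import City, FeatureBlocks

__all__ = [
    "FoldSplit",
    "CrossvalResult",
    "TransferResult",
    "make_fold_splits",
    "run_crossval",
    "run_transfer",
]


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_postcodes: tuple[str, ...]
    test_postcodes: tuple[str, ...]


@dataclass
class CrossvalResult:
    predictions: pd.DataFrame  # lsoa_id, outcome, mean_z, predicted_decile, fold, observed_decile
    report: MetricReport
    report_pooled_conversion: MetricReport
    matrix: np.ndarray
    extremes: ExtremesReport
    histories: list[dict]


@dataclass
class TransferResult:
    regime: str  # no_fine_tune | fine_tune@f | from_scratch
    report: MetricReport
    n_target_postcodes_used: int


def make_fold_splits(
    geography: pd.DataFrame,
    k: int = 5,
    unit: str = "postcode",
    seed: int = 0,
) -> list[FoldSplit]:
    """Seeded k-fold partition of postcodes.

    With ``unit="postcode"`` the partition is over postcodes directly;
    with ``unit="lsoa"`` whole LSOAs (all their postcodes) are assigned
    to one fold, preventing within-LSOA label leakage across folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 606]))
    postcodes = geography["postcode_id"].to_numpy()
    if unit == "postcode":
        units = postcodes
        members = {pc: (pc,) for pc in postcodes}
    elif unit == "lsoa":
        units = geography["lsoa_id"].unique()
        grouped = geography.groupby("lsoa_id")["postcode_id"].apply(tuple)
        members = grouped.to_dict()
    else:
        raise ValueError(f"unknown split unit {unit!r}")
    if k > len(units):
        raise ValueError(f"k={k} exceeds the {len(units)} available {unit} units")
    order = rng.permutation(len(units))
    fold_of_unit = np.empty(len(units), dtype=int)
    # contiguous blocks of a permutation -> test sizes differ by <= 1 unit
    bounds = np.linspace(0, len(units), k + 1).astype(int)
    for f in range(k):
        fold_of_unit[order[bounds[f] : bounds[f + 1]]] = f
    splits = []
    for f in range(k):
        test: list[str] = []
        trainp: list[str] = []
        for u, uf in zip(units, fold_of_unit):
            (test if uf == f else trainp).extend(members[u])
        splits.append(
            FoldSplit(fold_id=f + 1, train_postcodes=tuple(trainp), test_postcodes=tuple(test))
        )
    return splits


def _evaluate_subset(
    params: ModelParams,
    features: FeatureBlocks,
    city: City,
    outcome: str,
    postcodes: tuple[str, ...] | np.ndarray,
    decile_method: str = "rank",
) -> pd.DataFrame:
    """Score a postcode subset, aggregate per LSOA, convert to deciles."""
    sub = features.subset(list(postcodes))
    scores = ordinal_net.predict_postcodes(params, sub)
    lsoa_scores = lsoa_aggregation.aggregate_lsoa(scores, city.geography)
    preds = lsoa_aggregation.scores_to_deciles(lsoa_scores, method=decile_method)
    truth = city.decile_lookup(outcome)
    preds["observed_decile"] = preds["lsoa_id"].map(truth).astype(int)
    preds["outcome"] = outcome
    return preds


def run_crossval(
    city: City,
    features: FeatureBlocks,
    outcome: str,
    train_config: TrainConfig,
    k: int = 5,
    unit: str = "postcode",
    seed: int = 0,
    decile_method: str = "rank",
) -> CrossvalResult:
    """k-fold cross-validated decile allocation for one outcome.

    Each fold trains on 80% of postcodes and scores the withheld 20%;
    held-out postcode scores are averaged per LSOA and rank-cut into
    deciles *within the fold*.  Metrics are computed on the pooled
    (lsoa, fold) predictions; a pooled-conversion variant (one rank cut
    over all folds' LSOA means) is reported alongside.
    """
    splits = make_fold_splits(city.geography, k=k, unit=unit, seed=seed)
    postcode_labels = city.postcode_deciles(outcome)
    seeds = np.random.SeedSequence([int(seed), 707]).generate_state(k)
    fold_frames: list[pd.DataFrame] = []
    histories: list[dict] = []
    for split, fold_seed in zip(splits, seeds):
        lsoas_in_test = city.geography.loc[
            city.geography["postcode_id"].isin(split.test_postcodes), "lsoa_id"
        ].nunique()
        if lsoas_in_test < 10:
            raise ValueError(
                f"fold {split.fold_id} covers only {lsoas_in_test} LSOAs; "
                "decile conversion needs at least 10"
            )
        train_feats = features.subset(list(split.train_postcodes))
        labels = postcode_labels.loc[list(split.train_postcodes)].to_numpy()
        cfg = TrainConfig(
            learning_rate=train_config.learning_rate,
            n_iterations=train_config.n_iterations,
            batch_size=train_config.batch_size,
            validation_fraction=train_config.validation_fraction,
            selection_window_fraction=train_config.selection_window_fraction,
            eval_every=train_config.eval_every,
            seed=int(fold_seed % (2**31)),
        )
        params, history = ordinal_net.train(train_feats, labels, cfg)
        histories.append({"fold": split.fold_id, **{kk: history[kk] for kk in
                          ("best_val_mae", "n_train", "n_val")}})
        preds = _evaluate_subset(params, features, city, outcome,
                                 split.test_postcodes, decile_method)
        preds["fold"] = split.fold_id
        fold_frames.append(preds)

    predictions = pd.concat(fold_frames, ignore_index=True)
    obs = predictions["observed_decile"].to_numpy()
    pred = predictions["predicted_decile"].to_numpy()
    report = compute_metric_report(obs, pred)

    pooled = lsoa_aggregation.scores_to_deciles(
        predictions[["lsoa_id", "mean_z"]], method=decile_method
    )
    report_pooled = compute_metric_report(
        predictions["observed_decile"].to_numpy(),
        pooled["predicted_decile"].to_numpy(),
    )

    matrix = allocation_matrix(obs, pred)
    extremes = extremes_separation(
        predictions[["lsoa_id", "mean_z"]],
        pd.Series(obs, index=predictions["lsoa_id"].to_numpy()),
    )
    predictions = predictions[
        ["lsoa_id", "outcome", "mean_z", "n_postcodes_used",
         "predicted_decile", "observed_decile", "fold"]
    ]
    return CrossvalResult(predictions, report, report_pooled, matrix, extremes, histories)


def run_transfer(
    source_city: City,
    source_features: FeatureBlocks,
    target_city: City,
    target_features: FeatureBlocks,
    outcome: str,
    train_config: TrainConfig,
    fractions: tuple[float, ...] = (0.0, 0.01, 0.05, 0.10, 0.20),
    include_scratch: bool = True,
    seed: int = 0,
    decile_method: str = "rank",
) -> list[TransferResult]:
    """Source→target transfer under the three regimes.

    A single model is trained on all source postcodes.  Target postcodes
    are permuted once; the fine-tune subset at fraction f is the first
    ⌊f·n⌋ of the permutation (so subsets are nested), and the shared
    evaluation set is the complement of the largest subset.  Fine-tuning
    resumes training of all weights with a fresh optimizer; train-from-
    scratch uses the target training pool (the complement of the
    evaluation set).  Target deciles are the target city's own labels.
    """
    if source_features.feature_dim != target_features.feature_dim:
        raise ValueError("source and target feature dimensions differ")
    pos_fracs = sorted(f for f in fractions if f > 0)
    n_target = target_features.n_postcodes
    for f in pos_fracs:
        if int(f * n_target) < 1:
            raise ValueError(f"fraction {f} selects no postcode out of {n_target}")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 808]))
    perm = rng.permutation(target_features.postcode_ids)
    f_max = max(pos_fracs) if pos_fracs else 0.0
    n_max = int(f_max * n_target)
    train_pool = tuple(perm[:n_max])
    eval_set = tuple(perm[n_max:])
    if len(eval_set) == 0:
        raise ValueError("largest fine-tune fraction leaves no evaluation postcodes")

    target_labels = target_city.postcode_deciles(outcome)
    sub_seeds = np.random.SeedSequence([int(seed), 909]).generate_state(len(pos_fracs) + 2)

    def _cfg(s: int) -> TrainConfig:
        return TrainConfig(
            learning_rate=train_config.learning_rate,
            n_iterations=train_config.n_iterations,
            batch_size=train_config.batch_size,
            validation_fraction=train_config.validation_fraction,
            selection_window_fraction=train_config.selection_window_fraction,
            eval_every=train_config.eval_every,
            seed=int(s % (2**31)),
        )

    source_labels = source_city.postcode_deciles(outcome)
    src_params, _ = ordinal_net.train(
        source_features,
        source_labels.loc[list(source_features.postcode_ids)].to_numpy(),
        _cfg(sub_seeds[0]),
    )

    def _report(params: ModelParams) -> MetricReport:
        preds = _evaluate_subset(
            params, target_features, target_city, outcome, eval_set, decile_method
        )
        return compute_metric_report(
            preds["observed_decile"].to_numpy(), preds["predicted_decile"].to_numpy()
        )

    results = [TransferResult("no_fine_tune", _report(src_params), 0)]
    for f, s in zip(pos_fracs, sub_seeds[1:]):
        n_f = int(f * n_target)
        subset = list(perm[:n_f])
        feats = target_features.subset(subset)
        labels = target_labels.loc[subset].to_numpy()
        params, _ = ordinal_net.train(feats, labels, _cfg(s), init=src_params)
        results.append(TransferResult(f"fine_tune@{f:g}", _report(params), n_f))
    if include_scratch:
        if not train_pool:
            raise ValueError("from_scratch requires a non-empty target training pool")
        feats = target_features.subset(list(train_pool))
        labels = target_labels.loc[list(train_pool)].to_numpy()
        params, _ = ordinal_net.train(feats, labels, _cfg(sub_seeds[-1]))
        results.append(TransferResult("from_scratch", _report(params), len(train_pool)))
    return results
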