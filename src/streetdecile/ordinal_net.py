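"""Binomial-unimodal ordinal classifier over four-view feature blocks.

The model maps each postcode's four embeddings through a shared per-view
encoder, concatenates the four channel embeddings in fixed view order,
and produces a single pre-sigmoid score z.  p = sigmoid(z) parameterizes
a Binomial(K-1, p) distribution whose success counts 0..K-1 are the K
ordered decile classes; this guarantees a unimodal class distribution,
which is the point of casting decile assignment as ordinal rather than
flat classification.  Training minimizes the cross-entropy of the true
decile under the binomial class probabilities with an Adam optimizer,
keeping the parameter snapshot with the best validation MAE inside the
final selection window.

All forward/backward passes are explicit NumPy: the network is a small
multilayer perceptron with batch normalization on every layer except the
output, and exact gradients are simple enough to write and to verify
against finite differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import comb, expit

from .synthetic_city import N_VIEWS, FeatureBlocks

__all__ = [
    "Architecture",
    "TrainConfig",
    "ModelParams",
    "OrdinalHeadOutput",
    "binomial_class_probs",
    "ordinal_nll",
    "init_params",
    "forward",
    "train",
    "predict_postcodes",
    "replication_train_config",
]

PROB_FLOOR = 1e-12  # floor inside the log; keeps the loss finite at p in {0,1}
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9

Parameterization = Literal["binom_km1", "binom_k_renorm"]


# ---------------------------------------------------------------------------
# ordinal head
# ---------------------------------------------------------------------------


def binomial_class_probs(
    p: float | np.ndarray, K: int = 10, parameterization: Parameterization = "binom_km1"
) -> np.ndarray:
    """K ordered class probabilities from a single success probability.

    Default ("binom_km1"): class m (1-based) gets the Binomial(K-1, p)
    probability of m-1 successes.  The alternative "binom_k_renorm"
    evaluates Binomial(K, p) at 1..K successes and renormalizes; it is
    kept for sensitivity checks only.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)) or not np.all(np.isfinite(p_arr)):
        raise ValueError("p must lie in [0, 1]")
    scalar = p_arr.ndim == 0
    p_arr = np.atleast_1d(p_arr)[:, None]
    if parameterization == "binom_km1":
        m = np.arange(K)[None, :]
        n_trials = K - 1
    elif parameterization == "binom_k_renorm":
        m = np.arange(1, K + 1)[None, :]
        n_trials = K
    else:
        raise ValueError(f"unknown parameterization {parameterization!r}")
    with np.errstate(invalid="ignore"):
        probs = comb(n_trials, m) * p_arr**m * (1.0 - p_arr) ** (n_trials - m)
    # 0**0 == 1.0 in numpy, so endpoints are exact already
    if parameterization == "binom_k_renorm":
        norm = probs.sum(axis=1, keepdims=True)
        # p == 0 puts all mass on 0 successes, outside the 1..K support
        probs = np.where(norm > 0, probs / np.where(norm > 0, norm, 1.0), 0.0)
        probs[np.atleast_1d(np.squeeze(p_arr, -1)) == 0.0, 0] = 1.0
    return probs[0] if scalar else probs


def ordinal_nll(class_probs: np.ndarray, y: np.ndarray) -> float | np.ndarray:
    """Cross-entropy of the true class: -sum_m y_m ln p_m.

    ``y`` is one-hot (or a batch of one-hots).  Probabilities are floored
    at 1e-12 inside the log.  For batched input the per-sample losses are
    returned; the batch loss is their sum (the objective is additive).
    """
    probs = np.asarray(class_probs, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if probs.shape != y_arr.shape:
        raise ValueError("class_probs and y must have the same shape")
    if not np.allclose(y_arr.sum(axis=-1), 1.0) or not np.all(
        (y_arr == 0) | (y_arr == 1)
    ):
        raise ValueError("y must be one-hot")
    ll = (y_arr * np.log(np.clip(probs, PROB_FLOOR, None))).sum(axis=-1)
    return -ll if ll.ndim else float(-ll)


def _loss_grad_z(
    p: np.ndarray, class_idx0: np.ndarray, K: int, parameterization: Parameterization
) -> np.ndarray:
    """d(per-sample NLL)/dz.  class_idx0 is the 0-based class index."""
    if parameterization == "binom_km1":
        # log pmf = m ln p + (K-1-m) ln(1-p) + const, with m = class_idx0;
        # chaining through p = sigmoid(z) cancels the p(1-p) factors.
        return (K - 1) * p - class_idx0
    p_c = np.clip(p, 1e-9, 1 - 1e-9)
    m = class_idx0 + 1.0
    q = 1.0 - p_c
    dlog_dp = m / p_c - (K - m) / q - K * q ** (K - 1) / (1.0 - q**K)
    return -dlog_dp * p_c * (1.0 - p_c)


# ---------------------------------------------------------------------------
# architecture / parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Architecture:
    """Shapes of the fully connected stack.

    ``channel_widths`` are the shared per-view encoder layers applied to
    each D-dimensional view; the four channel embeddings are concatenated
    in fixed view order (0°, 90°, 180°, 270°) and passed through
    ``head_widths`` before the scalar output.
    """

    feature_dim: int = 64
    channel_widths: tuple[int, ...] = (256, 64)
    head_widths: tuple[int, ...] = (64,)
    n_classes: int = 10
    parameterization: Parameterization = "binom_km1"

    def layer_dims(self) -> list[tuple[str, int, int, bool]]:
        """(name, fan_in, fan_out, has_batchnorm) for every linear layer."""
        layers: list[tuple[str, int, int, bool]] = []
        fan_in = self.feature_dim
        for i, w in enumerate(self.channel_widths):
            layers.append((f"enc{i}", fan_in, w, True))
            fan_in = w
        fan_in = fan_in * N_VIEWS  # concatenation of the four channels
        for i, w in enumerate(self.head_widths):
            layers.append((f"head{i}", fan_in, w, True))
            fan_in = w
        layers.append(("out", fan_in, 1, False))
        return layers


@dataclass
class ModelParams:
    """Trainable weights, batch-norm statistics, and the architecture."""

    arch: Architecture
    weights: dict[str, np.ndarray]
    trained: bool = False  # running moments valid → eval mode permitted

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.arch, {k: v.copy() for k, v in self.weights.items()}, self.trained
        )

    def check_finite(self) -> None:
        for k, v in self.weights.items():
            if not np.all(np.isfinite(v)):
                raise RuntimeError(f"non-finite parameter array {k!r}")


@dataclass
class OrdinalHeadOutput:
    """z (pre-sigmoid), p = sigmoid(z), and the K class probabilities."""

    z: np.ndarray
    p: np.ndarray
    class_probs: np.ndarray


def init_params(arch: Architecture, seed: int = 0) -> ModelParams:
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 404]))
    weights: dict[str, np.ndarray] = {}
    for name, fan_in, fan_out, has_bn in arch.layer_dims():
        std = math.sqrt(2.0 / fan_in)
        weights[f"{name}.W"] = rng.standard_normal((fan_in, fan_out)) * std
        if has_bn:
            weights[f"{name}.gamma"] = np.ones(fan_out)
            weights[f"{name}.beta"] = np.zeros(fan_out)
            weights[f"{name}.rmean"] = np.zeros(fan_out)
            weights[f"{name}.rvar"] = np.ones(fan_out)
        else:
            weights[f"{name}.b"] = np.zeros(fan_out)
    return ModelParams(arch=arch, weights=weights)


_TRAINABLE_SUFFIXES = (".W", ".b", ".gamma", ".beta")


def _trainable_keys(params: ModelParams) -> list[str]:
    return [k for k in params.weights if k.endswith(_TRAINABLE_SUFFIXES)]


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------


def _layer_forward(
    params: ModelParams, name: str, x: np.ndarray, train_mode: bool,
    relu: bool, cache: dict | None,
) -> np.ndarray:
    w = params.weights
    h = x @ w[f"{name}.W"]
    if f"{name}.gamma" in w:
        if train_mode:
            mu = h.mean(axis=0)
            var = h.var(axis=0)
            w[f"{name}.rmean"] *= _BN_MOMENTUM
            w[f"{name}.rmean"] += (1 - _BN_MOMENTUM) * mu
            w[f"{name}.rvar"] *= _BN_MOMENTUM
            w[f"{name}.rvar"] += (1 - _BN_MOMENTUM) * var
        else:
            mu = w[f"{name}.rmean"]
            var = w[f"{name}.rvar"]
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (h - mu) * inv_std
        out = w[f"{name}.gamma"] * xhat + w[f"{name}.beta"]
    else:
        xhat, inv_std = None, None
        out = h + w[f"{name}.b"]
    pre_act = out
    if relu:
        out = np.maximum(out, 0.0)
    if cache is not None:
        cache[name] = {
            "x": x, "xhat": xhat, "inv_std": inv_std,
            "pre_act": pre_act, "relu": relu, "train_mode": train_mode,
        }
    return out


def _layer_backward(
    params: ModelParams, name: str, d_out: np.ndarray, cache: dict,
    grads: dict[str, np.ndarray],
) -> np.ndarray:
    w = params.weights
    c = cache[name]
    if c["relu"]:
        d_out = d_out * (c["pre_act"] > 0)
    if c["xhat"] is not None:
        xhat, inv_std = c["xhat"], c["inv_std"]
        grads[f"{name}.gamma"] = (d_out * xhat).sum(axis=0)
        grads[f"{name}.beta"] = d_out.sum(axis=0)
        if c["train_mode"]:
            nb = d_out.shape[0]
            dxhat = d_out * w[f"{name}.gamma"]
            dh = (inv_std / nb) * (
                nb * dxhat
                - dxhat.sum(axis=0)
                - xhat * (dxhat * xhat).sum(axis=0)
            )
        else:
            dh = d_out * w[f"{name}.gamma"] * inv_std
    else:
        grads[f"{name}.b"] = d_out.sum(axis=0)
        dh = d_out
    grads[f"{name}.W"] = c["x"].T @ dh
    return dh @ w[f"{name}.W"].T


def _net_forward(
    params: ModelParams, x: np.ndarray, train_mode: bool, cache: dict | None = None
) -> np.ndarray:
    """x: (B, 4, D) → z: (B,).  Shared encoder weights across the views."""
    arch = params.arch
    b = x.shape[0]
    h = x.reshape(b * N_VIEWS, arch.feature_dim)
    for i in range(len(arch.channel_widths)):
        h = _layer_forward(params, f"enc{i}", h, train_mode, relu=True, cache=cache)
    h = h.reshape(b, N_VIEWS * h.shape[1])  # concat in fixed view order
    for i in range(len(arch.head_widths)):
        h = _layer_forward(params, f"head{i}", h, train_mode, relu=True, cache=cache)
    z = _layer_forward(params, "out", h, train_mode, relu=False, cache=cache)
    return z[:, 0]


def _net_backward(
    params: ModelParams, dz: np.ndarray, cache: dict
) -> dict[str, np.ndarray]:
    arch = params.arch
    grads: dict[str, np.ndarray] = {}
    d = _layer_backward(params, "out", dz[:, None], cache, grads)
    for i in reversed(range(len(arch.head_widths))):
        d = _layer_backward(params, f"head{i}", d, cache, grads)
    b = d.shape[0]
    d = d.reshape(b * N_VIEWS, -1)
    for i in reversed(range(len(arch.channel_widths))):
        d = _layer_backward(params, f"enc{i}", d, cache, grads)
    return grads


def _as_batch(features: FeatureBlocks | np.ndarray) -> np.ndarray:
    x = features.values if isinstance(features, FeatureBlocks) else np.asarray(features)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3 or x.shape[1] != N_VIEWS:
        raise ValueError("features must have shape (B, 4, D) or (4, D)")
    return x


def forward(
    params: ModelParams,
    features: FeatureBlocks | np.ndarray,
    mode: Literal["train", "eval"] = "eval",
) -> OrdinalHeadOutput:
    """Full forward pass to the ordinal head.

    Eval mode uses running batch-norm moments and is deterministic;
    calling it before any training step (or checkpoint load) is refused
    because no running moments exist yet.
    """
    x = _as_batch(features)
    if x.shape[2] != params.arch.feature_dim:
        raise ValueError(
            f"feature dim {x.shape[2]} does not match model dim {params.arch.feature_dim}"
        )
    if mode == "eval" and not params.trained:
        raise RuntimeError("eval-mode forward before training: no running moments")
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    z = _net_forward(params, x, train_mode=(mode == "train"))
    p = expit(z)
    probs = binomial_class_probs(p, params.arch.n_classes, params.arch.parameterization)
    return OrdinalHeadOutput(z=z, p=p, class_probs=probs)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    Desk defaults (5,000 iterations, batch 64, lr 1e-4) keep a full
    five-fold run in seconds on one CPU; ``replication_train_config``
    returns the original regime (lr 5e-6, 100,000 iterations, model
    selection over the last 5%).
    """

    learning_rate: float = 1e-4
    n_iterations: int = 5000
    batch_size: int = 64
    validation_fraction: float = 0.1
    selection_window_fraction: float = 0.05
    eval_every: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if not 0 < self.selection_window_fraction <= 1:
            raise ValueError("selection_window_fraction must be in (0, 1]")

    @property
    def resolved_eval_every(self) -> int:
        if self.eval_every is not None:
            return self.eval_every
        return max(50, self.n_iterations // 100)


def replication_train_config(seed: int = 0) -> TrainConfig:
    """The original full-scale regime: Adam at 5e-6 for 100,000 iterations."""
    return TrainConfig(learning_rate=5e-6, n_iterations=100_000, seed=seed)


def _validation_mae(params: ModelParams, x: np.ndarray, y_class: np.ndarray) -> float:
    out = forward(params, x, mode="eval")
    pred = np.argmax(out.class_probs, axis=1) + 1
    return float(np.mean(np.abs(pred - y_class)))


def train(
    features: FeatureBlocks | np.ndarray,
    labels: np.ndarray,
    config: TrainConfig,
    arch: Architecture | None = None,
    init: ModelParams | None = None,
) -> tuple[ModelParams, dict]:
    """Fit the ordinal network; returns (selected params, history).

    ``labels`` are decile classes 1..K aligned with the feature rows.  A
    validation subset (``validation_fraction`` of the postcodes) is held
    out and scored every ``eval_every`` iterations; the returned
    parameters are the snapshot with the best validation MAE within the
    final ``selection_window_fraction`` of iterations.  Passing ``init``
    resumes from existing weights (fine-tuning) with a fresh optimizer
    state.  Fully deterministic given the config seed.
    """
    x = _as_batch(features)
    y = np.asarray(labels, dtype=int)
    if len(y) != x.shape[0]:
        raise ValueError("labels and features disagree on sample count")
    if init is not None:
        params = init.copy()
        if params.arch.feature_dim != x.shape[2]:
            raise ValueError("init params feature dim does not match data")
        arch = params.arch
    else:
        if arch is None:
            arch = Architecture(feature_dim=x.shape[2])
        params = init_params(arch, seed=config.seed)
    k = arch.n_classes
    if np.any((y < 1) | (y > k)):
        raise ValueError(f"labels must be decile classes in 1..{k}")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 distinct classes in the labels")

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 505]))
    n = x.shape[0]
    n_val = int(round(config.validation_fraction * n))
    n_val = min(max(n_val, 1), n - 1)
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0 or len(val_idx) == 0:
        raise ValueError("validation split leaves an empty side")
    x_tr, y_tr = x[tr_idx], y[tr_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    adam_m = {kk: np.zeros_like(v) for kk, v in params.weights.items()
              if kk.endswith(_TRAINABLE_SUFFIXES)}
    adam_v = {kk: np.zeros_like(v) for kk, v in adam_m.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8

    window_start = int(math.ceil(config.n_iterations * (1 - config.selection_window_fraction)))
    eval_every = config.resolved_eval_every
    best_mae = math.inf
    best_weights: dict[str, np.ndarray] | None = None
    history: dict[str, list] = {"iteration": [], "train_loss": [],
                                "val_iteration": [], "val_mae": []}
    batch = min(config.batch_size, len(tr_idx))

    for it in range(1, config.n_iterations + 1):
        idx = rng.integers(0, len(tr_idx), size=batch)
        xb, yb = x_tr[idx], y_tr[idx]
        cache: dict = {}
        z = _net_forward(params, xb, train_mode=True, cache=cache)
        params.trained = True  # running moments now exist
        p = expit(z)
        class_idx0 = yb - 1
        probs = binomial_class_probs(p, k, arch.parameterization)
        loss = float(
            -np.log(np.clip(probs[np.arange(batch), class_idx0], PROB_FLOOR, None)).mean()
        )
        if not math.isfinite(loss):
            raise RuntimeError(f"non-finite training loss at iteration {it}")
        dz = _loss_grad_z(p, class_idx0.astype(float), k, arch.parameterization) / batch
        grads = _net_backward(params, dz, cache)
        for kk in adam_m:
            g = grads[kk]
            adam_m[kk] = b1 * adam_m[kk] + (1 - b1) * g
            adam_v[kk] = b2 * adam_v[kk] + (1 - b2) * g * g
            m_hat = adam_m[kk] / (1 - b1**it)
            v_hat = adam_v[kk] / (1 - b2**it)
            params.weights[kk] -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

        if it % eval_every == 0 or it == config.n_iterations:
            history["iteration"].append(it)
            history["train_loss"].append(loss)
            val_mae = _validation_mae(params, x_val, y_val)
            history["val_iteration"].append(it)
            history["val_mae"].append(val_mae)
            if it >= window_start and val_mae < best_mae:
                best_mae = val_mae
                best_weights = {kk: v.copy() for kk, v in params.weights.items()}

    if best_weights is None:  # window had no eval point other than the final one
        best_weights = {kk: v.copy() for kk, v in params.weights.items()}
        best_mae = _validation_mae(params, x_val, y_val)
    selected = ModelParams(arch=arch, weights=best_weights, trained=True)
    selected.check_finite()
    history["best_val_mae"] = best_mae
    history["n_train"] = len(tr_idx)
    history["n_val"] = len(val_idx)
    return selected, history


def predict_postcodes(
    params: ModelParams, features: FeatureBlocks, batch_size: int = 4096
) -> pd.DataFrame:
    """Eval-mode (z, p) for every postcode; deterministic and batch-invariant."""
    if not params.trained:
        raise RuntimeError("predict_postcodes requires trained params")
    n = features.n_postcodes
    zs = np.empty(n)
    for start in range(0, n, batch_size):
        out = forward(params, features.values[start : start + batch_size], mode="eval")
        zs[start : start + len(out.z)] = out.z
    return pd.DataFrame(
        {"postcode_id": features.postcode_ids, "z": zs, "p": expit(zs)}
    )
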