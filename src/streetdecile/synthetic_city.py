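"""Synthetic city generator.

Produces the three ingredients the decile-measurement pipeline consumes —
a postcode→LSOA geography, per-LSOA outcome tables with decile labels, and
per-postcode four-view feature blocks — without any external data.

The generative model: each LSOA carries a latent *wellbeing* vector (one
entry per outcome) drawn from a spatially correlated Gaussian process with
an exponential covariance over LSOA centroids and a configurable
cross-outcome correlation matrix.  Outcome raw values are the latent (sign
flipped for "higher = worse" outcomes such as deprivation indices) and are
cut into equal-frequency deciles, decile 1 being the worst-off tenth.
Postcodes nest within LSOAs; each postcode's four feature views are fixed
random linear maps of a squashed, jittered copy of its LSOA latent plus
Gaussian noise, with a controllable signal-to-noise ratio.  The feature
blocks stand in for fixed CNN embeddings (e.g. 4096-D fc6 codes) of street
panorama cut-outs at camera directions 0°, 90°, 180°, 270°.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

N_VIEWS = 4  # camera directions 0, 90, 180, 270 degrees; fixed by contract

__all__ = [
    "N_VIEWS",
    "SyntheticCityConfig",
    "FeatureBlocks",
    "City",
    "compute_deciles",
    "generate_city",
    "generate_features",
    "apply_domain_shift",
    "morans_i",
]


@dataclass(frozen=True)
class SyntheticCityConfig:
    """Parameters of one synthetic city.

    Attributes
    ----------
    n_lsoa:
        Number of small areas (LSOAs).
    postcodes_per_lsoa:
        Mean of the (min-1 truncated) Poisson postcode count per LSOA.
        Default 32 ≈ 156,581 London postcodes / 4,838 LSOAs.
    n_outcomes:
        Number of wellbeing outcomes generated jointly.
    outcome_corr:
        Cross-outcome correlation matrix (symmetric PSD, unit diagonal).
        ``None`` means independent outcomes.
    spatial_corr_length:
        Length scale of the exponential spatial kernel, in abstract grid
        units (LSOA centroids are ~1 unit apart on average).  0 disables
        spatial correlation.
    higher_is_better:
        Per-outcome orientation flag; ``True`` for outcomes like mean
        income where a larger raw value means better-off.  Default: all
        ``False`` (deprivation-index convention, higher = worse).
    feature_dim:
        Embedding dimension D per view (64 for desk-scale runs; 4096
        mirrors the fc6 contract).
    signal_to_noise:
        Ratio of latent-driven feature variance to additive noise
        variance.  0 yields pure noise; ``math.inf`` disables noise.
    jitter:
        Within-LSOA standard deviation of the postcode latent around its
        LSOA latent (the LSOA latents have unit marginal variance).
    seed:
        Seed for all randomness in generation.
    """

    n_lsoa: int = 300
    postcodes_per_lsoa: float = 32.0
    n_outcomes: int = 1
    outcome_corr: np.ndarray | None = None
    spatial_corr_length: float = 2.0
    higher_is_better: tuple[bool, ...] | None = None
    feature_dim: int = 64
    n_views: int = N_VIEWS
    signal_to_noise: float = 10.0
    jitter: float = 0.1
    seed: int = 0
    outcome_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_lsoa < 1:
            raise ValueError("n_lsoa must be a positive integer")
        if self.postcodes_per_lsoa <= 0:
            raise ValueError("postcodes_per_lsoa must be positive")
        if self.n_outcomes < 1:
            raise ValueError("n_outcomes must be a positive integer")
        if self.n_views != N_VIEWS:
            raise ValueError(f"n_views is fixed at {N_VIEWS}")
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")
        if self.spatial_corr_length < 0:
            raise ValueError("spatial_corr_length must be non-negative")
        if self.signal_to_noise < 0:
            raise ValueError("signal_to_noise must be non-negative")
        corr = self.resolved_outcome_corr()
        if corr.shape != (self.n_outcomes, self.n_outcomes):
            raise ValueError("outcome_corr shape must be (n_outcomes, n_outcomes)")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("outcome_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError("outcome_corr must have unit diagonal")
        eigmin = np.linalg.eigvalsh(corr).min()
        if eigmin < -1e-10:
            raise ValueError(f"outcome_corr must be PSD (min eigenvalue {eigmin:.3g})")
        flags = self.resolved_orientation()
        if len(flags) != self.n_outcomes:
            raise ValueError("higher_is_better needs one flag per outcome")
        names = self.resolved_outcome_names()
        if len(names) != self.n_outcomes or len(set(names)) != len(names):
            raise ValueError("outcome_names must be unique, one per outcome")

    def resolved_outcome_corr(self) -> np.ndarray:
        if self.outcome_corr is None:
            return np.eye(self.n_outcomes)
        return np.asarray(self.outcome_corr, dtype=float)

    def resolved_orientation(self) -> tuple[bool, ...]:
        if self.higher_is_better is None:
            return tuple(False for _ in range(self.n_outcomes))
        return tuple(bool(f) for f in self.higher_is_better)

    def resolved_outcome_names(self) -> tuple[str, ...]:
        if self.outcome_names is None:
            return tuple(f"outcome_{i + 1}" for i in range(self.n_outcomes))
        return tuple(self.outcome_names)


@dataclass
class FeatureBlocks:
    """Per-postcode 4-view × D embeddings, aligned with ``postcode_ids``."""

    postcode_ids: np.ndarray  # shape (n,), dtype object/str
    values: np.ndarray  # shape (n, 4, D) float64

    def __post_init__(self) -> None:
        self.postcode_ids = np.asarray(self.postcode_ids)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[1] != N_VIEWS:
            raise ValueError("values must have shape (n_postcodes, 4, D)")
        if len(self.postcode_ids) != self.values.shape[0]:
            raise ValueError("postcode_ids and values disagree on n_postcodes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_postcodes(self) -> int:
        return self.values.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.values.shape[2]

    def index_of(self, postcode_ids: Sequence[str]) -> np.ndarray:
        lookup = {pc: i for i, pc in enumerate(self.postcode_ids)}
        try:
            return np.array([lookup[pc] for pc in postcode_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"postcode {exc.args[0]!r} has no feature block") from None

    def subset(self, postcode_ids: Sequence[str]) -> "FeatureBlocks":
        idx = self.index_of(postcode_ids)
        return FeatureBlocks(self.postcode_ids[idx], self.values[idx])


@dataclass
class City:
    """One generated city: geography, outcome table, and latent field."""

    config: SyntheticCityConfig
    geography: pd.DataFrame  # columns postcode_id, lsoa_id, x, y
    outcomes: pd.DataFrame  # columns lsoa_id, outcome, raw_value, decile
    latent: pd.DataFrame  # index lsoa_id, one wellbeing column per outcome

    @property
    def lsoa_ids(self) -> np.ndarray:
        return self.latent.index.to_numpy()

    @property
    def postcode_ids(self) -> np.ndarray:
        return self.geography["postcode_id"].to_numpy()

    def decile_lookup(self, outcome: str) -> pd.Series:
        sub = self.outcomes[self.outcomes["outcome"] == outcome]
        if sub.empty:
            raise KeyError(f"unknown outcome {outcome!r}")
        return sub.set_index("lsoa_id")["decile"]

    def postcode_deciles(self, outcome: str) -> pd.Series:
        """Decile label for every postcode (its LSOA's label)."""
        per_lsoa = self.decile_lookup(outcome)
        labels = self.geography["lsoa_id"].map(per_lsoa)
        labels.index = self.geography["postcode_id"]
        return labels


def compute_deciles(
    raw_values: pd.Series | np.ndarray,
    higher_is_better: bool = False,
    n_bins: int = 10,
) -> pd.Series:
    """Equal-frequency decile labels, decile 1 = worst-off tenth.

    Ranks areas by badness — the raw value itself for "higher = worse"
    outcomes, its negation when ``higher_is_better`` — breaking ties by
    the stable input order, then cuts the ranking into ``n_bins``
    contiguous blocks.  When n is not divisible by 10 the n mod 10
    leftover units are allocated one each to deciles 1 upward, so bin
    sizes differ by at most one.
    """
    values = pd.Series(raw_values).astype(float)
    n = len(values)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} areas to cut {n_bins} bins, got {n}")
    bad = ~np.isfinite(values.to_numpy())
    if bad.any():
        offender = values.index[bad.argmax()]
        raise ValueError(f"non-finite raw value for area {offender!r}")
    # badness key: worst first after stable argsort
    key = values.to_numpy() if higher_is_better else -values.to_numpy()
    order = np.argsort(key, kind="stable")
    base, extra = divmod(n, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    sizes[:extra] += 1
    deciles = np.empty(n, dtype=int)
    deciles[order] = np.repeat(np.arange(1, n_bins + 1), sizes)
    return pd.Series(deciles, index=values.index, name="decile")


def _spatial_chol(centroids: np.ndarray, length: float) -> np.ndarray | None:
    """Cholesky factor of the exponential kernel; None means identity."""
    if length == 0:
        return None
    diff = centroids[:, None, :] - centroids[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    cov = np.exp(-dist / length)
    cov[np.diag_indices_from(cov)] += 1e-8
    return np.linalg.cholesky(cov)


def generate_city(config: SyntheticCityConfig) -> City:
    """Generate geography, outcome table, and latent wellbeing field.

    Pure function of the config (including its seed).
    """
    root = np.random.default_rng(np.random.SeedSequence([int(config.seed), 101]))
    n = config.n_lsoa
    side = math.sqrt(n)  # unit average density so corr length is comparable across sizes
    centroids = root.uniform(0.0, side, size=(n, 2))

    corr = config.resolved_outcome_corr()
    l_out = np.linalg.cholesky(corr + 1e-12 * np.eye(config.n_outcomes))
    z = root.standard_normal((n, config.n_outcomes))
    l_sp = _spatial_chol(centroids, config.spatial_corr_length)
    latent_values = z if l_sp is None else l_sp @ z
    latent_values = latent_values @ l_out.T

    lsoa_ids = np.array([f"L{i:05d}" for i in range(n)])
    latent = pd.DataFrame(
        latent_values, index=pd.Index(lsoa_ids, name="lsoa_id"),
        columns=list(config.resolved_outcome_names()),
    )

    counts = root.poisson(config.postcodes_per_lsoa, size=n)
    counts = np.maximum(counts, 1)
    postcode_lsoa = np.repeat(lsoa_ids, counts)
    postcode_ids = np.array([f"PC{i:07d}" for i in range(len(postcode_lsoa))])
    cx = np.repeat(centroids[:, 0], counts)
    cy = np.repeat(centroids[:, 1], counts)
    geography = pd.DataFrame(
        {"postcode_id": postcode_ids, "lsoa_id": postcode_lsoa, "x": cx, "y": cy}
    )

    rows = []
    for j, (name, better) in enumerate(
        zip(config.resolved_outcome_names(), config.resolved_orientation())
    ):
        wellbeing = latent_values[:, j]
        raw = wellbeing if better else -wellbeing
        raw_series = pd.Series(raw, index=lsoa_ids)
        deciles = compute_deciles(raw_series, higher_is_better=better)
        rows.append(
            pd.DataFrame(
                {
                    "lsoa_id": lsoa_ids,
                    "outcome": name,
                    "raw_value": raw,
                    "decile": deciles.to_numpy(),
                }
            )
        )
    outcomes = pd.concat(rows, ignore_index=True)
    return City(config=config, geography=geography, outcomes=outcomes, latent=latent)


def generate_features(city: City) -> FeatureBlocks:
    """Four-view feature blocks as noisy maps of the postcode latent.

    Each postcode's latent is its LSOA wellbeing vector plus isotropic
    within-LSOA jitter.  Each view applies a fixed random linear map to a
    tanh-squashed copy of the postcode latent (so the downstream learning
    task is nonlinear but solvable), then adds Gaussian noise whose
    variance is the signal variance divided by ``signal_to_noise``.
    """
    config = city.config
    d = config.feature_dim
    k = config.n_outcomes
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 202]))

    lsoa_latent = city.latent.loc[city.geography["lsoa_id"]].to_numpy()  # (n_pc, k)
    n_pc = lsoa_latent.shape[0]
    postcode_latent = lsoa_latent + config.jitter * rng.standard_normal((n_pc, k))
    squashed = np.tanh(postcode_latent)

    # per-view fixed maps with unit-norm columns so signal scale is stable in D
    view_maps = rng.standard_normal((N_VIEWS, k, d))
    view_maps /= np.linalg.norm(view_maps, axis=1, keepdims=True)
    signal = np.einsum("pk,vkd->pvd", squashed, view_maps)

    snr = config.signal_to_noise
    if snr == 0:
        values = rng.standard_normal(signal.shape)
    elif math.isinf(snr):
        values = signal
    else:
        sig_std = signal.std()
        if sig_std == 0:  # degenerate constant latent
            sig_std = 1.0
        noise = rng.standard_normal(signal.shape) * (sig_std / math.sqrt(snr))
        values = signal + noise
    return FeatureBlocks(city.geography["postcode_id"].to_numpy(), values)


def apply_domain_shift(
    features: FeatureBlocks,
    scale: float | np.ndarray = 1.0,
    offset: float | np.ndarray = 0.0,
    extra_noise_std: float = 0.0,
    seed: int = 0,
) -> FeatureBlocks:
    """Affine per-feature transform plus optional extra noise.

    Simulates the gap between a source city and a target city whose
    imagery has different photometric/content statistics.  ``scale`` and
    ``offset`` may be scalars, (D,) vectors, or (4, D) per-view arrays.
    The identity shift (scale 1, offset 0, no noise) returns values equal
    to the input.
    """
    d = features.feature_dim
    scale_a = np.asarray(scale, dtype=float)
    offset_a = np.asarray(offset, dtype=float)
    for name, arr in (("scale", scale_a), ("offset", offset_a)):
        if arr.ndim == 0:
            continue
        if arr.shape not in ((d,), (N_VIEWS, d)):
            raise ValueError(
                f"{name} must be scalar, (D,), or (4, D); got shape {arr.shape} for D={d}"
            )
    if extra_noise_std < 0:
        raise ValueError("extra_noise_std must be non-negative")
    values = features.values * scale_a + offset_a
    if extra_noise_std > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
        values = values + extra_noise_std * rng.standard_normal(values.shape)
    return FeatureBlocks(features.postcode_ids.copy(), values)


def morans_i(
    values: np.ndarray, coords: np.ndarray, n_neighbors: int = 8
) -> tuple[float, float]:
    """Moran's I with binary k-nearest-neighbour weights.

    Returns ``(I, expected_I)`` where the expectation under spatial
    randomness is -1/(n-1).  Used as a diagnostic that the generator's
    latent field really is spatially autocorrelated.
    """
    x = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = len(x)
    if n < n_neighbors + 1:
        raise ValueError("need more points than neighbours")
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=n_neighbors + 1)
    neigh = idx[:, 1:]  # drop self
    z = x - x.mean()
    num = (z[:, None] * z[neigh]).sum()
    w_total = n * n_neighbors
    denom = (z**2).sum()
    i_stat = (n / w_total) * (num / denom)
    return float(i_stat), -1.0 / (n - 1)
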