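"""On-disk formats: geography/outcome CSVs, HDF5 feature blocks,
model checkpoints, and YAML run configs.

The HDF5 layout is a single dataset ``features`` of shape
(n_postcodes, 4, D) — axis order (postcode, view, feature), views in
fixed camera order 0°, 90°, 180°, 270° — plus a ``postcode_id`` string
index of length n_postcodes.  Externally computed embeddings (e.g. real
fc6 codes) can be supplied in the same layout and flow through the whole
pipeline unchanged.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .ordinal_net import Architecture, ModelParams
from .synthetic_city import City, FeatureBlocks, SyntheticCityConfig

__all__ = [
    "save_geography", "load_geography",
    "save_outcomes", "load_outcomes",
    "save_features", "load_features",
    "save_city", "load_city_tables",
    "save_checkpoint", "load_checkpoint",
    "load_config",
]

CHECKPOINT_SCHEMA_VERSION = 1


def save_geography(geography: pd.DataFrame, path: str | Path) -> None:
    geography[["postcode_id", "lsoa_id", "x", "y"]].to_csv(path, index=False)


def load_geography(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"postcode_id": str, "lsoa_id": str})
    missing = {"postcode_id", "lsoa_id", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"geography file missing columns {sorted(missing)}")
    return df


def save_outcomes(outcomes: pd.DataFrame, path: str | Path) -> None:
    outcomes[["lsoa_id", "outcome", "raw_value", "decile"]].to_csv(path, index=False)


def load_outcomes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"lsoa_id": str, "outcome": str})
    missing = {"lsoa_id", "outcome", "raw_value", "decile"} - set(df.columns)
    if missing:
        raise ValueError(f"outcome file missing columns {sorted(missing)}")
    df["decile"] = df["decile"].astype(int)
    return df


def save_features(features: FeatureBlocks, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=features.values)
        f.create_dataset(
            "postcode_id",
            data=np.asarray(features.postcode_ids, dtype="S"),
        )
        f["features"].attrs["axis_order"] = "postcode,view,feature"
        f["features"].attrs["view_order_degrees"] = [0, 90, 180, 270]


def load_features(path: str | Path) -> FeatureBlocks:
    with h5py.File(path, "r") as f:
        values = f["features"][...]
        ids = np.array([s.decode() for s in f["postcode_id"][...]])
    return FeatureBlocks(ids, values)


def save_city(city: City, features: FeatureBlocks | None, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_geography(city.geography, out / "geography.csv")
    save_outcomes(city.outcomes, out / "outcomes.csv")
    if features is not None:
        save_features(features, out / "features.h5")


def load_city_tables(data_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, FeatureBlocks]:
    data = Path(data_dir)
    return (
        load_geography(data / "geography.csv"),
        load_outcomes(data / "outcomes.csv"),
        load_features(data / "features.h5"),
    )


def save_checkpoint(params: ModelParams, path: str | Path, train_config: dict | None = None) -> None:
    """Single-file archive: weights + BN moments + architecture + config."""
    meta = {
        "schema_version": CHECKPOINT_SCHEMA_VERSION,
        "architecture": asdict(params.arch),
        "trained": params.trained,
        "train_config": train_config or {},
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **params.weights,
    )


def load_checkpoint(path: str | Path) -> ModelParams:
    with np.load(path) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        if meta["schema_version"] != CHECKPOINT_SCHEMA_VERSION:
            raise ValueError(f"unsupported checkpoint schema {meta['schema_version']}")
        arch_d = meta["architecture"]
        arch = Architecture(
            feature_dim=arch_d["feature_dim"],
            channel_widths=tuple(arch_d["channel_widths"]),
            head_widths=tuple(arch_d["head_widths"]),
            n_classes=arch_d["n_classes"],
            parameterization=arch_d["parameterization"],
        )
        weights = {k: archive[k] for k in archive.files if k != "__meta__"}
    return ModelParams(arch=arch, weights=weights, trained=meta["trained"])


def load_config(path: str | Path) -> dict:
    """YAML run config with sections generator/model/training/evaluation."""
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def generator_config_from_dict(d: dict, seed: int | None = None) -> SyntheticCityConfig:
    kwargs = dict(d)
    if "outcome_corr" in kwargs and kwargs["outcome_corr"] is not None:
        kwargs["outcome_corr"] = np.asarray(kwargs["outcome_corr"], dtype=float)
    for key in ("higher_is_better", "outcome_names"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    if seed is not None:
        kwargs["seed"] = seed
    return SyntheticCityConfig(**kwargs)
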