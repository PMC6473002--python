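import numpy as np
import pytest

import streetdecile as sd


@pytest.fixture(scope="session")
def tiny_city():
    """Small high-signal city shared by training-dependent tests."""
    cfg = sd.SyntheticCityConfig(
        n_lsoa=60, postcodes_per_lsoa=4, signal_to_noise=50.0,
        feature_dim=16, seed=42,
    )
    city = sd.generate_city(cfg)
    features = sd.generate_features(city)
    return city, features


@pytest.fixture(scope="session")
def tiny_train_config():
    return sd.TrainConfig(n_iterations=600, batch_size=32, eval_every=50, seed=7)


@pytest.fixture(scope="session")
def tiny_trained(tiny_city, tiny_train_config):
    """One trained model on the tiny city (decile labels of outcome_1)."""
    city, features = tiny_city
    labels = city.postcode_deciles("outcome_1").loc[list(features.postcode_ids)]
    arch = sd.Architecture(feature_dim=16, channel_widths=(32, 16), head_widths=(16,))
    params, history = sd.train(
        features, labels.to_numpy(), tiny_train_config, arch=arch
    )
    return params, history
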