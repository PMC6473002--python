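"""Ordinal head and network: binomial class probabilities, the
cross-entropy objective, exact gradients, and the training contract."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit
from scipy.stats import binom

import streetdecile as sd
from streetdecile import ordinal_net
from streetdecile.ordinal_net import (
    _loss_grad_z,
    _net_backward,
    _net_forward,
    binomial_class_probs,
    init_params,
    ordinal_nll,
)


def is_unimodal(v):
    """No strict local minimum between two larger entries."""
    v = np.asarray(v)
    rising = True
    for i in range(1, len(v)):
        if v[i] > v[i - 1] + 1e-15:
            if not rising:
                return False
        elif v[i] < v[i - 1] - 1e-15:
            rising = False
    return True


class TestBinomialClassProbs:
    @pytest.mark.parametrize("K", [2, 5, 10])
    @pytest.mark.parametrize("p", np.linspace(0, 1, 11))
    def test_matches_scipy_binomial_pmf(self, p, K):
        probs = binomial_class_probs(p, K)
        expected = binom.pmf(np.arange(K), K - 1, p)
        np.testing.assert_allclose(probs, expected, atol=1e-12)
        assert abs(probs.sum() - 1.0) < 1e-9
        assert is_unimodal(probs)

    def test_degenerate_endpoints(self):
        np.testing.assert_array_equal(binomial_class_probs(0.0, 10),
                                      np.eye(10)[0])
        np.testing.assert_array_equal(binomial_class_probs(1.0, 10),
                                      np.eye(10)[9])

    def test_half_probability_values(self):
        probs = binomial_class_probs(0.5, 10)
        assert probs[0] == pytest.approx(1 / 512, abs=1e-15)
        assert probs[4] == pytest.approx(126 / 512, abs=1e-15)
        np.testing.assert_allclose(probs, probs[::-1])  # symmetric about middle

    @given(st.floats(0, 1), st.integers(2, 12))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_mode_is_the_binomial_mode(self, p, K):
        probs = binomial_class_probs(p, K)
        assert abs(probs.sum() - 1) < 1e-9
        assert is_unimodal(probs)
        mode = int(math.floor((K - 1 + 1) * p))  # floor((n+1)p), clipped
        mode = min(mode, K - 1)
        assert probs[np.argmax(probs)] == pytest.approx(probs[mode], abs=1e-12)

    def test_refuses_invalid_p(self):
        with pytest.raises(ValueError):
            binomial_class_probs(-0.1, 10)
        with pytest.raises(ValueError):
            binomial_class_probs(1.1, 10)

    def test_renormalized_variant_is_a_distribution(self):
        probs = binomial_class_probs(0.3, 10, parameterization="binom_k_renorm")
        assert probs.shape == (10,)
        assert probs.sum() == pytest.approx(1.0)
        assert is_unimodal(probs)


class TestOrdinalNll:
    def test_zero_loss_at_certainty(self):
        y = np.eye(10)[3]
        assert ordinal_nll(y, y) == pytest.approx(0.0)

    def test_middle_class_at_half_probability(self):
        probs = binomial_class_probs(0.5, 10)
        y = np.eye(10)[4]  # true class 5
        assert ordinal_nll(probs, y) == pytest.approx(-math.log(126 / 512), rel=1e-9)

    def test_floor_keeps_loss_finite_at_zero_probability(self):
        probs = binomial_class_probs(0.0, 10)
        y = np.eye(10)[9]  # true class has probability exactly 0
        loss = ordinal_nll(probs, y)
        assert math.isfinite(loss) and loss == pytest.approx(-math.log(1e-12))

    def test_loss_for_top_class_decreases_in_p(self):
        # below p ~ 0.04 the true-class probability p^9 hits the 1e-12
        # floor and the loss plateaus by design; strict monotonicity holds
        # everywhere above the floor
        grid = np.linspace(0.05, 0.99, 95)
        y = np.eye(10)[9]
        losses = [ordinal_nll(binomial_class_probs(p, 10), y) for p in grid]
        assert np.all(np.diff(losses) < 0)

    @pytest.mark.parametrize("m", range(1, 11))
    def test_minimized_at_class_anchor(self, m):
        # population stationarity: argmin_p NLL(class m) = (m-1)/(K-1)
        grid = np.linspace(0, 1, 1001)
        y = np.eye(10)[m - 1]
        losses = [ordinal_nll(binomial_class_probs(p, 10), y) for p in grid]
        assert grid[int(np.argmin(losses))] == pytest.approx((m - 1) / 9, abs=2e-3)

    def test_population_minimizer_recovers_true_p(self):
        # labels drawn from Binomial(9, p*): empirical mean NLL is minimized
        # near p* (the head is a well-specified likelihood)
        rng = np.random.default_rng(0)
        p_star = 0.3
        counts = rng.binomial(9, p_star, size=10_000)
        grid = np.linspace(0.01, 0.99, 197)
        mat = binomial_class_probs(grid, 10)  # (grid, K)
        mean_nll = [-np.log(np.clip(mat[i, counts], 1e-12, None)).mean()
                    for i in range(len(grid))]
        assert grid[int(np.argmin(mean_nll))] == pytest.approx(p_star, abs=0.02)

    def test_shape_and_one_hot_validation(self):
        with pytest.raises(ValueError):
            ordinal_nll(binomial_class_probs(0.5, 10), np.full(10, 0.1))


class TestGradients:
    @pytest.mark.parametrize("parameterization", ["binom_km1", "binom_k_renorm"])
    def test_loss_gradient_through_sigmoid_and_binomial(self, parameterization):
        rng = np.random.default_rng(1)
        z = rng.normal(scale=2.0, size=40)
        classes = rng.integers(0, 10, size=40)
        analytic = _loss_grad_z(expit(z), classes.astype(float), 10, parameterization)
        eps = 1e-6

        def nll(zv, c):
            probs = binomial_class_probs(expit(np.array(zv)), 10, parameterization)
            return -math.log(max(float(probs[c]), 1e-300))

        numeric = np.array(
            [(nll(zi + eps, c) - nll(zi - eps, c)) / (2 * eps)
             for zi, c in zip(z, classes)]
        )
        np.testing.assert_allclose(analytic, numeric, rtol=1e-4, atol=1e-7)

    def test_full_network_backward_matches_finite_differences(self):
        arch = sd.Architecture(feature_dim=5, channel_widths=(4, 3), head_widths=(3,))
        params = init_params(arch, seed=3)
        rng = np.random.default_rng(4)
        x = rng.normal(size=(6, 4, 5))
        classes = rng.integers(0, 10, size=6)

        def loss_at(weights):
            saved = params.weights
            params.weights = weights
            try:
                z = _net_forward(params, x, train_mode=True)
            finally:
                params.weights = saved
            p = expit(z)
            probs = binomial_class_probs(p, 10)
            return -np.log(
                np.clip(probs[np.arange(6), classes], 1e-12, None)
            ).sum()

        cache = {}
        z = _net_forward(params, x, train_mode=True, cache=cache)
        dz = _loss_grad_z(expit(z), classes.astype(float), 10, "binom_km1")
        grads = _net_backward(params, dz, cache)

        eps = 1e-6
        for key in ["enc0.W", "enc1.gamma", "head0.beta", "out.W", "out.b"]:
            g = grads[key]
            flat_idx = [(0,) * g.ndim, tuple(s - 1 for s in g.shape)]
            for idx in flat_idx:
                w_plus = {k: v.copy() for k, v in params.weights.items()}
                w_minus = {k: v.copy() for k, v in params.weights.items()}
                w_plus[key][idx] += eps
                w_minus[key][idx] -= eps
                numeric = (loss_at(w_plus) - loss_at(w_minus)) / (2 * eps)
                assert numeric == pytest.approx(g[idx], rel=1e-4, abs=1e-7), key


class TestForward:
    def test_zero_output_layer_gives_symmetric_binomial(self):
        arch = sd.Architecture(feature_dim=6, channel_widths=(4,), head_widths=(3,))
        params = init_params(arch, seed=0)
        params.weights["out.W"][:] = 0.0
        params.weights["out.b"][:] = 0.0
        x = np.random.default_rng(1).normal(size=(5, 4, 6))
        out = sd.forward(params, x, mode="train")
        np.testing.assert_allclose(out.z, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.p, 0.5)
        np.testing.assert_allclose(
            out.class_probs, np.tile(binom.pmf(np.arange(10), 9, 0.5), (5, 1))
        )

    def test_eval_mode_is_deterministic(self, tiny_trained, tiny_city):
        params, _ = tiny_trained
        _, feats = tiny_city
        a = sd.forward(params, feats.values[:8], mode="eval")
        b = sd.forward(params, feats.values[:8], mode="eval")
        np.testing.assert_array_equal(a.z, b.z)
        np.testing.assert_array_equal(a.class_probs, b.class_probs)

    def test_class_probs_normalized(self, tiny_trained, tiny_city):
        params, _ = tiny_trained
        _, feats = tiny_city
        out = sd.forward(params, feats.values[:32], mode="eval")
        np.testing.assert_allclose(out.class_probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all([is_unimodal(row) for row in out.class_probs])

    def test_eval_before_training_is_refused(self):
        params = init_params(sd.Architecture(feature_dim=4), seed=0)
        with pytest.raises(RuntimeError, match="running moments"):
            sd.forward(params, np.zeros((1, 4, 4)), mode="eval")

    def test_shape_mismatch_is_refused(self, tiny_trained):
        params, _ = tiny_trained
        with pytest.raises(ValueError, match="dim"):
            sd.forward(params, np.zeros((2, 4, 99)), mode="eval")


class TestTrain:
    def test_same_seed_gives_identical_params(self, tiny_city, tiny_train_config):
        city, feats = tiny_city
        labels = city.postcode_deciles("outcome_1").loc[list(feats.postcode_ids)]
        arch = sd.Architecture(feature_dim=16, channel_widths=(16,), head_widths=(8,))
        cfg = sd.TrainConfig(n_iterations=200, eval_every=50, seed=3)
        p1, _ = sd.train(feats, labels.to_numpy(), cfg, arch=arch)
        p2, _ = sd.train(feats, labels.to_numpy(), cfg, arch=arch)
        for k in p1.weights:
            np.testing.assert_array_equal(p1.weights[k], p2.weights[k])

    def test_learnable_signal_reduces_training_loss(self, tiny_trained):
        _, history = tiny_trained
        assert history["train_loss"][-1] < history["train_loss"][0]
        assert history["best_val_mae"] < 2.0  # far better than the ~3.3 null

    def test_refuses_single_class_labels(self, tiny_city):
        _, feats = tiny_city
        labels = np.full(feats.n_postcodes, 5)
        with pytest.raises(ValueError, match="2 distinct classes"):
            sd.train(feats, labels, sd.TrainConfig(n_iterations=10, seed=0))

    def test_refuses_out_of_range_labels(self, tiny_city):
        _, feats = tiny_city
        labels = np.full(feats.n_postcodes, 11)
        with pytest.raises(ValueError, match="1..10"):
            sd.train(feats, labels, sd.TrainConfig(n_iterations=10, seed=0))


class TestPredictPostcodes:
    def test_batched_equals_one_at_a_time(self, tiny_trained, tiny_city):
        params, _ = tiny_trained
        _, feats = tiny_city
        sub = sd.FeatureBlocks(feats.postcode_ids[:10], feats.values[:10])
        batched = sd.predict_postcodes(params, sub)
        for i in range(10):
            single = sd.forward(params, feats.values[i], mode="eval")
            assert batched["z"].iloc[i] == pytest.approx(single.z[0], abs=1e-6)

    def test_p_is_sigmoid_of_z(self, tiny_trained, tiny_city):
        params, _ = tiny_trained
        _, feats = tiny_city
        preds = sd.predict_postcodes(params, feats)
        np.testing.assert_allclose(preds["p"], expit(preds["z"]), atol=1e-9)


class TestCheckpointRoundTrip:
    def test_save_load_preserves_predictions(self, tiny_trained, tiny_city, tmp_path):
        from streetdecile import io

        params, _ = tiny_trained
        _, feats = tiny_city
        path = tmp_path / "model.ckpt.npz"
        io.save_checkpoint(params, path, train_config={"seed": 7})
        loaded = io.load_checkpoint(path)
        a = sd.predict_postcodes(params, feats)
        b = sd.predict_postcodes(loaded, feats)
        np.testing.assert_array_equal(a["z"].to_numpy(), b["z"].to_numpy())
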