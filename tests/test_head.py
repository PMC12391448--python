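"""Hybrid head: forward anatomy, loss, loader, optimizer and training loop."""

import numpy as np
import pytest

from vqchead.head import (
    HeadWeights,
    HybridHeadClassifier,
    HybridHeadConfig,
    HybridHeadResults,
    SGDGroups,
    TrainingConfig,
    cosine_lr,
    forward_batch,
    head_forward,
    make_balanced_loader,
    overfit_gap,
    smoothed_cross_entropy,
    _backward,
)
from vqchead.synthetic import SyntheticSpec, generate_splits
from vqchead.vqc import VQCParams


def tiny_config(head_kind="vqc", **kw):
    return HybridHeadConfig(in_dim=4, n_qubits=4, n_layers=1,
                            head_kind=head_kind, **kw)


def zero_weights(config):
    rng = np.random.default_rng(0)
    w = HeadWeights.init(config, rng)
    w.w_in[:] = 0
    w.b_in[:] = 0
    return w


class TestHeadForward:
    def test_cascaded_identities_reduce_to_output_bias(self):
        cfg = tiny_config()
        w = zero_weights(cfg)
        w.b_out[:] = [0.3, -0.7]
        vp = VQCParams.zeros(4, 1)
        logits = head_forward(cfg, w, vp, np.ones(4))
        # zero W_in -> zero features -> uniform state -> <Z> = 0 -> logits = b_out
        assert np.allclose(logits, [0.3, -0.7], atol=1e-12)

    def test_fc_identity_passthrough(self):
        cfg = HybridHeadConfig(in_dim=4, n_qubits=4, head_kind="fc")
        w = zero_weights(cfg)
        w.w_in[:] = np.eye(4)
        w.w_mid[:] = np.eye(4)
        w.w_out[:] = np.eye(4)[:2]
        x = np.array([0.0, 1.0, 0.0, 0.0])
        logits = head_forward(cfg, w, None, x)
        assert np.allclose(logits, [0.0, 1.0])

    def test_shot_forward_converges_to_analytic(self, rng):
        cfg = tiny_config()
        w = HeadWeights.init(cfg, rng)
        vp = VQCParams.random(4, 1, rng)
        x = rng.standard_normal(4)
        exact = head_forward(cfg, w, vp, x)
        shots = 100_000
        cfg_shots = HybridHeadConfig(in_dim=4, n_qubits=4, n_layers=1,
                                     shots=shots)
        noisy = head_forward(cfg_shots, w, vp, x, seed=7)
        # middle coordinates deviate by <= 3/sqrt(shots); logits are a
        # bounded linear map of them
        bound = 3.0 / np.sqrt(shots) * (np.abs(w.w_out).sum(axis=1).max())
        assert np.abs(noisy - exact).max() <= bound

    def test_dimension_mismatch(self):
        cfg = tiny_config()
        w = zero_weights(cfg)
        with pytest.raises(ValueError):
            head_forward(cfg, w, VQCParams.zeros(4, 1), np.ones(5))


class TestLoss:
    def test_uniform_logits_give_ln2(self):
        assert smoothed_cross_entropy([0.0, 0.0], 1, 0.0) == pytest.approx(
            np.log(2))

    def test_confident_correct_prediction_vanishes(self):
        assert smoothed_cross_entropy([-30.0, 30.0], 1, 0.0) < 1e-10

    def test_smoothing_invariant_at_uniform_prediction(self):
        # targets still sum to 1, so -sum t * log(1/2) = ln 2 for any s
        assert smoothed_cross_entropy([0.0, 0.0], 0, 0.1) == pytest.approx(
            np.log(2))

    def test_smoothing_bounds_confident_loss_away_from_zero(self):
        assert smoothed_cross_entropy([-30.0, 30.0], 1, 0.1) > 1.0

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.standard_normal((5, 2))
        labels = rng.integers(0, 2, 5)
        _, grad = smoothed_cross_entropy(logits, labels, 0.1, return_grad=True)
        h = 1e-7
        for b in range(5):
            for c in range(2):
                lp = logits.copy()
                lp[b, c] += h
                lm = logits.copy()
                lm[b, c] -= h
                fd = (smoothed_cross_entropy(lp, labels, 0.1)
                      - smoothed_cross_entropy(lm, labels, 0.1)) / (2 * h)
                assert abs(grad[b, c] - fd) < 1e-6


class TestBalancedLoader:
    def test_oversamples_minority_to_half(self):
        y = np.array([0] * 900 + [1] * 100)
        idx = make_balanced_loader(y, 1000, seed=3)
        n_pos = int(np.sum(y[idx]))
        sigma = np.sqrt(1000 * 0.25)
        assert abs(n_pos - 500) <= 3 * sigma

    def test_balanced_data_stays_balanced(self):
        y = np.array([0, 1] * 200)
        idx = make_balanced_loader(y, 400, seed=5)
        assert abs(int(np.sum(y[idx])) - 200) <= 3 * np.sqrt(400 * 0.25)

    def test_deterministic_under_seed(self):
        y = np.array([0] * 30 + [1] * 10)
        a = make_balanced_loader(y, 100, seed=11)
        b = make_balanced_loader(y, 100, seed=11)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            make_balanced_loader(np.zeros(10, dtype=int), 10, seed=0)


class TestSchedule:
    def test_cosine_midpoint_is_half(self):
        assert cosine_lr(0.004, 40, 80) == pytest.approx(0.002)

    def test_cosine_starts_full_ends_zero(self):
        assert cosine_lr(1.0, 0, 80) == pytest.approx(1.0)
        assert cosine_lr(1.0, 80, 80) == pytest.approx(0.0, abs=1e-15)


class TestOverfitGap:
    def test_identical_curves_give_zero(self):
        g, series = overfit_gap([1.0, 0.5], [1.0, 0.5])
        assert g == 0.0 and np.all(series == 0.0)

    def test_constant_offset_recovered(self):
        t = np.linspace(1.0, 0.2, 10)
        g, series = overfit_gap(t, t + 0.135)
        assert g == pytest.approx(0.135)
        assert series.shape == (10,)
        assert np.all(np.isfinite(series))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            overfit_gap([1.0], [1.0, 2.0])


class TestOptimizer:
    def test_learning_rate_grouping(self):
        """Quantum angles move with lr_quantum, classical maps with lr_classical."""
        params = {"w_in": np.zeros((2, 2)), "vqc": np.zeros((1, 2, 3))}
        opt = SGDGroups({k: v.shape for k, v in params.items()},
                        momentum=0.0, weight_decay=0.0)
        grads = {"w_in": np.ones((2, 2)), "vqc": np.ones((1, 2, 3))}
        opt.step(params, grads, lr_classical=0.0004, lr_quantum=0.004)
        assert np.allclose(params["w_in"], -0.0004)
        assert np.allclose(params["vqc"], -0.004)

    def test_weight_decay_only_on_classical(self):
        params = {"w_in": np.full((2, 2), 10.0), "vqc": np.full((1, 1, 3), 10.0)}
        opt = SGDGroups({k: v.shape for k, v in params.items()},
                        momentum=0.0, weight_decay=0.1)
        grads = {"w_in": np.zeros((2, 2)), "vqc": np.zeros((1, 1, 3))}
        opt.step(params, grads, lr_classical=1.0, lr_quantum=1.0)
        assert np.allclose(params["w_in"], 9.0)   # decayed
        assert np.allclose(params["vqc"], 10.0)   # untouched

    def test_momentum_accumulates(self):
        params = {"w": np.zeros(1)}
        opt = SGDGroups({"w": (1,)}, momentum=0.9, weight_decay=0.0,
                        quantum_keys=frozenset())
        for _ in range(2):
            opt.step(params, {"w": np.ones(1)}, 1.0, 1.0)
        # steps: -1, then -(0.9 + 1) => total -2.9
        assert params["w"][0] == pytest.approx(-2.9)


def _small_data(seed=0, n=60, p=4):
    spec = SyntheticSpec(n_samples=n, n_features=p, separation=3.0, seed=seed)
    return generate_splits(spec, n_val=30)


class TestTraining:
    def test_zero_learning_rates_freeze_everything(self):
        (Xtr, ytr), (Xv, yv) = _small_data()
        cfg = tiny_config()
        model = HybridHeadClassifier(Xtr, ytr, cfg)
        # plain loader so every epoch sees the same sample set once
        tc = TrainingConfig(epochs=3, lr_classical=0.0, lr_quantum=0.0,
                            balanced_resampling=False, seed=1)
        res = model.fit(tc, Xv, yv)
        assert np.ptp(res.train_curve) < 1e-12
        assert np.ptp(res.val_curve) < 1e-12

    def test_seeded_determinism_bit_identical(self):
        (Xtr, ytr), (Xv, yv) = _small_data()
        cfg = tiny_config()
        tc = TrainingConfig(epochs=3, seed=4)
        r1 = HybridHeadClassifier(Xtr, ytr, cfg).fit(tc, Xv, yv)
        r2 = HybridHeadClassifier(Xtr, ytr, cfg).fit(tc, Xv, yv)
        assert np.array_equal(r1.train_curve, r2.train_curve)
        assert np.array_equal(r1.val_curve, r2.val_curve)
        assert np.array_equal(r1.vqc_params.angles, r2.vqc_params.angles)

    def test_single_step_decreases_single_sample_loss(self, rng):
        """Gradient flow: a small SGD step reduces the trained sample's loss."""
        cfg = tiny_config()
        x = rng.standard_normal(4)
        y = 1
        for trial in range(20):
            init = np.random.default_rng(100 + trial)
            w = HeadWeights.init(cfg, init)
            vp = VQCParams.random(4, 1, init)
            params = {"w_in": w.w_in, "b_in": w.b_in, "w_out": w.w_out,
                      "b_out": w.b_out, "vqc": vp.angles}
            logits, u, z, amps = forward_batch(cfg, w, vp, x[None, :])
            loss0, dlogits = smoothed_cross_entropy(logits, [y], 0.0,
                                                    return_grad=True)
            grads = _backward(cfg, w, vp, x[None, :], u, z, amps, dlogits)
            opt = SGDGroups({k: v.shape for k, v in params.items()},
                            momentum=0.0, weight_decay=0.0)
            opt.step(params, grads, 1e-4, 1e-4)
            logits1, *_ = forward_batch(cfg, w, vp, x[None, :])
            loss1 = smoothed_cross_entropy(logits1, [y], 0.0)
            assert loss1 < loss0

    def test_parameter_shift_training_mode_matches_adjoint_gradients(self, rng):
        cfg = tiny_config()
        w = HeadWeights.init(cfg, rng)
        vp = VQCParams.random(4, 1, rng)
        X = rng.standard_normal((3, 4))
        yb = np.array([0, 1, 1])
        logits, u, z, amps = forward_batch(cfg, w, vp, X)
        _, dlogits = smoothed_cross_entropy(logits, yb, 0.1, return_grad=True)
        g_adj = _backward(cfg, w, vp, X, u, z, amps, dlogits, "adjoint")
        g_psr = _backward(cfg, w, vp, X, u, z, amps, dlogits, "parameter_shift")
        for key in g_adj:
            assert np.abs(g_adj[key] - g_psr[key]).max() < 1e-8

    def test_middle_block_parameter_counts(self):
        vqc = HybridHeadConfig(in_dim=8, n_qubits=8, n_layers=2, head_kind="vqc")
        fc = HybridHeadConfig(in_dim=8, n_qubits=8, head_kind="fc")
        assert vqc.middle_param_count() == 48       # 3KN
        assert fc.middle_param_count() == 72        # N^2 + N

    def test_fc_head_trains_too(self):
        (Xtr, ytr), (Xv, yv) = _small_data()
        cfg = HybridHeadConfig(in_dim=4, n_qubits=4, head_kind="fc")
        res = HybridHeadClassifier(Xtr, ytr, cfg).fit(
            TrainingConfig(epochs=5, seed=2), Xv, yv)
        assert len(res.train_curve) == 5
        assert np.all(np.isfinite(res.train_curve))

    def test_results_save_load_round_trip(self, tmp_path):
        (Xtr, ytr), (Xv, yv) = _small_data()
        cfg = tiny_config()
        res = HybridHeadClassifier(Xtr, ytr, cfg).fit(
            TrainingConfig(epochs=2, seed=3), Xv, yv)
        path = tmp_path / "model.json"
        res.save(path)
        back = HybridHeadResults.load(path)
        assert np.allclose(back.predict_logits(Xv), res.predict_logits(Xv))
        assert np.array_equal(back.history["train_loss"].to_numpy(),
                              res.train_curve)

    def test_summary_mentions_key_quantities(self):
        (Xtr, ytr), (Xv, yv) = _small_data()
        res = HybridHeadClassifier(Xtr, ytr, tiny_config()).fit(
            TrainingConfig(epochs=2, seed=0), Xv, yv)
        text = res.summary()
        assert "overfit gap" in text and "middle-block params" in text
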