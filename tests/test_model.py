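import numpy as np
import pytest

from sesnet.model import (
    ModelParams,
    TrainingConfig,
    TrainingError,
    forward,
    gradients,
    grid_search,
    init_model,
    load_checkpoint,
    loss,
    save_checkpoint,
    train,
)


def tiny_dataset(n=200, d=8, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = np.tanh(X[:, 0]) + 0.3 * X[:, 1]
    return X, y


class TestInit:
    def test_default_parameter_count(self):
        p = init_model(64, 32, seed=0)
        assert p.n_parameters == 96 * 64 + 64 + 64 * 32 + 32 + 32 * 1 + 1 == 8321

    def test_seed_determinism(self):
        a, b = init_model(16, 8, seed=5), init_model(16, 8, seed=5)
        for k in a.arrays():
            np.testing.assert_array_equal(a.arrays()[k], b.arrays()[k])

    def test_smallest_search_architecture(self):
        assert init_model(8, 8, seed=0).sizes == (96, 8, 8, 1)

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            init_model(0, 8)


class TestForward:
    def test_zero_parameters_give_zero(self):
        p = init_model(4, 3, seed=0, d_in=6)
        zero = ModelParams(**{k: np.zeros_like(v) for k, v in p.arrays().items()})
        out = forward(zero, np.random.default_rng(0).normal(size=(7, 6)))
        np.testing.assert_array_equal(out, 0.0)

    def test_batch_consistency(self):
        p = init_model(8, 4, seed=1, d_in=10)
        X = np.random.default_rng(1).normal(size=(12, 10))
        whole = forward(p, X)
        split = np.concatenate([forward(p, X[:5]), forward(p, X[5:])])
        np.testing.assert_allclose(whole, split, atol=1e-6)

    def test_hand_computed_single_unit(self):
        # x=[1,2] -> z1 = 1+2+0.5 = 3.5 -> z2 = 2*3.5-1 = 6 -> out = 0.5*6+0.25
        p = ModelParams(
            W1=np.array([[1.0], [1.0]]), b1=np.array([0.5]),
            W2=np.array([[2.0]]), b2=np.array([-1.0]),
            W3=np.array([[0.5]]), b3=np.array([0.25]),
        )
        assert forward(p, np.array([[1.0, 2.0]]))[0] == pytest.approx(3.25, abs=1e-6)

    def test_dimension_mismatch_raises(self):
        p = init_model(4, 3, seed=0, d_in=6)
        with pytest.raises(ValueError, match="feature dim"):
            forward(p, np.zeros((2, 5)))


class TestLoss:
    def test_perfect_and_shifted(self):
        y = np.array([0.0, 1.0, -1.0])
        assert loss(y, y) == 0.0
        assert loss(y + 1, y) == pytest.approx(1.0)

    def test_hand_computed(self):
        assert loss(np.array([0.0, 2.0]), np.array([1.0, 1.0])) == pytest.approx(1.0)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            loss(np.array([]), np.array([]))


class TestGradients:
    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(3)
        base = init_model(3, 2, seed=3, d_in=4)
        # nonzero biases keep pre-activations away from the ReLU kink, where
        # the derivative is undefined and finite differences straddle it
        p = ModelParams(
            **{k: v + rng.normal(0.3, 0.2, v.shape) for k, v in base.arrays().items()}
        )
        X = rng.normal(size=(5, 4))
        y = rng.normal(size=5)
        grads, _ = gradients(p, X, y)
        eps = 1e-6
        for name, arr in p.arrays().items():
            flat_idx = [(0,) * arr.ndim, tuple(d - 1 for d in arr.shape)]
            for idx in flat_idx:
                plus = {k: v.copy() for k, v in p.arrays().items()}
                minus = {k: v.copy() for k, v in p.arrays().items()}
                plus[name][idx] += eps
                minus[name][idx] -= eps
                lp = loss(forward(ModelParams(**plus), X), y)
                lm = loss(forward(ModelParams(**minus), X), y)
                numeric = (lp - lm) / (2 * eps)
                analytic = grads[name][idx]
                assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-8)


class TestTrain:
    def test_zero_learning_rate_is_identity(self):
        X, y = tiny_dataset()
        p0 = init_model(6, 4, seed=0, d_in=X.shape[1])
        cfg = TrainingConfig(learning_rate=0.0, epochs=3, batch_size=64, optimizer="sgd", seed=0)
        p1, hist = train(p0, (X, y), cfg)
        for k in p0.arrays():
            np.testing.assert_array_equal(p0.arrays()[k], p1.arrays()[k])
        assert len(set(np.round(hist.train_loss, 12))) == 1

    def test_seeded_training_reproducible(self):
        X, y = tiny_dataset()
        cfg = TrainingConfig(learning_rate=1e-2, epochs=5, batch_size=32, optimizer="adam", seed=9)
        h1 = train(init_model(6, 4, seed=9, d_in=X.shape[1]), (X, y), cfg)[1]
        h2 = train(init_model(6, 4, seed=9, d_in=X.shape[1]), (X, y), cfg)[1]
        assert h1.train_loss == h2.train_loss
        assert h1.val_mae == h2.val_mae

    def test_loss_decreases(self):
        X, y = tiny_dataset(400)
        cfg = TrainingConfig(learning_rate=1e-2, epochs=30, batch_size=64, optimizer="adam", seed=0)
        _, hist = train(init_model(16, 8, seed=0, d_in=X.shape[1]), (X, y), cfg)
        assert hist.train_loss[-1] < hist.train_loss[0] / 5

    def test_divergence_raises_with_epoch(self):
        X, y = tiny_dataset(100)
        cfg = TrainingConfig(learning_rate=1e12, epochs=5, batch_size=32, optimizer="sgd", seed=0)
        with np.errstate(all="ignore"), pytest.raises(TrainingError, match="epoch"):
            train(init_model(6, 4, seed=0, d_in=X.shape[1]), (X, y), cfg)

    def test_history_lengths_match_epochs(self):
        X, y = tiny_dataset()
        cfg = TrainingConfig(learning_rate=1e-3, epochs=4, batch_size=64, seed=0)
        _, hist = train(init_model(4, 4, seed=0, d_in=X.shape[1]), (X, y), cfg)
        assert hist.n_epochs == len(hist.val_mae) == len(hist.val_r2) == 4


class TestGridSearch:
    def test_row_per_architecture_pair(self):
        X, y = tiny_dataset(150)
        cfg = TrainingConfig(learning_rate=1e-2, epochs=2, batch_size=64, seed=0)
        table = grid_search([8, 16], [8, 16], (X, y), cfg)
        assert len(table) == 4
        assert set(table.columns) == {"h2", "h3", "mae", "r2"}
        assert set(zip(table.h2, table.h3)) == {(8, 8), (8, 16), (16, 8), (16, 16)}

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError):
            grid_search([], [8], (np.zeros((4, 8)), np.zeros(4)))

    def test_wider_third_layer_improves_median_mae(self):
        """With h2 = 64 fixed, growing h3 from 8 to 40 should not hurt the
        median validation MAE over seeds once capacity is the binding factor."""
        import sesnet as sn

        mol = sn.generate_synthetic("cluster", 20, seed=3)
        grid = sn.make_grid(mol, 0.5)
        field = sn.label_level_set(mol, grid, sn.ProbeParams(1.4))
        feats, y = sn.feature_dataset(field, mol, k=24, subsample=12000, seed=0, balanced=True)
        medians = {}
        for h3 in (8, 40):
            maes = []
            for seed in range(5):
                cfg = TrainingConfig(
                    learning_rate=3e-3, epochs=150, batch_size=1024, optimizer="adam",
                    lr_decay=0.99, validation_fraction=0.2, dtype="float32", seed=seed,
                )
                _, hist = train(init_model(64, h3, seed=seed), (feats, y), cfg)
                maes.append(min(hist.val_mae))
            medians[h3] = float(np.median(maes))
        assert medians[40] <= medians[8]


class TestCheckpoint:
    def test_round_trip_forward_bitwise(self, tmp_path):
        p = init_model(12, 6, seed=2, d_in=16)
        path = tmp_path / "m.ckpt.npz"
        save_checkpoint(p, path, k=4, clamp=1.0)
        p2, meta = load_checkpoint(path)
        X = np.random.default_rng(2).normal(size=(9, 16))
        np.testing.assert_array_equal(forward(p, X), forward(p2, X))
        assert meta["k"] == 4 and meta["clamp"] == 1.0
        assert meta["h2"] == 12 and meta["h3"] == 6 and meta["activation"] == "relu"

    def test_truncated_file_rejected(self, tmp_path):
        p = init_model(4, 3, seed=0, d_in=4)
        path = tmp_path / "m.ckpt.npz"
        save_checkpoint(p, path)
        path.write_bytes(path.read_bytes()[:40])
        with pytest.raises(ValueError, match="checkpoint"):
            load_checkpoint(path)
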