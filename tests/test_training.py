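"""Loss/metric oracles, early stopping and the training loop contract."""

import numpy as np
import pytest

from brainrate.nn import Dense, Sequential
from brainrate.training import (EarlyStopper, TrainConfig, TrainingDivergedError,
                                evaluate, mape, mse, train)


class TestMetrics:
    def test_mse_trivia(self):
        assert mse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert mse([0.0, 0.0], [1.0, 1.0]) == 1.0

    def test_mape_trivia(self):
        assert mape([100.0], [90.0]) == pytest.approx(10.0)
        assert mape([3.0, 4.0], [3.0, 4.0]) == 0.0

    def test_against_definition_loops(self, rng):
        for _ in range(100):
            n = rng.integers(1, 30)
            y = rng.uniform(1, 10, n)
            y_hat = rng.uniform(1, 10, n)
            assert mse(y, y_hat) == pytest.approx(sum((a - b) ** 2 for a, b in zip(y, y_hat)) / n,
                                                  rel=1e-9)
            assert mape(y, y_hat) == pytest.approx(
                100.0 / n * sum(abs((a - b) / a) for a, b in zip(y, y_hat)), rel=1e-9)

    def test_mape_rejects_zero_observations(self):
        with pytest.raises(ValueError):
            mape([0.0, 1.0], [1.0, 1.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse([1.0], [1.0, 2.0])


class TestEarlyStopper:
    def test_plateau_stops_exactly_at_patience(self):
        """Improvement through epoch 3, then flat: stop at epoch 9, best = 3."""
        stopper = EarlyStopper(patience=6)
        losses = [3.0, 2.0, 1.0] + [1.0] * 10
        stopped_at = None
        for epoch, loss in enumerate(losses, start=1):
            if stopper.update(loss, epoch):
                stopped_at = epoch
                break
        assert stopped_at == 9
        assert stopper.best_epoch == 3

    def test_strictly_improving_stream_never_stops(self):
        stopper = EarlyStopper(patience=6)
        assert not any(stopper.update(1.0 / e, e) for e in range(1, 61))

    def test_recovery_resets_the_streak(self):
        stopper = EarlyStopper(patience=3)
        for epoch, loss in enumerate([5, 6, 6, 4, 6, 6], start=1):
            assert not stopper.update(loss, epoch)
        assert stopper.best_epoch == 4


class _LinearModel:
    """One dense layer; enough to exercise the training loop contract."""

    def __init__(self, dim, seed):
        self.net = Sequential([Dense(dim, 1, np.random.default_rng(seed))])

    @property
    def params(self):
        return self.net.params

    @property
    def grads(self):
        return self.net.grads

    def zero_grad(self):
        for g in self.grads:
            g[...] = 0

    def forward(self, x, training=False):
        return self.net.forward(x.reshape(len(x), -1).astype(np.float32), training)[:, 0]

    def backward(self, dy):
        self.net.backward(np.asarray(dy, dtype=np.float32)[:, None])


def _linear_problem(n=64, dim=6, seed=0, noise=0.05):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, dim))
    w = rng.normal(size=dim)
    y = X @ w + noise * rng.normal(size=n)
    return X, y


class TestTrainLoop:
    def test_learns_a_linear_map_and_restores_best_weights(self):
        X, y = _linear_problem()
        model = _LinearModel(6, seed=1)
        cfg = TrainConfig(max_epochs=200, batch_size=16, patience=6, seed=0,
                          learning_rate=1e-2)
        hist = train(model, (X[:48], y[:48]), (X[48:], y[48:]), cfg)
        assert min(hist.val_loss) < 0.02
        # restored weights reproduce the best recorded validation loss
        final_val = mse(y[48:], model.forward(X[48:]))
        assert final_val == pytest.approx(min(hist.val_loss), rel=1e-5)
        assert hist.best_epoch == int(np.argmin(hist.val_loss)) + 1

    def test_same_seed_gives_identical_history(self):
        X, y = _linear_problem()
        cfg = TrainConfig(max_epochs=10, batch_size=16, seed=5, learning_rate=1e-2)
        h1 = train(_LinearModel(6, seed=2), (X[:48], y[:48]), (X[48:], y[48:]), cfg)
        h2 = train(_LinearModel(6, seed=2), (X[:48], y[:48]), (X[48:], y[48:]), cfg)
        assert h1.train_loss == h2.train_loss and h1.val_loss == h2.val_loss

    def test_early_stop_on_plateau_retains_pre_plateau_model(self):
        """A model that cannot improve plateaus; patience 6 ends training early."""
        X, y = _linear_problem(noise=0.0)
        model = _LinearModel(6, seed=1)
        cfg = TrainConfig(max_epochs=60, batch_size=16, patience=6, seed=0,
                          learning_rate=0.0 + 1e-12)  # effectively frozen -> flat stream
        hist = train(model, (X[:48], y[:48]), (X[48:], y[48:]), cfg)
        assert hist.early_stopped
        assert hist.stopped_epoch == hist.best_epoch + 6

    def test_diverged_loss_aborts(self):
        X, y = _linear_problem()
        model = _LinearModel(6, seed=1)
        model.params[0][...] = np.inf
        with pytest.raises(TrainingDivergedError):
            train(model, (X, y), (X, y), TrainConfig(max_epochs=2))

    def test_empty_sets_rejected(self):
        X, y = _linear_problem()
        with pytest.raises(ValueError):
            train(_LinearModel(6, 0), (X[:0], y[:0]), (X, y), TrainConfig())


class TestEvaluate:
    def test_perfect_predictions(self):
        X, y = _linear_problem(n=20)
        report = evaluate(None, (X, y), predictions=y.copy())
        assert report.mape == 0.0 and report.mse == 0.0
        assert report.pearson_r == pytest.approx(1.0)

    def test_constant_predictor_correlation_is_flagged_undefined(self):
        X, y = _linear_problem(n=20)
        report = evaluate(None, (X, y), trial_ids=["t0"] * 10 + ["t1"] * 10,
                          predictions=np.full(20, 2.5))
        assert report.pearson_r is None
        assert report.pearson_r_per_trial == {"t0": None, "t1": None}
        assert report.degenerate

    def test_per_trial_pearson_matches_definition(self, rng):
        y = rng.uniform(1, 5, 30)
        y_hat = y + rng.normal(0, 0.3, 30)
        trials = ["a"] * 15 + ["b"] * 15
        report = evaluate(None, (np.zeros((30, 1)), y), trial_ids=trials, predictions=y_hat)
        for key, sel in (("a", slice(0, 15)), ("b", slice(15, 30))):
            c = np.corrcoef(y[sel], y_hat[sel])[0, 1]
            assert report.pearson_r_per_trial[key] == pytest.approx(c, rel=1e-9)
        assert report.pearson_r_mean == pytest.approx(
            np.mean(list(report.pearson_r_per_trial.values())), rel=1e-9)

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate(None, (np.zeros((0, 1)), np.zeros(0)), predictions=np.zeros(0))
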