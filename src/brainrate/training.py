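"""Self-supervised training and evaluation protocol.

Models are fit by minimising mean squared error with Adam (learning rate
1e-3, moment decays 0.9/0.999), minibatches of 32 (or 100), and early
stopping with patience 6 on the validation loss: training halts once the
validation loss has not improved for 6 consecutive epochs and the weights
from the best validation epoch are restored.

Evaluation reports MSE, MAPE (in percent, 100/n * sum |y - yhat| / y) and
the Pearson correlation between predicted and observed brain-rate series,
per trial and pooled.  ``run_experiment`` drives the within-/across-subject
protocol: split trials, assemble datasets, train, evaluate, one result row
per trained model.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import CNNLSTMRegressor, CNNRegressor, CNNSpec, FullModelSpec
from .nn import Adam
from .sequencing import (SequenceInstance, assemble_dataset, build_sequences,
                         monte_carlo_plans, split_by_trial)

__all__ = ["TrainConfig", "History", "EvalReport", "EarlyStopper",
           "TrainingDivergedError", "mse", "mape", "train", "evaluate",
           "collate", "run_experiment"]

logger = logging.getLogger(__name__)


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""


def mse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean squared error, 1/n * sum (y_i - yhat_i)^2."""
    y, y_hat = _aligned(y, y_hat)
    return float(np.mean((y - y_hat) ** 2))


def mape(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean absolute percentage error, 100/n * sum |(y_i - yhat_i) / y_i|."""
    y, y_hat = _aligned(y, y_hat)
    if np.any(y == 0):
        raise ValueError("MAPE undefined: observed series contains zeros")
    return float(100.0 * np.mean(np.abs((y - y_hat) / y)))


def _aligned(y, y_hat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=np.float64).ravel()
    y_hat = np.asarray(y_hat, dtype=np.float64).ravel()
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if y.size == 0:
        raise ValueError("empty series")
    return y, y_hat


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation protocol settings."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    patience: int = 6
    max_epochs: int = 60
    seed: int = 0
    standardize_targets: bool = False
    standardize_inputs: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


class EarlyStopper:
    """Patience-based early stopping on a loss stream (lower is better)."""

    def __init__(self, patience: int) -> None:
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = np.inf
        self.best_epoch: int | None = None
        self.bad_streak = 0

    def update(self, loss: float, epoch: int) -> bool:
        """Record this epoch's validation loss; True means stop now."""
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self.bad_streak = 0
            return False
        self.bad_streak += 1
        return self.bad_streak >= self.patience


@dataclass
class History:
    """Per-epoch loss record of one training run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int | None = None
    stopped_epoch: int | None = None
    early_stopped: bool = False

    def to_json(self) -> dict:
        return {"train_loss": self.train_loss, "val_loss": self.val_loss,
                "best_epoch": self.best_epoch, "stopped_epoch": self.stopped_epoch,
                "early_stopped": self.early_stopped}


def collate(instances: Sequence[SequenceInstance]) -> tuple[np.ndarray, np.ndarray, list]:
    """Stack sequence instances into (X [n, z, 32, 32, 5], y [n], trial ids)."""
    if not instances:
        raise ValueError("no instances to collate")
    X = np.stack([
        np.stack([t.grid if hasattr(t, "grid") else np.asarray(t) for t in inst.tensors])
        for inst in instances
    ]).astype(np.float32)
    y = np.array([inst.target_br for inst in instances], dtype=np.float64)
    trials = [(inst.participant_id, inst.trial_id) for inst in instances]
    return X, y, trials


def _predict(model, X: np.ndarray, batch: int = 64) -> np.ndarray:
    out = [model.forward(X[i : i + batch], training=False) for i in range(0, len(X), batch)]
    return np.concatenate(out).astype(np.float64)


def train(model, train_set: tuple[np.ndarray, np.ndarray],
          val_set: tuple[np.ndarray, np.ndarray],
          config: TrainConfig = TrainConfig()) -> History:
    """Fit ``model`` in place; returns the training history.

    Stops at ``max_epochs`` or when the validation loss has not improved for
    ``patience`` consecutive epochs, whichever comes first, and restores the
    weights of the best validation epoch (the model from ``patience`` epochs
    before the stop).  Deterministic given ``config.seed``.
    """
    X_tr, y_tr = train_set
    X_va, y_va = val_set
    if len(X_tr) == 0 or len(X_va) == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params, lr=config.learning_rate,
               beta1=config.beta1, beta2=config.beta2)
    stopper = EarlyStopper(config.patience)
    hist = History()
    best_weights = None
    y_tr32 = y_tr.astype(np.float32)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(X_tr))
        ep_loss, n_seen = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            pred = model.forward(X_tr[idx], training=True)
            resid = pred - y_tr32[idx]
            loss = float(np.mean(resid.astype(np.float64) ** 2))
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            model.zero_grad()
            model.backward(2.0 * resid / len(idx))
            opt.step(model.grads)
            ep_loss += loss * len(idx)
            n_seen += len(idx)
        val_loss = mse(y_va, _predict(model, X_va))
        hist.train_loss.append(ep_loss / n_seen)
        hist.val_loss.append(val_loss)
        if val_loss < stopper.best:
            best_weights = [p.copy() for p in model.params]
        stop = stopper.update(val_loss, epoch)
        if stop:
            hist.early_stopped = True
            break
    hist.best_epoch = stopper.best_epoch
    hist.stopped_epoch = len(hist.val_loss)
    if best_weights is not None:
        for p, w in zip(model.params, best_weights):
            p[...] = w
    return hist


@dataclass
class EvalReport:
    """Test-set metrics of one trained model."""

    mse: float
    mape: float
    pearson_r: float | None            # pooled over all test sequences
    pearson_r_per_trial: dict
    pearson_r_mean: float | None       # mean over trials with defined r
    n: int
    degenerate: bool = False           # some correlation was undefined

    def to_json(self) -> dict:
        return {"mse": self.mse, "mape": self.mape, "pearson_r": self.pearson_r,
                "pearson_r_per_trial": {str(k): v for k, v in self.pearson_r_per_trial.items()},
                "pearson_r_mean": self.pearson_r_mean, "n": self.n,
                "degenerate": self.degenerate}


def _pearson(y: np.ndarray, y_hat: np.ndarray) -> float | None:
    if len(y) < 2 or np.std(y) == 0 or np.std(y_hat) == 0:
        return None
    return float(stats.pearsonr(y, y_hat).statistic)


def evaluate(model, test_set: tuple[np.ndarray, np.ndarray],
             trial_ids: Sequence | None = None, *,
             predictions: np.ndarray | None = None) -> EvalReport:
    """Evaluate on a held-out set: MSE, MAPE (%), Pearson r per trial and pooled.

    A correlation is undefined when either series is constant within a trial;
    such trials are reported as None and flagged, never silently dropped.
    """
    X_te, y_te = test_set
    if len(y_te) == 0:
        raise ValueError("empty test set")
    y_hat = _predict(model, X_te) if predictions is None else np.asarray(predictions, dtype=np.float64)
    per_trial: dict = {}
    if trial_ids is not None:
        for key in dict.fromkeys(trial_ids):  # preserve order, unique
            sel = np.array([t == key for t in trial_ids])
            per_trial[key] = _pearson(y_te[sel], y_hat[sel])
    defined = [v for v in per_trial.values() if v is not None]
    pooled = _pearson(y_te, y_hat)
    return EvalReport(
        mse=mse(y_te, y_hat),
        mape=mape(y_te, y_hat),
        pearson_r=pooled,
        pearson_r_per_trial=per_trial,
        pearson_r_mean=float(np.mean(defined)) if defined else None,
        n=len(y_te),
        degenerate=pooled is None or (len(per_trial) > 0 and len(defined) < len(per_trial)),
    )


# ---------------------------------------------------------------------------
# experiment driver

TrialData = Mapping[str, tuple[Sequence, Sequence[float]]]
"""Per trial: (window tensor list/array, brain rate per window)."""


def _sequences_for(trials: TrialData, pid: str, z: int) -> dict[str, list[SequenceInstance]]:
    return {
        tid: build_sequences(tensors, brs, z=z, participant_id=pid, trial_id=tid)
        for tid, (tensors, brs) in trials.items()
    }


def _make_model(arch: str, z: int, seed: int, *, cnn_spec: CNNSpec | None = None,
                full_spec: FullModelSpec | None = None):
    if arch == "cnn":
        return CNNRegressor(cnn_spec or CNNSpec(), seed=seed)
    if arch == "cnn_lstm":
        spec = full_spec or FullModelSpec(z=z, cnn=cnn_spec or CNNSpec())
        if spec.z != z:
            raise ValueError("full model spec z disagrees with sequencing z")
        return CNNLSTMRegressor(spec, seed=seed)
    raise ValueError(f"unknown architecture {arch!r}")


def run_experiment(participants: Mapping[str, TrialData], *, kind: str = "within",
                   arch: str = "cnn_lstm", n_people: int = 1, repetitions: int = 1,
                   z: int = 7, config: TrainConfig = TrainConfig(),
                   fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                   cnn_spec: CNNSpec | None = None) -> pd.DataFrame:
    """Train and evaluate models per the within-/across-subject protocol.

    ``participants`` maps participant id -> trial id -> (window tensors,
    per-window brain rates).  The standalone CNN (``arch='cnn'``) is trained
    on z=1 sequences -- window i predicting the brain rate of window i+1 --
    so its trunk weights are directly transferable to the full model.

    Returns one row per trained model with split counts, epochs, losses,
    test MAPE (%), mean per-trial Pearson r and the flags that produced it.
    """
    if kind not in ("within", "across"):
        raise ValueError(f"unknown experiment kind {kind!r}")
    z_eff = 1 if arch == "cnn" else z
    rows = []
    pids = list(participants)
    if kind == "within":
        runs = [([pid], None) for pid in pids]
    else:
        trial_ids_of = {pid: list(participants[pid]) for pid in pids}
        runs = monte_carlo_plans(pids, n_people, repetitions=repetitions,
                                 fractions=fractions, trial_ids_of=trial_ids_of,
                                 seed=config.seed)
    for rep, (subset, plans) in enumerate(runs):
        row = {"kind": kind, "arch": arch, "repetition": rep,
               "participants": ",".join(subset), "seed": config.seed,
               "batch_size": config.batch_size, "z": z_eff,
               "standardize_targets": config.standardize_targets,
               "standardize_inputs": config.standardize_inputs}
        try:
            if plans is None:
                plans = {subset[0]: split_by_trial(list(participants[subset[0]]),
                                                  fractions, seed=config.seed + rep)}
            seqs = {pid: _sequences_for(participants[pid], pid, z_eff) for pid in subset}
            splits = assemble_dataset(seqs, plans)
            X_tr, y_tr, _ = collate(splits.train)
            X_va, y_va, _ = collate(splits.validation)
            X_te, y_te, te_trials = collate(splits.test)
            row.update(n_train=len(y_tr), n_val=len(y_va), n_test=len(y_te))

            mu_x, sd_x = 0.0, 1.0
            if config.standardize_inputs:
                mu_x = X_tr.mean()
                sd_x = X_tr.std() or 1.0
                X_tr, X_va, X_te = [(A - mu_x) / sd_x for A in (X_tr, X_va, X_te)]
            mu_y, sd_y = 0.0, 1.0
            if config.standardize_targets:
                mu_y, sd_y = y_tr.mean(), y_tr.std() or 1.0
            yt = (y_tr - mu_y) / sd_y
            yv = (y_va - mu_y) / sd_y

            model = _make_model(arch, z_eff, config.seed + rep, cnn_spec=cnn_spec)
            hist = train(model, (X_tr, yt), (X_va, yv), config)
            preds = _predict(model, X_te) * sd_y + mu_y
            report = evaluate(model, (X_te, y_te), te_trials, predictions=preds)

            baseline = mape(y_te, np.full_like(y_te, y_tr.mean()))
            row.update(
                epochs=hist.stopped_epoch, best_epoch=hist.best_epoch,
                early_stopped=hist.early_stopped,
                val_mse=hist.val_loss[hist.best_epoch - 1] * sd_y**2,
                test_mse=report.mse, test_mape=report.mape,
                baseline_mape=baseline,
                pearson_r_mean=report.pearson_r_mean,
                n_parameters=model.manifest()["n_parameters"],
                failed=False,
            )
        except Exception as exc:  # noqa: BLE001 - a failed run is a marked row
            logger.exception("experiment repetition %d failed", rep)
            row.update(failed=True, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)
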