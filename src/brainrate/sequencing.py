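"""Sliding-window segmentation, sequence assembly and trial-level splitting.

A recording is cut into overlapping windows of ``window_seconds`` (default
2 s) shifted by ``shift_seconds`` (default 125 ms).  A 63-s trial at 128 Hz
(8064 samples, 256-sample windows, 16-sample shift) yields 489 windows.
Sequences of z consecutive window tensors (default z = 7, i.e. 14 s of
activity) form the self-supervised training unit; the target is the brain
rate of the (z+1)-th window, the one immediately after the sequence, so a
63-s trial yields 489 - 7 = 482 sequences.

Splits are drawn at the *trial* ("video") level -- whole trials go to train,
validation or test -- so no trial contributes sequences to more than one
part.  With 40 trials and 70/15/15 fractions that is 28/6/6 trials, i.e.
13,496 / 2,892 / 2,892 sequences per participant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

__all__ = [
    "SequencingConfig",
    "SequenceInstance",
    "SplitPlan",
    "DatasetSplits",
    "slide_windows",
    "extract_windows",
    "build_sequences",
    "split_by_trial",
    "assemble_dataset",
    "monte_carlo_plans",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequencingConfig:
    """Windowing geometry: window length k, shift w (seconds) and sequence length z."""

    window_seconds: float = 2.0
    shift_seconds: float = 0.125
    sequence_length: int = 7

    def __post_init__(self) -> None:
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be >= 1")
        if self.window_seconds <= 0 or self.shift_seconds <= 0:
            raise ValueError("window and shift must be positive")

    def window_samples(self, fs: float) -> int:
        return _integral(self.window_seconds * fs, "window_seconds * fs")

    def shift_samples(self, fs: float) -> int:
        return _integral(self.shift_seconds * fs, "shift_seconds * fs")


def _integral(x: float, what: str) -> int:
    n = round(x)
    if abs(x - n) > 1e-9:
        raise ValueError(f"{what} = {x} is not an integral number of samples")
    return int(n)


@dataclass(frozen=True)
class SequenceInstance:
    """z consecutive window tensors plus the brain rate of the following window."""

    tensors: tuple[Any, ...]
    target_br: float
    participant_id: str | None = None
    trial_id: str | None = None
    first_window_index: int = 0

    @property
    def target_window_index(self) -> int:
        return self.first_window_index + len(self.tensors)


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint trial-id sets for train / validation / test, plus the seed used."""

    train: tuple[str, ...]
    validation: tuple[str, ...]
    test: tuple[str, ...]

    seed: int | None = None

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(p) for p in parts)
        if len(set().union(*parts)) != total:
            raise ValueError("split parts must be disjoint")

    @property
    def all_trials(self) -> set[str]:
        return set(self.train) | set(self.validation) | set(self.test)

    def part_of(self, trial_id: str) -> str:
        for name in ("train", "validation", "test"):
            if trial_id in getattr(self, name):
                return name
        raise KeyError(trial_id)

    def to_json(self) -> dict:
        return {"train": list(self.train), "validation": list(self.validation),
                "test": list(self.test), "seed": self.seed}

    @classmethod
    def from_json(cls, obj: Mapping) -> "SplitPlan":
        return cls(tuple(obj["train"]), tuple(obj["validation"]), tuple(obj["test"]),
                   obj.get("seed"))


def slide_windows(n_samples: int, window_samples: int, shift_samples: int) -> np.ndarray:
    """Start indices 0, S, 2S, ... of every full window; floor((N-L)/S)+1 of them."""
    if shift_samples < 1:
        raise ValueError("shift must be at least 1 sample")
    if window_samples < 1:
        raise ValueError("window must be at least 1 sample")
    if window_samples > n_samples:
        logger.warning("window (%d) longer than signal (%d); no windows produced",
                       window_samples, n_samples)
        return np.empty(0, dtype=np.int64)
    n = (n_samples - window_samples) // shift_samples + 1
    return np.arange(n, dtype=np.int64) * shift_samples


def extract_windows(data: np.ndarray, window_samples: int, shift_samples: int) -> np.ndarray:
    """View of a [n_channels x n_samples] matrix as [n_windows x n_channels x L]."""
    starts = slide_windows(data.shape[1], window_samples, shift_samples)
    return np.stack([data[:, s : s + window_samples] for s in starts]) if len(starts) else \
        np.empty((0, data.shape[0], window_samples))


def build_sequences(tensors: Sequence[Any], br_per_window: Sequence[float], *,
                    z: int = 7, participant_id: str | None = None,
                    trial_id: str | None = None) -> list[SequenceInstance]:
    """Assemble sequences of z consecutive windows with the next window's BR as target.

    One instance starts at every window index i = 0 .. n_windows - z - 1
    (stride one window), giving n_windows - z instances; the target of the
    instance starting at i is the brain rate of window i + z.
    """
    if len(tensors) != len(br_per_window):
        raise ValueError("need one brain rate per window")
    n = len(tensors) - z
    if n <= 0:
        logger.warning("only %d windows for sequence length z=%d; no sequences",
                       len(tensors), z)
        return []
    return [
        SequenceInstance(
            tensors=tuple(tensors[i : i + z]),
            target_br=float(br_per_window[i + z]),
            participant_id=participant_id,
            trial_id=trial_id,
            first_window_index=i,
        )
        for i in range(n)
    ]


def split_by_trial(trial_ids: Sequence[str],
                   fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                   seed: int | None = None) -> SplitPlan:
    """Shuffle trials and split whole trials ~70/15/15 into train/validation/test.

    Counts are round(f_train * V) and round(f_val * V) with half-up rounding
    (40 trials -> 28/6/6; 10 trials -> 7/2/1); the remainder goes to test.
    """
    ids = list(trial_ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 trials to form three non-empty parts")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n_train = int(np.floor(fractions[0] * len(ids) + 0.5))
    n_val = int(np.floor(fractions[1] * len(ids) + 0.5))
    n_test = len(ids) - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"split {n_train}/{n_val}/{n_test} has an empty part")
    return SplitPlan(
        train=tuple(shuffled[:n_train]),
        validation=tuple(shuffled[n_train : n_train + n_val]),
        test=tuple(shuffled[n_train + n_val :]),
        seed=seed,
    )


@dataclass
class DatasetSplits:
    """Concatenated sequence sets with per-participant bookkeeping."""

    train: list[SequenceInstance] = field(default_factory=list)
    validation: list[SequenceInstance] = field(default_factory=list)
    test: list[SequenceInstance] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {"train": len(self.train), "validation": len(self.validation),
                "test": len(self.test), "total": len(self.train) + len(self.validation) + len(self.test)}

    def manifest(self) -> list[dict]:
        rows = []
        for part in ("train", "validation", "test"):
            by_trial: dict[tuple, int] = {}
            for inst in getattr(self, part):
                key = (inst.participant_id, inst.trial_id)
                by_trial[key] = by_trial.get(key, 0) + 1
            for (pid, tid), n in sorted(by_trial.items(), key=str):
                rows.append({"participant": pid, "trial": tid, "part": part, "n_sequences": n})
        return rows


def assemble_dataset(
    sequences_by_participant: Mapping[str, Mapping[str, Sequence[SequenceInstance]]],
    plans: Mapping[str, SplitPlan],
) -> DatasetSplits:
    """Route each participant's trials into splits and concatenate across participants.

    ``sequences_by_participant`` maps participant -> trial -> sequence list.
    Every participant must have the same trial structure (same per-trial
    sequence counts); a mismatch is reported with the offending trial.
    """
    reference: dict[str, int] | None = None
    ref_pid = None
    out = DatasetSplits()
    for pid, trials in sequences_by_participant.items():
        shape = {tid: len(seqs) for tid, seqs in trials.items()}
        if reference is None:
            reference, ref_pid = shape, pid
        elif shape != reference:
            bad = sorted(set(shape.items()) ^ set(reference.items()))[0][0]
            raise ValueError(
                f"inconsistent trial structure: trial {bad!r} differs between "
                f"participants {ref_pid!r} and {pid!r}"
            )
        plan = plans[pid]
        if plan.all_trials != set(trials):
            raise ValueError(f"split plan for {pid!r} does not cover its trials exactly")
        for tid, seqs in trials.items():
            getattr(out, plan.part_of(tid)).extend(seqs)
    return out


def monte_carlo_plans(all_participants: Sequence[str], n_people: int, *,
                      repetitions: int = 10,
                      fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                      trial_ids_of: Mapping[str, Sequence[str]],
                      seed: int | None = None) -> list[tuple[list[str], dict[str, SplitPlan]]]:
    """Monte Carlo repetitions for across-subject models.

    Each repetition samples ``n_people`` participants without replacement and
    draws a fresh trial-level split plan per sampled participant.  Fully
    reproducible from ``seed``.
    """
    pool = list(all_participants)
    if n_people > len(pool):
        raise ValueError(f"requested {n_people} participants but only {len(pool)} available")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(repetitions):
        subset = [pool[i] for i in rng.choice(len(pool), size=n_people, replace=False)]
        plans = {
            pid: split_by_trial(trial_ids_of[pid], fractions,
                                seed=int(rng.integers(0, 2**31 - 1)))
            for pid in subset
        }
        out.append((subset, plans))
    return out
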