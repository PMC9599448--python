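"""End-to-end preprocessing: recordings -> window tensors and brain-rate series.

These helpers bind the spectral, topomap and sequencing stages together in
the order the method prescribes: slide windows over each trial, compute the
per-window head-map tensor and brain rate, and hand the per-trial pairs to
the experiment driver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EEGRecording
from .montage import Montage, standard_montage_1020
from .sequencing import SequencingConfig, extract_windows
from .spectral import BandScheme, brain_rate
from .synth import SyntheticStudy
from .topomap import HeadMapTensor, project_azimuthal_equidistant, window_to_tensor

__all__ = ["PreprocessConfig", "prepare_trial", "prepare_study", "brain_rate_table"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Settings shared by every window of a preprocessing run."""

    sequencing: SequencingConfig = SequencingConfig()
    scheme: BandScheme = BandScheme()
    br_mode: str = "sum_channels"
    br_variant: str = "mean_ratio"
    fill_value: float = 0.0


def prepare_trial(rec: EEGRecording, config: PreprocessConfig = PreprocessConfig(),
                  montage: Montage | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Windows of one trial -> (tensors [n_win, 32, 32, 5], brain rates [n_win])."""
    montage = montage or standard_montage_1020(rec.channel_names)
    projected = project_azimuthal_equidistant(montage)
    L = config.sequencing.window_samples(rec.fs)
    S = config.sequencing.shift_samples(rec.fs)
    windows = extract_windows(rec.data, L, S)
    tensors = np.empty((len(windows), 32, 32, len(config.scheme.bands)), dtype=np.float32)
    brs = np.empty(len(windows))
    for i, w in enumerate(windows):
        t = window_to_tensor(w, rec.fs, config.scheme, channel_names=rec.channel_names,
                             fill_value=config.fill_value, projected=projected)
        tensors[i] = t.grid
        brs[i] = brain_rate(w, rec.fs, config.scheme,
                            mode=config.br_mode, variant=config.br_variant).value
    return tensors, brs


def prepare_study(study: SyntheticStudy | dict, config: PreprocessConfig = PreprocessConfig()
                  ) -> dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Prepare every trial of a study for ``run_experiment``.

    Accepts a :class:`~brainrate.synth.SyntheticStudy` or a plain mapping of
    participant id -> list of recordings.  Returns participant -> trial ->
    (tensors, brain rates); the montage and projection are computed once.
    """
    participants = study.participants if isinstance(study, SyntheticStudy) else study
    out: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    montage = None
    for pid, trials in participants.items():
        out[pid] = {}
        for rec in trials:
            if montage is None:
                montage = standard_montage_1020(rec.channel_names)
            tid = rec.trial_id or f"t{len(out[pid]) + 1:02d}"
            out[pid][tid] = prepare_trial(rec, config, montage)
    return out


def brain_rate_table(prepared: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]) -> pd.DataFrame:
    """Flatten prepared brain-rate series to {participant, trial, window_index, brain_rate}."""
    rows = []
    for pid, trials in prepared.items():
        for tid, (_, brs) in trials.items():
            rows += [
                {"participant": pid, "trial": tid, "window_index": i, "brain_rate": float(v)}
                for i, v in enumerate(brs)
            ]
    return pd.DataFrame(rows)
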