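"""Synthetic EEG studies with controlled band-power structure.

Trials mimic the shape of a 32-channel video-watching study: 128 Hz, 63 s
(8064 samples), 40 trials per participant.  Each trial is a sum over the
five EEG bands of

    envelope_b(t) * gain_b(ch) * oscillation_b(ch, t)  +  broadband noise

where ``oscillation_b`` is unit-RMS narrow-band noise confined to band b
(or, in ``tone`` mode, a pure sinusoid at the band mid-frequency, useful for
exact-bin spectral oracles), ``envelope_b`` is a slow non-negative amplitude
modulation (the ground-truth cognitive-activation dynamics the pipeline
should recover), and ``gain_b`` is a smooth spatial gain over the scalp
(anterior-posterior and left-right gradients) so head maps carry learnable
structure.

Everything is reproducible from a seed; per-sample envelopes and gains are
returned as ground truth next to each recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import EEGRecording
from .montage import standard_montage_1020
from .spectral import BandScheme

__all__ = ["DEAP_CHANNELS", "BandSchedule", "SyntheticStudy", "generate_trial",
           "generate_study", "slow_drift_schedule"]

DEAP_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7", "CP5", "CP1", "P3",
    "P7", "PO3", "O1", "Oz", "Pz", "Fp2", "AF4", "Fz", "F4", "F8", "FC6",
    "FC2", "Cz", "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

#: Realistic resting-scale band RMS amplitudes in microvolts.
DEFAULT_BASE_UV: dict[str, float] = {
    "delta": 8.0, "theta": 6.0, "alpha": 10.0, "beta": 4.0, "gamma": 1.5,
}
#: Relative modulation depth of the slow envelopes (alpha/beta dominate,
#: mirroring load-sensitive rhythms).
DEFAULT_DEPTH: dict[str, float] = {
    "delta": 0.3, "theta": 0.4, "alpha": 0.8, "beta": 0.6, "gamma": 0.3,
}
DEFAULT_NOISE_UV = 2.0
ENVELOPE_PERIOD_RANGE = (15.0, 30.0)  # seconds; slow relative to 2-s windows


@dataclass
class BandSchedule:
    """Per-band amplitude envelopes, spatial gains and broadband noise level.

    ``envelopes`` holds one non-negative per-sample amplitude array (in
    microvolts RMS) per band name; ``gains`` one non-negative per-channel
    multiplier per band.  ``mode`` selects narrow-band noise carriers
    (``"noise"``, default) or pure mid-frequency tones (``"tone"``).
    """

    envelopes: dict[str, np.ndarray]
    gains: dict[str, np.ndarray]
    noise_uv: float = DEFAULT_NOISE_UV
    mode: str = "noise"
    scheme: BandScheme = field(default_factory=BandScheme)

    def __post_init__(self) -> None:
        for name, env in self.envelopes.items():
            if np.any(np.asarray(env) < 0):
                raise ValueError(f"negative envelope for band {name!r}")
        for name, g in self.gains.items():
            if np.any(np.asarray(g) < 0):
                raise ValueError(f"negative gain for band {name!r}")
        if self.mode not in ("noise", "tone"):
            raise ValueError(f"unknown oscillation mode {self.mode!r}")


@dataclass
class SyntheticStudy:
    """A cohort of synthetic participants with per-trial ground truth."""

    participants: dict[str, list[EEGRecording]]
    ground_truth: dict[tuple[str, str], dict]
    fs: float
    channel_names: tuple[str, ...]
    seed: int | None = None

    @property
    def participant_ids(self) -> list[str]:
        return list(self.participants)


def _band_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-RMS noise band-limited to [lo, hi] Hz by FFT masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < lo) | (freqs > hi)] = 0
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def slow_drift_schedule(n_channels: int = 32, fs: float = 128.0, seconds: float = 63.0,
                        *, channel_names: tuple[str, ...] = DEAP_CHANNELS,
                        seed: int | None = None,
                        base_uv: dict[str, float] | None = None,
                        depth: dict[str, float] | None = None,
                        noise_uv: float = DEFAULT_NOISE_UV,
                        mode: str = "noise") -> BandSchedule:
    """Draw a random slow-drift schedule: sinusoidal envelopes, smooth gains.

    Each band's envelope is base * (1 + depth * sin(2 pi t / T + phase)) with
    the period T drawn from 15-30 s, so band power drifts on a time scale
    several windows long -- the premise that makes the next-window brain rate
    predictable from the preceding sequence.
    """
    rng = np.random.default_rng(seed)
    base_uv = dict(DEFAULT_BASE_UV, **(base_uv or {}))
    depth = dict(DEFAULT_DEPTH, **(depth or {}))
    n = round(seconds * fs)
    t = np.arange(n) / fs
    scheme = BandScheme()
    montage = standard_montage_1020(list(channel_names[:n_channels]))
    pos = montage.as_array()
    envelopes, gains = {}, {}
    for band in scheme.bands:
        period = rng.uniform(*ENVELOPE_PERIOD_RANGE)
        phase = rng.uniform(0, 2 * np.pi)
        env = base_uv[band.name] * (1 + depth[band.name] * np.sin(2 * np.pi * t / period + phase))
        envelopes[band.name] = np.clip(env, 0, None)
        # smooth scalp gradient: anterior-posterior (y) and lateral (x) tilt
        a, b = rng.uniform(-0.4, 0.4, 2)
        gains[band.name] = np.clip(1 + a * pos[:, 1] + b * pos[:, 0], 0.2, None)
    return BandSchedule(envelopes=envelopes, gains=gains, noise_uv=noise_uv,
                        mode=mode, scheme=scheme)


def generate_trial(schedule: BandSchedule, n_channels: int = 32, fs: float = 128.0,
                   seconds: float = 63.0, seed: int | None = None, *,
                   channel_names: tuple[str, ...] = DEAP_CHANNELS,
                   participant_id: str | None = None,
                   trial_id: str | None = None) -> tuple[EEGRecording, dict]:
    """Synthesize one trial from a schedule; returns (recording, ground truth).

    Ground truth holds the per-sample band envelopes and per-channel gains
    actually used, aligned to the sample grid so per-window references can be
    derived for any windowing.
    """
    rng = np.random.default_rng(seed)
    n = round(seconds * fs)
    names = list(channel_names[:n_channels])
    data = np.zeros((n_channels, n))
    t = np.arange(n) / fs
    for band in schedule.scheme.bands:
        env = np.asarray(schedule.envelopes[band.name], dtype=np.float64)
        if len(env) != n:
            raise ValueError(f"envelope for {band.name!r} has {len(env)} samples, expected {n}")
        gain = np.asarray(schedule.gains[band.name], dtype=np.float64)
        if len(gain) != n_channels:
            raise ValueError(f"gain for {band.name!r} has {len(gain)} channels, expected {n_channels}")
        if schedule.mode == "tone":
            phases = rng.uniform(0, 2 * np.pi, n_channels)
            osc = np.sqrt(2.0) * np.sin(2 * np.pi * band.weight * t[None, :] + phases[:, None])
        else:
            osc = np.stack([_band_noise(rng, n, fs, band.lo, band.hi) for _ in range(n_channels)])
        data += env[None, :] * gain[:, None] * osc
    if schedule.noise_uv > 0:
        data += schedule.noise_uv * rng.standard_normal(data.shape)
    rec = EEGRecording(data=data, fs=fs, channel_names=names,
                       participant_id=participant_id, trial_id=trial_id)
    truth = {
        "band_envelopes": {k: v.copy() for k, v in schedule.envelopes.items()},
        "band_gains": {k: v.copy() for k, v in schedule.gains.items()},
        "noise_uv": schedule.noise_uv,
        "mode": schedule.mode,
    }
    return rec, truth


def generate_study(n_participants: int, n_trials: int = 40, *,
                   fs: float = 128.0, seconds: float = 63.0, n_channels: int = 32,
                   channel_names: tuple[str, ...] = DEAP_CHANNELS,
                   seed: int | None = None, noise_uv: float = DEFAULT_NOISE_UV,
                   mode: str = "noise") -> SyntheticStudy:
    """Generate a cohort of participants with independent slow-drift trials.

    Deterministic from ``seed``; participant p, trial t gets its own schedule
    and noise stream, so trials are independent but reproducible.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    root = np.random.default_rng(seed)
    participants: dict[str, list[EEGRecording]] = {}
    truths: dict[tuple[str, str], dict] = {}
    for p in range(n_participants):
        pid = f"p{p + 1:02d}"
        trials = []
        for tr in range(n_trials):
            tid = f"t{tr + 1:02d}"
            s_sched, s_trial = root.integers(0, 2**31 - 1, size=2)
            sched = slow_drift_schedule(n_channels, fs, seconds,
                                        channel_names=channel_names,
                                        seed=int(s_sched), noise_uv=noise_uv, mode=mode)
            rec, truth = generate_trial(sched, n_channels, fs, seconds, seed=int(s_trial),
                                        channel_names=channel_names,
                                        participant_id=pid, trial_id=tid)
            trials.append(rec)
            truths[(pid, tid)] = truth
        participants[pid] = trials
    return SyntheticStudy(participants=participants, ground_truth=truths,
                          fs=fs, channel_names=tuple(channel_names[:n_channels]),
                          seed=seed)
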