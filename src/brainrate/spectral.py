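"""Spectral features: band scheme, per-window FFT, band weights and brain rate.

The brain rate (BR) is a spectrum-weighted activation index.  For a window of
multi-channel EEG it is

    BR = sum_ch sum_b  f_b * P(b, ch)

where b runs over the five canonical bands (delta [0.5,4], theta (4,8],
alpha (8,12], beta (12,30], gamma (30,45] Hz), f_b is the band's
mid-frequency (2.25, 6, 10, 21, 37.5 Hz) and P(b, ch) weights band b of
channel ch.  Two weight variants are provided:

* ``mean_ratio`` (default, the definitional form): mean one-sided FFT amplitude
  inside the band divided by the mean amplitude over the whole 0.5-45 Hz
  analysis range.  These weights do not sum to one.
* ``power_fraction``: band power over total power, a proper convex weighting,
  under which the per-channel BR is bounded by [2.25, 37.5] Hz.

Both are scale invariant: multiplying the window by c > 0 changes nothing.
Channel aggregation is either the plain sum over channels (``sum_channels``,
the definitional form) or its mean (``mean_channels``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Band",
    "BandScheme",
    "ChannelSpectrum",
    "BandPowerMatrix",
    "BrainRate",
    "ZeroSpectrumError",
    "window_spectrum",
    "band_centroid",
    "band_weights",
    "band_power_matrix",
    "brain_rate",
]

ANALYSIS_RANGE = (0.5, 45.0)


class ZeroSpectrumError(ValueError):
    """A channel's spectrum is identically zero over the analysis range."""

    def __init__(self, channel: int | str):
        self.channel = channel
        super().__init__(f"zero spectrum over the analysis range (channel {channel})")


@dataclass(frozen=True)
class Band:
    """A frequency band [lo, hi] with boundary-inclusion flags and weight f_b (Hz)."""

    name: str
    lo: float
    hi: float
    lo_inclusive: bool
    hi_inclusive: bool

    @property
    def weight(self) -> float:
        """Mid-frequency f_b = (lo + hi) / 2 in Hz."""
        return (self.lo + self.hi) / 2.0

    def member_mask(self, freqs: np.ndarray) -> np.ndarray:
        lo_ok = freqs >= self.lo if self.lo_inclusive else freqs > self.lo
        hi_ok = freqs <= self.hi if self.hi_inclusive else freqs < self.hi
        return lo_ok & hi_ok


@dataclass(frozen=True)
class BandScheme:
    """The ordered five-band partition of the 0.5-45 Hz analysis range."""

    bands: tuple[Band, ...] = (
        Band("delta", 0.5, 4.0, True, True),
        Band("theta", 4.0, 8.0, False, True),
        Band("alpha", 8.0, 12.0, False, True),
        Band("beta", 12.0, 30.0, False, True),
        Band("gamma", 30.0, 45.0, False, True),
    )
    analysis_range: tuple[float, float] = ANALYSIS_RANGE

    def __post_init__(self) -> None:
        lo, hi = self.analysis_range
        if abs(self.bands[0].lo - lo) > 1e-12 or abs(self.bands[-1].hi - hi) > 1e-12:
            raise ValueError("bands must cover the analysis range")
        for a, b in zip(self.bands, self.bands[1:]):
            if abs(a.hi - b.lo) > 1e-12 or a.hi_inclusive == b.lo_inclusive:
                raise ValueError(f"bands {a.name}/{b.name} not contiguous and disjoint")

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    @property
    def weights(self) -> np.ndarray:
        """f_b for the five bands, in Hz."""
        return np.array([b.weight for b in self.bands])

    def __getitem__(self, name: str) -> Band:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)

    def to_config(self) -> list[dict]:
        return [
            {"name": b.name, "lo": b.lo, "hi": b.hi,
             "lo_inclusive": b.lo_inclusive, "hi_inclusive": b.hi_inclusive,
             "weight": b.weight}
            for b in self.bands
        ]

    @classmethod
    def from_config(cls, cfg: list[dict]) -> "BandScheme":
        bands = tuple(
            Band(c["name"], float(c["lo"]), float(c["hi"]),
                 bool(c["lo_inclusive"]), bool(c["hi_inclusive"]))
            for c in cfg
        )
        return cls(bands=bands, analysis_range=(bands[0].lo, bands[-1].hi))


@dataclass(frozen=True)
class ChannelSpectrum:
    """One-sided magnitude spectrum of one channel, restricted to 0.5-45 Hz."""

    freqs: np.ndarray
    amps: np.ndarray

    def __post_init__(self) -> None:
        if len(self.freqs) != len(self.amps):
            raise ValueError("freqs and amps length mismatch")
        if len(self.freqs) > 1 and not np.all(np.diff(self.freqs) > 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def is_zero(self) -> bool:
        return bool(np.all(self.amps == 0))


@dataclass(frozen=True)
class BandPowerMatrix:
    """Per-channel band centroids avg_b(FFT_ch) and weights P(b, ch), [n_channels x 5]."""

    centroids: np.ndarray
    weights: np.ndarray
    band_names: tuple[str, ...]


@dataclass(frozen=True)
class BrainRate:
    """A brain-rate value in Hz with the aggregation conventions that produced it."""

    value: float
    mode: str = "sum_channels"
    variant: str = "mean_ratio"

    def __float__(self) -> float:
        return self.value


def window_spectrum(window: np.ndarray, fs: float, *,
                    analysis_range: tuple[float, float] = ANALYSIS_RANGE,
                    power: bool = False) -> list[ChannelSpectrum]:
    """One-sided magnitude spectrum per channel, rectangular taper.

    Amplitudes are scaled by 2/L so an exact-bin unit sinusoid has amplitude
    one.  Bins are restricted to the analysis range (0.5-45 Hz by default);
    for a 2-s window at 128 Hz that grid is 0.5, 1.0, ..., 45.0 Hz (90 bins).
    With ``power=True`` squared magnitudes are returned instead.
    """
    window = np.atleast_2d(np.asarray(window, dtype=np.float64))
    L = window.shape[1]
    if L < 2:
        raise ValueError("window must contain at least 2 samples")
    if not fs > 0:
        raise ValueError("sampling rate must be positive")
    freqs = np.fft.rfftfreq(L, d=1.0 / fs)
    amps = np.abs(np.fft.rfft(window, axis=1)) * (2.0 / L)
    keep = (freqs >= analysis_range[0] - 1e-12) & (freqs <= analysis_range[1] + 1e-12)
    freqs = freqs[keep]
    amps = amps[:, keep]
    if power:
        amps = amps**2
    return [ChannelSpectrum(freqs=freqs, amps=a) for a in amps]


def band_centroid(spec: ChannelSpectrum, band: Band) -> float:
    """Arithmetic mean of the spectral amplitudes at the bins inside ``band``."""
    mask = band.member_mask(spec.freqs)
    if not mask.any():
        raise ValueError(f"band {band.name} has no bins on the frequency grid")
    return float(spec.amps[mask].mean())


def band_weights(spec: ChannelSpectrum, scheme: BandScheme = BandScheme(), *,
                 variant: str = "mean_ratio", channel: int | str = 0) -> np.ndarray:
    """The five weights P(b, ch) for one channel spectrum.

    ``mean_ratio`` returns avg_b(FFT_ch) / avg(FFT_ch); ``power_fraction``
    returns (band power) / (total power), which sums to one.
    """
    in_range = _range_mask(spec.freqs, scheme.analysis_range)
    if variant == "mean_ratio":
        overall = float(spec.amps[in_range].mean())
        if overall <= 0:
            raise ZeroSpectrumError(channel)
        return np.array([band_centroid(spec, b) / overall for b in scheme.bands])
    if variant == "power_fraction":
        pw = spec.amps**2
        total = float(pw[in_range].sum())
        if total <= 0:
            raise ZeroSpectrumError(channel)
        return np.array([pw[b.member_mask(spec.freqs)].sum() / total for b in scheme.bands])
    raise ValueError(f"unknown variant {variant!r}")


def _range_mask(freqs: np.ndarray, rng: tuple[float, float]) -> np.ndarray:
    return (freqs >= rng[0] - 1e-12) & (freqs <= rng[1] + 1e-12)


def band_power_matrix(window: np.ndarray, fs: float,
                      scheme: BandScheme = BandScheme(), *,
                      variant: str = "mean_ratio") -> BandPowerMatrix:
    """Band centroids and weights for every channel of a window."""
    specs = window_spectrum(window, fs, analysis_range=scheme.analysis_range)
    cent = np.array([[band_centroid(s, b) for b in scheme.bands] for s in specs])
    wts = np.array([
        band_weights(s, scheme, variant=variant, channel=i) for i, s in enumerate(specs)
    ])
    return BandPowerMatrix(centroids=cent, weights=wts, band_names=tuple(scheme.names))


def brain_rate(window: np.ndarray, fs: float,
               scheme: BandScheme = BandScheme(), *,
               mode: str = "sum_channels", variant: str = "mean_ratio") -> BrainRate:
    """Brain rate of a window: BR = sum_ch sum_b f_b * P(b, ch).

    ``mode='mean_channels'`` divides by the channel count; together with
    ``variant='power_fraction'`` BR is then a convex combination of the band
    mid-frequencies and lies in [2.25, 37.5] Hz.
    """
    if mode not in ("sum_channels", "mean_channels"):
        raise ValueError(f"unknown mode {mode!r}")
    bpm = band_power_matrix(window, fs, scheme, variant=variant)
    total = float((bpm.weights * scheme.weights).sum())
    if mode == "mean_channels":
        total /= bpm.weights.shape[0]
    return BrainRate(value=total, mode=mode, variant=variant)


def brain_rate_series(windows: np.ndarray, fs: float,
                      scheme: BandScheme = BandScheme(), *,
                      mode: str = "sum_channels", variant: str = "mean_ratio") -> np.ndarray:
    """Brain rate for each window of a [n_windows x n_channels x L] stack."""
    return np.array([
        brain_rate(w, fs, scheme, mode=mode, variant=variant).value for w in windows
    ])
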