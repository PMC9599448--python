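"""Reading and writing multi-channel EEG recordings.

Three on-disk formats are supported:

* ``interchange`` -- a channels x samples matrix (``.npy`` or ``.csv``) plus a
  JSON sidecar ``{fs, channel_names, participant_id, trial_id}``.  Lossless
  (bit-exact for ``.npy``); the fixture format used throughout the tests.
* ``edf`` -- European Data Format, 16-bit.
* ``bdf`` -- BioSemi data format, 24-bit.

EDF/BDF reading is delegated to :mod:`mne`.  Writing EDF/BDF is implemented
here directly (single data record, per-channel physical scaling), since the
round-trip precision of those formats is bounded by their integer sample
depth anyway; the mne reader doubles as an independent check of the writer.

Amplitudes are handled in microvolts throughout.  No filtering, resampling or
re-referencing is ever applied implicitly: the usual upstream preprocessing
(downsample to 128 Hz, 0.5-45 Hz band-pass, average reference) is expected to
have happened before data enter this package.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["EEGRecording", "FormatError", "ConsistencyError", "load_recording", "write_recording"]


class FormatError(ValueError):
    """File unreadable or malformed in the named format."""


class ConsistencyError(ValueError):
    """Sidecar metadata disagrees with the data matrix."""


@dataclass
class EEGRecording:
    """A multi-channel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Ordered channel labels, one per row of ``data``.
    participant_id, trial_id : str, optional
        Provenance tags carried through sidecars and manifests.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    participant_id: str | None = None
    trial_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2D channels x samples matrix")
        if self.data.shape[0] != len(self.channel_names):
            raise ConsistencyError(
                f"{self.data.shape[0]} data rows but {len(self.channel_names)} channel names"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains NaN or Inf")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def load_recording(path: str | Path, format: str = "interchange") -> EEGRecording:
    """Load a recording from ``path`` in the named format.

    The channel order is returned exactly as stored; nothing is resampled,
    filtered or re-referenced.
    """
    path = Path(path)
    if format == "interchange":
        return _load_interchange(path)
    if format in ("edf", "bdf"):
        return _load_edf_bdf(path, format)
    raise ValueError(f"unknown format {format!r}")


def write_recording(rec: EEGRecording, path: str | Path, format: str = "interchange") -> Path:
    """Write ``rec`` to ``path``; returns the path written."""
    path = Path(path)
    if rec.n_samples == 0:
        raise ValueError("refusing to write an empty recording (0 samples)")
    if format == "interchange":
        return _write_interchange(rec, path)
    if format in ("edf", "bdf"):
        return _write_edf_bdf(rec, path, format)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# interchange: matrix + JSON sidecar

def _write_interchange(rec: EEGRecording, path: Path) -> Path:
    if path.suffix == ".csv":
        np.savetxt(path, rec.data, delimiter=",", fmt="%.17g")
    else:
        if path.suffix != ".npy":
            path = path.with_suffix(".npy")
        np.save(path, rec.data)
    meta = {
        "fs": rec.fs,
        "channel_names": list(rec.channel_names),
        "participant_id": rec.participant_id,
        "trial_id": rec.trial_id,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _load_interchange(path: Path) -> EEGRecording:
    sidecar = _sidecar_path(path)
    if not path.exists() or not sidecar.exists():
        raise FormatError(f"missing matrix file or JSON sidecar for {path}")
    try:
        meta = json.loads(sidecar.read_text())
        if path.suffix == ".csv":
            data = np.loadtxt(path, delimiter=",", ndmin=2)
        else:
            data = np.load(path)
    except Exception as exc:  # noqa: BLE001 - normalize parse failures
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    names = meta["channel_names"]
    if data.shape[0] != len(names):
        raise ConsistencyError(
            f"matrix has {data.shape[0]} rows but sidecar lists {len(names)} channels"
        )
    return EEGRecording(
        data=data,
        fs=float(meta["fs"]),
        channel_names=list(names),
        participant_id=meta.get("participant_id"),
        trial_id=meta.get("trial_id"),
    )


# ---------------------------------------------------------------------------
# EDF (16-bit) / BDF (24-bit)

def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw + b" " * (width - len(raw))


def _write_edf_bdf(rec: EEGRecording, path: Path, fmt: str) -> Path:
    ns = rec.n_channels
    n_samp = rec.n_samples
    duration = rec.n_samples / rec.fs
    if fmt == "edf":
        magic = _pad("0", 8)
        reserved = _pad("", 44)
        dmin, dmax = -32768, 32767
        sample_bytes = 2
    else:
        magic = b"\xffBIOSEMI"
        reserved = _pad("24BIT", 44)
        dmin, dmax = -8388608, 8388607
        sample_bytes = 3

    pmin = rec.data.min(axis=1)
    pmax = rec.data.max(axis=1)
    flat = pmax - pmin <= 0
    pmax = np.where(flat, pmin + 1.0, pmax)

    header = bytearray()
    header += magic
    header += _pad(rec.participant_id or "X", 80)
    header += _pad(rec.trial_id or "X", 80)
    header += _pad("01.01.00", 8) + _pad("00.00.00", 8)
    header += _pad(str(256 * (ns + 1)), 8)
    header += reserved
    header += _pad("1", 8)  # one data record holding the whole signal
    header += _pad(f"{duration:.6g}", 8)
    header += _pad(str(ns), 4)
    for nm in rec.channel_names:
        header += _pad(nm, 16)
    for _ in range(ns):
        header += _pad("AgCl electrode", 80)
    for _ in range(ns):
        header += _pad("uV", 8)
    for v in pmin:
        header += _pad(f"{v:.6g}"[:8], 8)
    for v in pmax:
        header += _pad(f"{v:.6g}"[:8], 8)
    for _ in range(ns):
        header += _pad(str(dmin), 8)
    for _ in range(ns):
        header += _pad(str(dmax), 8)
    for _ in range(ns):
        header += _pad("", 80)
    for _ in range(ns):
        header += _pad(str(n_samp), 8)
    for _ in range(ns):
        header += _pad("", 32)

    # physical min/max are re-read from their truncated ASCII form so that the
    # digital scaling matches what any reader will reconstruct
    pmin_r = np.array([float(f"{v:.6g}"[:8]) for v in pmin])
    pmax_r = np.array([float(f"{v:.6g}"[:8]) for v in pmax])
    scale = (dmax - dmin) / (pmax_r - pmin_r)
    digital = np.rint((rec.data - pmin_r[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype(np.int64)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        if sample_bytes == 2:
            fh.write(digital.astype("<i2").tobytes())
        else:
            as32 = digital.astype("<i4").tobytes()
            buf = bytearray()
            for i in range(0, len(as32), 4):
                buf += as32[i : i + 3]  # little-endian 24-bit: drop the top byte
            fh.write(bytes(buf))
    return path


def _load_edf_bdf(path: Path, fmt: str) -> EEGRecording:
    import mne

    if not path.exists():
        raise FormatError(f"no such file: {path}")
    reader = mne.io.read_raw_edf if fmt == "edf" else mne.io.read_raw_bdf
    try:
        raw = reader(path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse {path} as {fmt.upper()}: {exc}") from exc
    data = raw.get_data(units="uV")
    info = _read_header_ids(path)
    return EEGRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        participant_id=info.get("participant_id"),
        trial_id=info.get("trial_id"),
    )


def _read_header_ids(path: Path) -> dict[str, str | None]:
    with open(path, "rb") as fh:
        head = fh.read(168)
    pid = head[8:88].decode("ascii", errors="replace").strip() or None
    tid = head[88:168].decode("ascii", errors="replace").strip() or None
    return {"participant_id": None if pid in (None, "X") else pid,
            "trial_id": None if tid in (None, "X") else tid}
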