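"""Electrode montage geometry on an idealized unit sphere.

EEG electrodes are addressed by their 10-20 / 10-10 site labels.  For the
head-map pipeline only the *relative* scalp geometry matters, so positions
are served on an idealized unit sphere centred in the head, with the vertex
electrode Cz at (0, 0, 1), +x toward the right ear and +y toward the nasion.

Coordinates are derived from the standard 10-05 electrode table embedded in
:mod:`mne` (sphere-fitted, rotated so Cz is the vertex and Fpz lies on the
+y meridian, then mirror-symmetrized across the sagittal plane), which keeps
homologous left/right pairs exactly symmetric.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = ["Montage", "MontageLookupError", "standard_montage_1020", "normalize_label"]


class MontageLookupError(KeyError):
    """Raised when one or more channel labels are not known 10-20/10-10 sites."""

    def __init__(self, unknown: list[str]):
        self.unknown = list(unknown)
        super().__init__(f"unknown 10-20/10-10 channel label(s): {', '.join(self.unknown)}")


@dataclass(frozen=True)
class Montage:
    """Map from channel label to a 3D unit-sphere position (head-centred, Cz at +z)."""

    positions: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return list(self.positions)

    def __len__(self) -> int:
        return len(self.positions)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.positions[label]

    def as_array(self, labels: list[str] | None = None) -> np.ndarray:
        """Stack positions for ``labels`` (default: montage order) into [n, 3]."""
        labels = self.labels if labels is None else labels
        return np.stack([self.positions[lb] for lb in labels])


_ZERO_FOR_O = re.compile(r"^([A-Za-z]+)0(\d)$")


def normalize_label(label: str) -> str:
    """Canonicalize an electrode label.

    Handles case variants (``FP1`` -> ``Fp1``, ``OZ`` -> ``Oz``) and the common
    transcription slip of a zero for the letter O in parieto-occipital sites
    (``P03`` -> ``PO3``).
    """
    s = label.strip()
    m = _ZERO_FOR_O.match(s)
    if m:
        s = f"{m.group(1)}O{m.group(2)}"
    # canonical capitalisation: letters upper-case except a lone trailing 'p'
    # in prefrontal sites (Fp*, AFp*, ...) and the midline suffix 'z'.
    s = s.upper().replace("FP", "Fp").replace("Z", "z")
    return s


def _mirror_label(label: str) -> str | None:
    """Label of the contralateral homologue, or None if not a numbered site."""
    m = re.match(r"^([A-Za-z]+?)(\d+)([Hh]?)$", label)
    if not m:
        return None
    num = int(m.group(2))
    partner = num + 1 if num % 2 == 1 else num - 1
    return f"{m.group(1)}{partner}{m.group(3)}"


@lru_cache(maxsize=1)
def _reference_table() -> dict[str, np.ndarray]:
    """Idealized spherical coordinates for every standard 10-05 site."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        monty = mne.channels.make_standard_montage("standard_1005")
    raw = monty.get_positions()["ch_pos"]
    labels = list(raw)
    pts = np.stack([raw[lb] for lb in labels])

    # least-squares sphere fit: |p - c|^2 = r^2  ->  linear in (c, r^2 - |c|^2)
    A = np.c_[2.0 * pts, np.ones(len(pts))]
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    unit = pts - center
    unit /= np.linalg.norm(unit, axis=1, keepdims=True)
    table = {normalize_label(lb): u for lb, u in zip(labels, unit)}

    # rotate Cz to the vertex
    table = _rotate_all(table, _rotation_to_z(table["Cz"]))
    # spin about z so Fpz (nasion side) sits on the +y meridian
    fpz = table["Fpz"]
    ang = np.arctan2(fpz[1], fpz[0])
    spin = np.pi / 2 - ang
    cz_, sz_ = np.cos(spin), np.sin(spin)
    rz = np.array([[cz_, -sz_, 0.0], [sz_, cz_, 0.0], [0.0, 0.0, 1.0]])
    table = _rotate_all(table, rz)

    # enforce exact sagittal mirror symmetry and exact unit norms
    sym: dict[str, np.ndarray] = {}
    for lb, p in table.items():
        partner = _mirror_label(lb)
        if "z" in lb:  # midline site: pin to the sagittal plane
            q = np.array([0.0, p[1], p[2]])
        elif partner is not None and partner in table:
            pm = table[partner]
            q = np.array([(abs(p[0]) + abs(pm[0])) / 2 * np.sign(p[0]),
                          (p[1] + pm[1]) / 2, (p[2] + pm[2]) / 2])
        else:
            q = p
        sym[lb] = q / np.linalg.norm(q)
    sym["Cz"] = np.array([0.0, 0.0, 1.0])
    for v in sym.values():
        v.setflags(write=False)
    return sym


def _rotation_to_z(v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector v to (0, 0, 1)."""
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    c = float(v @ z)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    theta = np.arctan2(s, c)
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def _rotate_all(table: dict[str, np.ndarray], R: np.ndarray) -> dict[str, np.ndarray]:
    return {lb: R @ p for lb, p in table.items()}


def standard_montage_1020(channel_names: list[str]) -> Montage:
    """Build a :class:`Montage` for the given 10-20/10-10 channel labels.

    Labels are normalized (case, the P03->PO3 zero-for-O slip) before lookup.
    Raises :class:`MontageLookupError` listing every unknown label.
    """
    table = _reference_table()
    unknown = [nm for nm in channel_names if normalize_label(nm) not in table]
    if unknown:
        raise MontageLookupError(unknown)
    return Montage({nm: table[normalize_label(nm)] for nm in channel_names})
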