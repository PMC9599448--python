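"""Spatially-preserving spectral head maps.

Per window, the five per-channel band centroids are turned into a 32x32x5
image tensor: electrode positions on the unit sphere are flattened with the
azimuthal equidistant (polar) projection about the vertex -- which preserves
the great-circle distance of every electrode from Cz -- and each band's
scattered centroid values are interpolated onto a regular grid with the
piecewise-cubic Clough-Tocher scheme over a Delaunay triangulation.

Orientation convention: +y is the nasion (front of head), +x the right ear;
image row 0 is the front.  Grid nodes outside the electrode convex hull,
where triangulation-based interpolation is undefined, take ``fill_value``
(default 0).  The grid extent is the bounding square of the projected
electrodes plus a 5% margin, fixed per montage so tensors are comparable
across windows and recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator
from scipy.spatial import QhullError

from .montage import Montage
from .spectral import BandScheme, band_power_matrix

__all__ = [
    "ProjectedMontage",
    "HeadMapTensor",
    "project_azimuthal_equidistant",
    "interpolate_band_map",
    "window_to_tensor",
    "render_tensor",
]

GRID_SIZE = 32
MARGIN = 0.05


@dataclass(frozen=True)
class ProjectedMontage:
    """Channel label -> 2D plane coordinates from the azimuthal equidistant projection."""

    labels: tuple[str, ...]
    points: np.ndarray  # [n, 2]

    def __getitem__(self, label: str) -> np.ndarray:
        return self.points[self.labels.index(label)]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """Bounding square (xmin, xmax, ymin, ymax) plus a 5% margin."""
        xmin, ymin = self.points.min(axis=0)
        xmax, ymax = self.points.max(axis=0)
        cx, cy = (xmin + xmax) / 2, (ymin + ymax) / 2
        half = max(xmax - xmin, ymax - ymin) / 2 * (1 + MARGIN)
        return (cx - half, cx + half, cy - half, cy + half)


@dataclass(frozen=True)
class HeadMapTensor:
    """A 32x32x5 interpolated spectral head map (rows front-to-back, bands delta..gamma)."""

    grid: np.ndarray
    extent: tuple[float, float, float, float]
    fill_value: float
    band_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.grid.shape != (GRID_SIZE, GRID_SIZE, len(self.band_names)):
            raise ValueError(f"head-map tensor must be {GRID_SIZE}x{GRID_SIZE}x{len(self.band_names)}")
        if not np.isfinite(self.grid).all():
            raise ValueError("head-map tensor contains non-finite values")


def project_azimuthal_equidistant(montage: Montage) -> ProjectedMontage:
    """Project unit-sphere electrode positions to the plane about the vertex.

    A channel at polar angle theta from the vertex and azimuth phi maps to
    (theta cos phi, theta sin phi), so its planar distance from the origin
    equals its great-circle arc distance from Cz.
    """
    labels = tuple(montage.labels)
    pos = montage.as_array()
    norms = np.linalg.norm(pos, axis=1)
    if np.any(np.abs(norms - 1) > 1e-6):
        raise ValueError("montage positions must lie on the unit sphere")
    z = np.clip(pos[:, 2], -1.0, 1.0)
    theta = np.arccos(z)
    if np.any(theta >= np.pi - 1e-9):
        bad = [labels[i] for i in np.nonzero(theta >= np.pi - 1e-9)[0]]
        raise ValueError(f"projection singular at the antipode for: {', '.join(bad)}")
    phi = np.arctan2(pos[:, 1], pos[:, 0])
    pts = np.stack([theta * np.cos(phi), theta * np.sin(phi)], axis=1)
    return ProjectedMontage(labels=labels, points=pts)


def _grid_nodes(extent: tuple[float, float, float, float], grid_size: int) -> tuple[np.ndarray, np.ndarray]:
    xmin, xmax, ymin, ymax = extent
    xs = np.linspace(xmin, xmax, grid_size)
    ys = np.linspace(ymax, ymin, grid_size)  # row 0 = front (+y)
    return np.meshgrid(xs, ys)


def interpolate_band_map(points: ProjectedMontage, values: np.ndarray, *,
                         grid_size: int = GRID_SIZE, fill_value: float = 0.0,
                         extent: tuple[float, float, float, float] | None = None) -> np.ndarray:
    """Clough-Tocher interpolation of per-channel values onto a regular grid.

    Returns a [grid_size x grid_size] array; nodes outside the convex hull of
    the projected electrodes take ``fill_value``.
    """
    values = np.asarray(values, dtype=np.float64)
    if len(values) != len(points.labels):
        raise ValueError("one value per projected channel required")
    if len(values) < 3:
        raise ValueError("Clough-Tocher interpolation needs at least 3 points")
    try:
        interp = CloughTocher2DInterpolator(points.points, values, fill_value=fill_value)
    except QhullError as exc:
        raise ValueError(f"electrode triangulation failed (collinear points?): {exc}") from exc
    gx, gy = _grid_nodes(extent or points.extent, grid_size)
    return interp(gx, gy)


def window_to_tensor(window: np.ndarray, fs: float,
                     scheme: BandScheme = BandScheme(),
                     montage: Montage | None = None, *,
                     channel_names: list[str] | None = None,
                     fill_value: float = 0.0,
                     projected: ProjectedMontage | None = None) -> HeadMapTensor:
    """Full window -> head-map pipeline: FFT, band centroids, projection, interpolation.

    ``channel_names`` gives the label of each window row; rows are matched to
    montage labels by name, so permuting channels (with their labels) leaves
    the tensor unchanged.  Passing a precomputed ``projected`` montage skips
    the projection step when converting many windows.
    """
    if projected is None:
        if montage is None:
            raise ValueError("either montage or projected must be given")
        projected = project_azimuthal_equidistant(montage)
    labels = list(projected.labels)
    window = np.atleast_2d(np.asarray(window, dtype=np.float64))
    if channel_names is not None:
        missing = [lb for lb in labels if lb not in channel_names]
        extra = [lb for lb in channel_names if lb not in labels]
        if missing or extra:
            raise ValueError(
                f"channel/montage mismatch; missing from window: {missing}, "
                f"not in montage: {extra}"
            )
        order = [channel_names.index(lb) for lb in labels]
        window = window[order]
    elif window.shape[0] != len(labels):
        raise ValueError(
            f"window has {window.shape[0]} channels but montage has {len(labels)}"
        )
    cent = band_power_matrix(window, fs, scheme).centroids  # [n_ch x 5]
    extent = projected.extent
    slices = [
        interpolate_band_map(projected, cent[:, b], fill_value=fill_value, extent=extent)
        for b in range(cent.shape[1])
    ]
    return HeadMapTensor(
        grid=np.stack(slices, axis=-1),
        extent=extent,
        fill_value=fill_value,
        band_names=tuple(scheme.names),
    )


def render_tensor(tensor: HeadMapTensor, path: str) -> None:
    """Save a side-by-side PNG of the five band maps (inspection aid)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(tensor.band_names), figsize=(3 * len(tensor.band_names), 3))
    for ax, b, name in zip(np.atleast_1d(axes), range(tensor.grid.shape[-1]), tensor.band_names):
        im = ax.imshow(tensor.grid[:, :, b], extent=tensor.extent, cmap="viridis")
        ax.set_title(name)
        ax.set_xticks([]), ax.set_yticks([])
        fig.colorbar(im, ax=ax, shrink=0.75)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
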