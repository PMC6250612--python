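"""Core containers shared across the pipeline.

Coordinate convention (fixed so that centroids round-trip through rendered
images): continuous coordinates are in micrometers, origin at the top-left
pixel corner, x increasing rightward (columns), y increasing downward (rows).
Pixel (i, j) covers the square [j*p, (j+1)*p) x [i*p, (i+1)*p) and its center
sits at ((j + 0.5)*p, (i + 0.5)*p), with p the pixel size in um/pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

UM2_PER_MM2 = 1e6


@dataclass
class ChannelImage:
    """A single 2D fluorescence channel with physical pixel size.

    Parameters
    ----------
    data : ndarray, shape (H, W)
        Pixel intensities (photon counts or denoised estimates thereof).
    channel : str
        Channel label, e.g. ``"DAPI"``, ``"Pax5"``, ``"CD3"``.
    pixel_size : float
        Edge length of one pixel in micrometers.
    """

    data: np.ndarray
    channel: str
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("ChannelImage.data must be 2D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class RegionMask:
    """Binary pixel mask naming a tissue compartment (GC, LZ, DZ or FL).

    The mask doubles as the observation window for point patterns; its area
    is the foreground pixel count times ``pixel_size**2``.
    """

    mask: np.ndarray
    pixel_size: float
    label: str = "GC"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("RegionMask.mask must be 2D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self._setcov_cache: Optional[np.ndarray] = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size**2

    @property
    def area_mm2(self) -> float:
        return self.area_um2 / UM2_PER_MM2

    @property
    def width_um(self) -> float:
        return self.mask.shape[1] * self.pixel_size

    @property
    def height_um(self) -> float:
        return self.mask.shape[0] * self.pixel_size

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership per point.

        A point belongs to the window iff the pixel containing it is set;
        a point exactly on a pixel boundary belongs to the pixel whose index
        is floor(coord / pixel_size) (half-open pixel convention).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.size == 0:
            return np.zeros(0, dtype=bool)
        j = np.floor(pts[:, 0] / self.pixel_size).astype(int)
        i = np.floor(pts[:, 1] / self.pixel_size).astype(int)
        ok = (i >= 0) & (i < self.mask.shape[0]) & (j >= 0) & (j < self.mask.shape[1])
        out = np.zeros(len(pts), dtype=bool)
        out[ok] = self.mask[i[ok], j[ok]]
        return out

    def bbox_um(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) bounding box of foreground pixels in um."""
        rows = np.any(self.mask, axis=1)
        cols = np.any(self.mask, axis=0)
        if not rows.any():
            raise ValueError("empty mask has no bounding box")
        i0, i1 = np.flatnonzero(rows)[[0, -1]]
        j0, j1 = np.flatnonzero(cols)[[0, -1]]
        p = self.pixel_size
        return (j0 * p, i0 * p, (j1 + 1) * p, (i1 + 1) * p)


@dataclass
class PointPattern:
    """Cell centroids (um) observed inside a window, tagged with a cell type."""

    points: np.ndarray
    window: RegionMask
    cell_type: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must have shape (n, 2)")
        self.points = pts

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def intensity_hat(self) -> float:
        """Estimated intensity in points per mm^2."""
        area = self.window.area_mm2
        if area <= 0:
            raise ValueError("window has zero area")
        return self.n / area

    @property
    def intensity_hat_um2(self) -> float:
        """Estimated intensity in points per um^2 (for bandwidth rules)."""
        return self.n / self.window.area_um2


@dataclass
class SpatialCurve:
    """Second-order summary curve(s) on a radius grid.

    ``k`` holds Ripley's K(r) in um^2, ``g`` the pair correlation g(r);
    either may be absent. ``lo``/``med``/``hi`` are envelope curves, present
    for pooled or simulated-CSR sources. ``unreliable`` flags radii where the
    kernel estimate is known to be biased (r below the bandwidth).
    """

    r: np.ndarray
    k: Optional[np.ndarray] = None
    g: Optional[np.ndarray] = None
    lo: Optional[np.ndarray] = None
    med: Optional[np.ndarray] = None
    hi: Optional[np.ndarray] = None
    source: str = "single"
    unreliable: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 1:
            raise ValueError("r grid must be 1D")
        if len(self.r) > 1 and not np.all(np.diff(self.r) > 0):
            raise ValueError("r grid must be strictly increasing")
        if self.r.size and self.r[0] < 0:
            raise ValueError("r must be non-negative")


@dataclass
class CellDetection:
    """One segmented cell: centroid (um), area (um^2), type and marker score."""

    centroid: tuple[float, float]
    area: float
    cell_type: str
    marker_score: float = float("nan")


@dataclass
class GroundTruth:
    """Planted points plus the process that generated them (synthetic data)."""

    points: np.ndarray
    cell_type: str
    process: object  # ProcessSpec; kept loose to avoid circular import
    window: RegionMask

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        self.points = pts
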