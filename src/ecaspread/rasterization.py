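"""Point-set → binary presence-image rasterization.

A cluster's occurrences are binned onto a 20×20 grid spanning the cluster's
bounding box; a cell is 1 if at least one occurrence falls in it, regardless
of how many (observation density is deliberately discarded — the data are
presence-only).  Cells outside the point set are 0: the model assumes the
species has never been found outside the cluster.

Grid convention: row 0 is the northernmost latitude band and column 0 the
westernmost longitude band, so the array reads like a map.  Cell intervals
are half-open ``[edge_i, edge_{i+1})`` with the last interval closed, so
points on the maximum coordinate are binned.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GridSpec",
    "PresenceImage",
    "ImageSequence",
    "bounding_box",
    "rasterize",
    "sequence_to_images",
    "write_image",
    "read_image",
]

#: padding applied to a zero-width bbox axis, in degrees
DEGENERATE_PAD = 1e-6


@dataclass(frozen=True)
class GridSpec:
    """A rectangular lon/lat grid of nx × ny equal cells."""

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    nx: int = 20
    ny: int = 20

    def __post_init__(self) -> None:
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError(
                "bbox must be well-ordered: "
                f"({self.lon_min}, {self.lon_max}, {self.lat_min}, {self.lat_max})"
            )
        if self.nx < 1 or self.ny < 1:
            raise ValueError(f"grid must have >= 1 cell per axis, got {self.nx}x{self.ny}")

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        return (self.lon_min, self.lon_max, self.lat_min, self.lat_max)


@dataclass
class PresenceImage:
    """A binary ny × nx grid; 1 marks a cell with at least one occurrence."""

    grid: np.ndarray
    gridspec: GridSpec = field(
        default_factory=lambda: GridSpec(0.0, 1.0, 0.0, 1.0)
    )

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=np.uint8)
        if g.shape != (self.gridspec.ny, self.gridspec.nx):
            raise ValueError(
                f"grid shape {g.shape} does not match gridspec "
                f"{self.gridspec.ny}x{self.gridspec.nx}"
            )
        if not np.isin(g, (0, 1)).all():
            raise ValueError("grid values must be 0 or 1")
        self.grid = g

    @property
    def presence_count(self) -> int:
        return int(self.grid.sum())

    def __eq__(self, other: object) -> bool:
        if isinstance(other, PresenceImage):
            return (
                self.gridspec == other.gridspec
                and np.array_equal(self.grid, other.grid)
            )
        return NotImplemented


@dataclass
class ImageSequence:
    """An ordered series of presence images on one shared grid."""

    images: list[PresenceImage]

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("an image sequence must contain at least one image")
        spec = self.images[0].gridspec
        for img in self.images[1:]:
            if img.gridspec != spec:
                raise ValueError("all images in a sequence must share one gridspec")

    @property
    def gridspec(self) -> GridSpec:
        return self.images[0].gridspec

    def __len__(self) -> int:
        return len(self.images)

    def __getitem__(self, i):
        return self.images[i]

    def __iter__(self):
        return iter(self.images)


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"points must be an (n, 2) array of (lon, lat), got {pts.shape}")
    if pts.shape[0] == 0:
        raise ValueError("at least one point is required")
    if not np.isfinite(pts).all():
        raise ValueError("points contain non-finite coordinates")
    return pts


def bounding_box(points, nx: int = 20, ny: int = 20) -> GridSpec:
    """Tight min/max bbox of the points, padded on any zero-width axis.

    All points coincident (or collinear along an axis) would give a
    zero-area box; the degenerate axis is padded by ±1e-6° so the grid is
    always well-formed.
    """
    pts = _as_points(points)
    lon_min, lat_min = pts.min(axis=0)
    lon_max, lat_max = pts.max(axis=0)
    if lon_min == lon_max:
        lon_min -= DEGENERATE_PAD
        lon_max += DEGENERATE_PAD
    if lat_min == lat_max:
        lat_min -= DEGENERATE_PAD
        lat_max += DEGENERATE_PAD
    return GridSpec(lon_min, lon_max, lat_min, lat_max, nx=nx, ny=ny)


def _cell_indices(pts: np.ndarray, gs: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    lon, lat = pts[:, 0], pts[:, 1]
    inside = (
        (lon >= gs.lon_min)
        & (lon <= gs.lon_max)
        & (lat >= gs.lat_min)
        & (lat <= gs.lat_max)
    )
    if not inside.all():
        bad = pts[~inside][0]
        raise ValueError(
            f"point (lon={bad[0]}, lat={bad[1]}) lies outside the grid bbox {gs.bbox}"
        )
    dx = (gs.lon_max - gs.lon_min) / gs.nx
    dy = (gs.lat_max - gs.lat_min) / gs.ny
    col = np.minimum(((lon - gs.lon_min) / dx).astype(int), gs.nx - 1)
    band = np.minimum(((lat - gs.lat_min) / dy).astype(int), gs.ny - 1)
    row = gs.ny - 1 - band  # row 0 = northernmost band
    return row, col


def rasterize(points, gridspec: GridSpec) -> PresenceImage:
    """Bin points into the grid: cell = 1 iff >= 1 point falls in it."""
    pts = _as_points(points)
    row, col = _cell_indices(pts, gridspec)
    grid = np.zeros((gridspec.ny, gridspec.nx), dtype=np.uint8)
    grid[row, col] = 1
    return PresenceImage(grid=grid, gridspec=gridspec)


def sequence_to_images(seq, gridspec: GridSpec) -> ImageSequence:
    """Rasterize each subset of an inclusion sequence on one fixed grid.

    The grid comes from the FULL cluster, so every frame shares the final
    image's bbox and the 1s can only accumulate along the sequence.
    ``seq`` may be an InclusionSequence or any iterable of (n, 2) point
    arrays.
    """
    subsets = seq.point_subsets() if hasattr(seq, "point_subsets") else seq
    images = [rasterize(pts, gridspec) for pts in subsets]
    return ImageSequence(images=images)


def write_image(image: PresenceImage, path: str | Path) -> None:
    """Write a presence image as ny lines of nx 0/1 digits plus a JSON
    sidecar (``<path>.json``) holding the gridspec."""
    path = Path(path)
    lines = "\n".join(" ".join(str(v) for v in row) for row in image.grid)
    path.write_text(lines + "\n")
    gs = image.gridspec
    sidecar = {
        "lon_min": gs.lon_min,
        "lon_max": gs.lon_max,
        "lat_min": gs.lat_min,
        "lat_max": gs.lat_max,
        "nx": gs.nx,
        "ny": gs.ny,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_image(path: str | Path) -> PresenceImage:
    """Round-trip reader for :func:`write_image`."""
    path = Path(path)
    grid = np.array(
        [[int(v) for v in line.split()] for line in path.read_text().splitlines() if line],
        dtype=np.uint8,
    )
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        gridspec = GridSpec(**meta)
    else:
        warnings.warn(f"no gridspec sidecar at {sidecar_path}; using unit bbox")
        gridspec = GridSpec(0.0, 1.0, 0.0, 1.0, nx=grid.shape[1], ny=grid.shape[0])
    return PresenceImage(grid=grid, gridspec=gridspec)
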