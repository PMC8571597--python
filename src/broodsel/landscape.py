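"""Raster covariate engineering for third-order resource selection.

A study landscape is a single complete class raster (burned upland, nonburned
upland, hardwood drain, fallow field).  From it we derive the continuous
covariate surfaces the selection model consumes:

* binary indicator layers per landcover class,
* circular focal-proportion surfaces (share of a class within a metric
  radius of each cell — the default 105 m radius corresponds to a 3.46-ha
  neighbourhood),
* distance-to-feedline surfaces (minimum Euclidean distance from each cell
  centre to any supplemental-feed transect segment).

Conventions: planar metres, y increasing northward.  Cell arrays are stored
with row 0 at the *north* edge; ``origin_x/origin_y`` is the lower-left
corner of the grid.  Focal kernels use inclusive centre-to-centre distance
and truncate to in-bounds cells at the study boundary, so proportions stay
unbiased at edges and the per-class surfaces of one landscape always sum
to 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

#: Canonical landcover classes and their integer raster codes.
CLASS_CODES = {
    "burned_upland": 1,
    "nonburned_upland": 2,
    "drain": 3,
    "field": 4,
}
CODE_CLASSES = {v: k for k, v in CLASS_CODES.items()}

NODATA = -9999


@dataclass
class LandcoverGrid:
    """Complete rectangular class raster in planar metres.

    ``cells`` holds integer class codes (see :data:`CLASS_CODES`), shape
    ``(n_rows, n_cols)``, row 0 at the north edge.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells)
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.cells.ndim != 2:
            raise ValueError("cells must be a 2-D array")
        known = set(CODE_CLASSES)
        present = set(np.unique(self.cells).tolist())
        if not present <= known:
            raise ValueError(f"unknown class codes in grid: {sorted(present - known)}")

    @property
    def n_rows(self) -> int:
        return self.cells.shape[0]

    @property
    def n_cols(self) -> int:
        return self.cells.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def class_proportions(self) -> dict[str, float]:
        total = self.cells.size
        return {
            name: float(np.count_nonzero(self.cells == code)) / total
            for name, code in CLASS_CODES.items()
        }


@dataclass
class Surface:
    """A continuous raster sharing a :class:`LandcoverGrid`'s geometry."""

    origin_x: float
    origin_y: float
    cell_size: float
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )


# A ProportionSurface is a Surface with values in [0, 1] and meta["radius_m"];
# a DistanceSurface is a Surface with values >= 0.  Both keep the plain
# Surface container: what differs is provenance, carried in ``meta``.
ProportionSurface = Surface
DistanceSurface = Surface


@dataclass
class FeedlineSet:
    """Supplemental-feed transects as planar segments ((x1,y1),(x2,y2))."""

    segments: np.ndarray  # shape (n, 4): x1, y1, x2, y2

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float).reshape(-1, 4)
        if not np.all(np.isfinite(self.segments)):
            raise ValueError("feedline endpoints must be finite")
        lengths = np.hypot(
            self.segments[:, 2] - self.segments[:, 0],
            self.segments[:, 3] - self.segments[:, 1],
        )
        if self.segments.shape[0] and np.any(lengths == 0):
            raise ValueError("feedline segments must have nonzero length")

    def total_length(self) -> float:
        return float(
            np.hypot(
                self.segments[:, 2] - self.segments[:, 0],
                self.segments[:, 3] - self.segments[:, 1],
            ).sum()
        )


def binarize_landcover(grid: LandcoverGrid, target_class: str) -> Surface:
    """Indicator layer: 1 where the cell's class equals ``target_class``."""
    if target_class not in CLASS_CODES:
        raise ValueError(
            f"unknown landcover class {target_class!r}; known: {sorted(CLASS_CODES)}"
        )
    code = CLASS_CODES[target_class]
    return Surface(
        grid.origin_x,
        grid.origin_y,
        grid.cell_size,
        (grid.cells == code).astype(float),
        meta={"class": target_class},
    )


def circular_kernel(radius_m: float, cell_size: float) -> np.ndarray:
    """Binary kernel of cells whose centre lies within ``radius_m`` (inclusive)."""
    if radius_m < 0:
        raise ValueError("radius must be >= 0")
    r_cells = int(np.floor(radius_m / cell_size))
    offs = np.arange(-r_cells, r_cells + 1)
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    dist = np.hypot(dx, dy) * cell_size
    return (dist <= radius_m).astype(float)


def focal_proportion(binary: Surface, radius_m: float) -> ProportionSurface:
    """Share of 1-cells within a circular neighbourhood of each cell.

    The kernel is truncated to in-bounds cells at the grid edge, i.e. each
    output value is the mean of the binary layer over the in-bounds cells
    whose centre-to-centre distance is <= ``radius_m``.
    """
    if radius_m < 0:
        raise ValueError("radius must be >= 0")
    vals = np.asarray(binary.values, dtype=float)
    kernel = circular_kernel(radius_m, binary.cell_size)
    if kernel.size == 1:
        out = vals.copy()
    else:
        num = ndimage.convolve(vals, kernel, mode="constant", cval=0.0)
        den = ndimage.convolve(np.ones_like(vals), kernel, mode="constant", cval=0.0)
        out = num / den
    return Surface(
        binary.origin_x,
        binary.origin_y,
        binary.cell_size,
        out,
        meta={**binary.meta, "radius_m": radius_m},
    )


def _cell_centers(surface: Surface) -> tuple[np.ndarray, np.ndarray]:
    """x (per column) and y (per row, row 0 north) centre coordinates."""
    xs = surface.origin_x + (np.arange(surface.n_cols) + 0.5) * surface.cell_size
    ys = (
        surface.origin_y
        + (surface.n_rows - np.arange(surface.n_rows) - 0.5) * surface.cell_size
    )
    return xs, ys


def point_segment_distance(
    px: np.ndarray, py: np.ndarray, segments: np.ndarray
) -> np.ndarray:
    """Min Euclidean distance from each point to any segment (vectorized)."""
    px = np.atleast_1d(np.asarray(px, dtype=float))
    py = np.atleast_1d(np.asarray(py, dtype=float))
    x1, y1, x2, y2 = (segments[:, i] for i in range(4))
    dx, dy = x2 - x1, y2 - y1
    seg_len2 = dx * dx + dy * dy
    # projection parameter of each point on each segment, clipped to [0, 1]
    t = ((px[:, None] - x1) * dx + (py[:, None] - y1) * dy) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    cx = x1 + t * dx
    cy = y1 + t * dy
    d = np.hypot(px[:, None] - cx, py[:, None] - cy)
    return d.min(axis=1)


def distance_to_feed(template: Surface | LandcoverGrid, feedlines: FeedlineSet) -> DistanceSurface:
    """Distance from every cell centre to the nearest feedline segment."""
    if feedlines.segments.shape[0] == 0:
        raise ValueError("FeedlineSet is empty: at least one segment required")
    if isinstance(template, LandcoverGrid):
        template = Surface(
            template.origin_x,
            template.origin_y,
            template.cell_size,
            np.zeros_like(template.cells, dtype=float),
        )
    xs, ys = _cell_centers(template)
    out = np.empty((template.n_rows, template.n_cols))
    # Chunk rows to bound the (points x segments) intermediate.
    for r0 in range(0, template.n_rows, 64):
        r1 = min(r0 + 64, template.n_rows)
        yy = np.repeat(ys[r0:r1], template.n_cols)
        xx = np.tile(xs, r1 - r0)
        out[r0:r1] = point_segment_distance(xx, yy, feedlines.segments).reshape(
            r1 - r0, template.n_cols
        )
    return Surface(
        template.origin_x,
        template.origin_y,
        template.cell_size,
        out,
        meta={"covariate": "feed_distance_m"},
    )


def point_to_rowcol(
    surface: Surface | LandcoverGrid, x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row/col of the cell containing each point (edges assign to the
    cell on the lower-left side, i.e. floor indexing)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    col = np.floor((x - surface.origin_x) / surface.cell_size).astype(int)
    row_from_bottom = np.floor((y - surface.origin_y) / surface.cell_size).astype(int)
    row = surface.n_rows - 1 - row_from_bottom
    return row, col


def extract_at_points(surface: Surface, x, y) -> np.ndarray:
    """Value of the cell containing each point; rejects out-of-bounds points."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    xmin, ymin, xmax, ymax = surface.bounds
    bad = (x < xmin) | (x >= xmax) | (y < ymin) | (y >= ymax)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValueError(
            f"point ({x[i]:.3f}, {y[i]:.3f}) lies outside grid bounds {surface.bounds}"
        )
    row, col = point_to_rowcol(surface, x, y)
    return surface.values[row, col]


# ---------------------------------------------------------------------------
# ESRI ASCII grid + feedline text I/O


def write_ascii_grid(path: str | Path, surface: Surface | LandcoverGrid) -> None:
    """Write as ESRI ASCII grid (.asc), NODATA_value -9999.

    For a :class:`LandcoverGrid` a sidecar ``<path>.legend.json`` documents
    the integer class codes.
    """
    path = Path(path)
    if isinstance(surface, LandcoverGrid):
        values = surface.cells
        fmt = "%d"
        legend = path.with_suffix(path.suffix + ".legend.json")
        legend.write_text(json.dumps(CLASS_CODES, indent=1) + "\n")
    else:
        values = surface.values
        fmt = "%.8g"
    header = (
        f"ncols {surface.n_cols}\n"
        f"nrows {surface.n_rows}\n"
        f"xllcorner {surface.origin_x:.6f}\n"
        f"yllcorner {surface.origin_y:.6f}\n"
        f"cellsize {surface.cell_size:.6f}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values, fmt=fmt)


def read_ascii_grid(path: str | Path, as_landcover: bool = False):
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = values.reshape(int(header["nrows"]), int(header["ncols"]))
    args = (header["xllcorner"], header["yllcorner"], header["cellsize"])
    if as_landcover:
        return LandcoverGrid(*args, values.astype(int))
    return Surface(*args, values)


def write_feedlines(path: str | Path, feedlines: FeedlineSet) -> None:
    """One segment per line: x1,y1,x2,y2 in metres."""
    np.savetxt(
        path,
        feedlines.segments,
        fmt="%.6f",
        delimiter=",",
        header="x1,y1,x2,y2",
        comments="",
    )


def read_feedlines(path: str | Path) -> FeedlineSet:
    segs = np.loadtxt(path, delimiter=",", skiprows=1)
    return FeedlineSet(segs)
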