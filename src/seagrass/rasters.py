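"""Grid geometry and the raster container types shared by every pipeline stage.

All rasters live on a simple affine grid (north-up, square pixels).  A pixel
``(row, col)`` covers the half-open square
``[x_origin + col*p, x_origin + (col+1)*p) x (y_origin - (row+1)*p, y_origin - row*p]``
with ``p`` the pixel size in metres; point-to-pixel lookups use the pixel that
contains the point, so coordinates exactly on a shared edge belong to the
pixel on the right / below (half-open convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "Grid",
    "GridMismatchError",
    "ReflectanceScene",
    "DepthRaster",
    "HabitatMap",
    "CLASS_TABLE",
    "NODATA_LABEL",
    "STAGE_SURFACE",
    "STAGE_RRS",
    "STAGE_BOTTOM",
    "require_same_grid",
    "sample_at_points",
]

#: Reflectance processing stages.
STAGE_SURFACE = "surface_R"
STAGE_RRS = "Rrs"
STAGE_BOTTOM = "bottom_Rb"
_STAGES = (STAGE_SURFACE, STAGE_RRS, STAGE_BOTTOM)

#: Benthic class code table used throughout (0 is reserved for nodata).
CLASS_TABLE = {
    1: "Cymodocea nodosa",
    2: "Posidonia oceanica",
    3: "Rocky algae",
    4: "Sand",
}
NODATA_LABEL = 0


class GridMismatchError(ValueError):
    """Raised when two rasters that must share a grid do not."""


@dataclass(frozen=True)
class Grid:
    """Affine raster grid: shape, pixel size (m) and top-left origin.

    ``y_origin`` is the *top* edge; rows increase southward.  If omitted it
    defaults to ``rows * pixel_size`` so that the bottom-left corner sits at
    ``(x_origin, 0)``.
    """

    rows: int
    cols: int
    pixel_size: float = 5.0
    x_origin: float = 0.0
    y_origin: float | None = None

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.y_origin is None:
            object.__setattr__(self, "y_origin", self.rows * self.pixel_size)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def pixel_area_ha(self) -> float:
        """Area of one pixel in hectares."""
        return self.pixel_size**2 / 10_000.0

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return full ``(X, Y)`` arrays of pixel-centre coordinates."""
        xs = self.x_origin + (np.arange(self.cols) + 0.5) * self.pixel_size
        ys = self.y_origin - (np.arange(self.rows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.x_origin + (col + 0.5) * self.pixel_size,
            self.y_origin - (row + 0.5) * self.pixel_size,
        )

    def rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col) indices (may be out of range).

        Half-open pixel boundaries: a point on the left/top edge of a pixel
        belongs to that pixel.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_origin) / self.pixel_size).astype(int)
        row = np.floor((self.y_origin - y) / self.pixel_size).astype(int)
        return row, col

    def contains(self, row, col) -> np.ndarray:
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.rows) & (col >= 0) & (col < self.cols)


def require_same_grid(*objs) -> Grid:
    """Assert all raster objects share one grid; return it."""
    grids = [o.grid for o in objs]
    first = grids[0]
    for g in grids[1:]:
        if g != first:
            raise GridMismatchError(f"grids differ: {first} vs {g}")
    return first


def _as_mask(mask, shape) -> np.ndarray:
    if mask is None:
        return np.zeros(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} != raster shape {shape}")
    return mask


@dataclass
class ReflectanceScene:
    """Multiband unitless reflectance raster with a processing-stage tag.

    ``values`` has shape ``(n_bands, rows, cols)``; ``mask`` is True where a
    pixel carries no data (mask applies to all bands jointly).
    """

    values: np.ndarray
    bands: tuple[float, ...]
    grid: Grid
    mask: np.ndarray | None = None
    stage: str = STAGE_SURFACE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_bands, rows, cols)")
        self.bands = tuple(float(b) for b in self.bands)
        if self.values.shape[0] != len(self.bands):
            raise ValueError("number of bands does not match values")
        if self.values.shape[1:] != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {_STAGES}")
        self.mask = _as_mask(self.mask, self.grid.shape)
        if not np.isfinite(self.values[:, ~self.mask]).all():
            raise ValueError("non-finite reflectance at unmasked pixels")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def band_index(self, wavelength: float) -> int:
        for i, b in enumerate(self.bands):
            if abs(b - wavelength) < 0.5:
                return i
        raise KeyError(f"band {wavelength} nm not in scene bands {self.bands}")

    def band(self, wavelength: float) -> np.ndarray:
        return self.values[self.band_index(wavelength)]

    def with_values(self, values: np.ndarray, stage: str, mask=None) -> "ReflectanceScene":
        """New scene on the same grid/bands; mask defaults to a copy of ours."""
        return ReflectanceScene(
            values=values,
            bands=self.bands,
            grid=self.grid,
            mask=self.mask.copy() if mask is None else mask,
            stage=stage,
        )


@dataclass
class DepthRaster:
    """Per-pixel water depth in metres, positive downward."""

    values: np.ndarray
    grid: Grid
    mask: np.ndarray | None = None
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("depth shape does not match grid")
        self.mask = _as_mask(self.mask, self.grid.shape)
        if not np.isfinite(self.values[~self.mask]).all():
            raise ValueError("non-finite depth at unmasked pixels")


@dataclass
class HabitatMap:
    """Categorical per-pixel benthic label raster; 0 codes nodata."""

    labels: np.ndarray
    grid: Grid
    class_table: dict[int, str] = field(default_factory=lambda: dict(CLASS_TABLE))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.uint8)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid")
        valid = set(self.class_table) | {NODATA_LABEL}
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise ValueError(f"labels {sorted(present - valid)} not in class table")

    @property
    def mask(self) -> np.ndarray:
        return self.labels == NODATA_LABEL

    def class_counts(self) -> dict[int, int]:
        return {
            c: int(np.count_nonzero(self.labels == c)) for c in sorted(self.class_table)
        }


def sample_at_points(values: np.ndarray, grid: Grid, x, y, mask: np.ndarray | None = None):
    """Nearest-pixel lookup of a 2-D field at point coordinates.

    Returns ``(sampled, usable)`` where ``usable`` is False for points that
    fall off-grid or on masked pixels; ``sampled`` is NaN there.
    """
    row, col = grid.rowcol(np.atleast_1d(x), np.atleast_1d(y))
    usable = grid.contains(row, col)
    if mask is not None:
        idx = np.flatnonzero(usable)
        bad = mask[row[idx], col[idx]]
        usable[idx[bad]] = False
    out = np.full(usable.shape, np.nan)
    out[usable] = values[row[usable], col[usable]]
    return out, usable
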