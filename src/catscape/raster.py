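"""Gridded utilization surfaces: grid geometry, text raster I/O, resampling.

Rasters follow map convention: row 0 is the northernmost row, column 0 the
westernmost; cell (r, c) covers the square
``[x_min + c*cell, x_min + (c+1)*cell) x (y_max - (r+1)*cell, y_max - r*cell]``.
Cell values are probability mass per cell (not density), so an individual
utilization distribution sums to 1 over the grid.

On-disk format is the ESRI ASCII grid (plain text), which round-trips the
grid geometry and values exactly enough for reproducible pipelines without
binary dependencies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular square-celled raster grid."""

    x_min: float
    y_min: float
    cell_size: float
    n_cols: int
    n_rows: int
    crs_tag: str = "local-meters"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.cell_size

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def x_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        """Cell-center northings ordered north to south (row order)."""
        return self.y_max - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_rows, n_cols) arrays of cell-center x and y."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def covers(self, x: np.ndarray, y: np.ndarray) -> bool:
        return bool(
            np.all(x >= self.x_min)
            and np.all(x <= self.x_max)
            and np.all(y >= self.y_min)
            and np.all(y <= self.y_max)
        )

    @classmethod
    def from_extent(
        cls,
        x_min: float,
        y_min: float,
        x_max: float,
        y_max: float,
        cell_size: float,
        crs_tag: str = "local-meters",
    ) -> "GridSpec":
        """Smallest grid with the given cell size covering the extent."""
        n_cols = max(1, int(np.ceil((x_max - x_min) / cell_size - 1e-9)))
        n_rows = max(1, int(np.ceil((y_max - y_min) / cell_size - 1e-9)))
        return cls(x_min, y_min, cell_size, n_cols, n_rows, crs_tag)


@dataclass
class UdRaster:
    """A gridded utilization distribution (mass per cell)."""

    grid: GridSpec
    values: np.ndarray
    cat_id: str = "unknown"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError(
                f"values shape {v.shape} does not match grid "
                f"({self.grid.n_rows}, {self.grid.n_cols})"
            )
        if np.any(v < 0):
            raise ValueError("UD cell values must be nonnegative")
        self.values = v

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def normalized(self) -> "UdRaster":
        s = self.total
        if s <= 0:
            raise ValueError("cannot normalize an all-zero raster")
        return UdRaster(self.grid, self.values / s, self.cat_id)

    def copy(self) -> "UdRaster":
        return UdRaster(self.grid, self.values.copy(), self.cat_id)

    def plot(self, ax=None, transform=np.sqrt, **imshow_kwargs):
        """Quick-look map of the surface (square-root stretched by default)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        g = self.grid
        vals = transform(self.values) if transform is not None else self.values
        im = ax.imshow(
            vals,
            extent=(g.x_min, g.x_max, g.y_min, g.y_max),
            origin="upper",
            **imshow_kwargs,
        )
        ax.set_xlabel("x (m)")
        ax.set_ylabel("y (m)")
        ax.set_title(self.cat_id)
        return im


# ---------------------------------------------------------------------------
# Volume-contour cell selection
# ---------------------------------------------------------------------------


def contour_mask(values: np.ndarray, level: float) -> np.ndarray:
    """Cells of the minimal set whose cumulative mass reaches ``level``.

    Cells are ranked by value (descending); the smallest prefix whose sum
    is >= ``level`` is selected, with value ties at the cut included in
    full.  ``values`` must be a normalized mass array (sum 1).
    """
    if not 0.0 < level <= 1.0:
        raise ValueError("contour level must lie in (0, 1]")
    flat = values.ravel()
    order = np.sort(flat)[::-1]
    csum = np.cumsum(order)
    k = int(np.searchsorted(csum, min(level, csum[-1]) - 1e-12))
    threshold = order[min(k, len(order) - 1)]
    return (values >= threshold) & (values > 0)


# ---------------------------------------------------------------------------
# Conservative (area-weighted) resampling
# ---------------------------------------------------------------------------


def _axis_overlap(
    src_lo: np.ndarray, src_hi: np.ndarray, dst_lo: np.ndarray, dst_hi: np.ndarray
) -> np.ndarray:
    """(n_dst, n_src) matrix of interval-overlap lengths."""
    return np.clip(
        np.minimum.outer(dst_hi, src_hi) - np.maximum.outer(dst_lo, src_lo), 0.0, None
    )


def resample_mass(raster: UdRaster, template: GridSpec) -> UdRaster:
    """Re-grid a mass raster onto ``template`` by area-weighted overlap.

    Each source cell's mass is distributed over the template cells it
    overlaps, in proportion to overlap area; total mass is conserved as
    long as the template covers the source extent.  When the grids already
    coincide the values are returned bitwise-identical.
    """
    src = raster.grid
    if (
        src.x_min == template.x_min
        and src.y_min == template.y_min
        and src.cell_size == template.cell_size
        and src.n_cols == template.n_cols
        and src.n_rows == template.n_rows
    ):
        return UdRaster(replace(template), raster.values.copy(), raster.cat_id)

    if (
        src.x_max <= template.x_min
        or template.x_max <= src.x_min
        or src.y_max <= template.y_min
        or template.y_max <= src.y_min
    ):
        raise ValueError("source raster extent is disjoint from the template grid")

    sx_lo = src.x_min + np.arange(src.n_cols) * src.cell_size
    dx_lo = template.x_min + np.arange(template.n_cols) * template.cell_size
    fx = _axis_overlap(sx_lo, sx_lo + src.cell_size, dx_lo, dx_lo + template.cell_size)

    # rows run north->south: row r spans [y_max - (r+1)*cell, y_max - r*cell]
    sy_hi = src.y_max - np.arange(src.n_rows) * src.cell_size
    dy_hi = template.y_max - np.arange(template.n_rows) * template.cell_size
    fy = _axis_overlap(sy_hi - src.cell_size, sy_hi, dy_hi - template.cell_size, dy_hi)

    frac = 1.0 / src.cell_area
    out = fy @ (raster.values * frac) @ fx.T
    return UdRaster(replace(template), out, raster.cat_id)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------


def write_ascii_grid(raster: UdRaster, path) -> None:
    g = raster.grid
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {float(g.x_min)!r}\n")
        fh.write(f"yllcorner {float(g.y_min)!r}\n")
        fh.write(f"cellsize {float(g.cell_size)!r}\n")
        fh.write("NODATA_value -9999\n")
        np.savetxt(fh, raster.values, fmt="%.17e")


def read_ascii_grid(path, cat_id: str = "unknown", crs_tag: str = "local-meters") -> UdRaster:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    grid = GridSpec(
        x_min=header["xllcorner"],
        y_min=header["yllcorner"],
        cell_size=header["cellsize"],
        n_cols=int(header["ncols"]),
        n_rows=int(header["nrows"]),
        crs_tag=crs_tag,
    )
    return UdRaster(grid, values, cat_id)
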