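"""Regular metric grids and single-band rasters.

All spatial analyses in this package run on a planar metric grid.  Cells are
half-open squares ``[x0 + i*cell, x0 + (i+1)*cell) x [y0 + j*cell, ...)`` so
every point belongs to exactly one cell; a point sitting on a shared edge is
assigned to the cell on its east/north side.  Raster values are stored with
row 0 as the southernmost row (``values[iy, ix]``); the ESRI ASCII-grid
reader/writer flips rows so files follow the format's north-to-south order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "Raster", "read_ascii_grid", "write_ascii_grid", "resample_to"]

NODATA_DEFAULT = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular square-celled grid.

    Parameters
    ----------
    x0, y0 : float
        Projected coordinates (metres) of the grid's lower-left corner.
    cell : float
        Cell edge length in metres.
    nx, ny : int
        Number of columns / rows.
    """

    x0: float
    y0: float
    cell: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("grid must have at least one cell")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (self.x0, self.y0, self.x0 + self.nx * self.cell, self.y0 + self.ny * self.cell)

    def cell_index(self, x, y):
        """Map points to (ix, iy) column/row indices (half-open convention).

        Points outside the grid get indices outside ``[0, nx) x [0, ny)``;
        use :meth:`contains` to screen them.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ix = np.floor((x - self.x0) / self.cell).astype(int)
        iy = np.floor((y - self.y0) / self.cell).astype(int)
        return ix, iy

    def contains(self, x, y):
        ix, iy = self.cell_index(x, y)
        return (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids of cell-centre coordinates, shape (ny, nx)."""
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.cell
        ys = self.y0 + (np.arange(self.ny) + 0.5) * self.cell
        return np.meshgrid(xs, ys)

    def cell_polygon(self, ix: int, iy: int):
        from shapely.geometry import box

        return box(
            self.x0 + ix * self.cell,
            self.y0 + iy * self.cell,
            self.x0 + (ix + 1) * self.cell,
            self.y0 + (iy + 1) * self.cell,
        )

    def shifted(self, dx: float, dy: float) -> "GridSpec":
        return GridSpec(self.x0 + dx, self.y0 + dy, self.cell, self.nx, self.ny)


@dataclass
class Raster:
    """A single-band raster: values on a :class:`GridSpec`.

    ``values[iy, ix]`` with row 0 the southernmost row.  ``nodata`` marks
    missing cells (compared with exact equality for integer rasters, NaN is
    also treated as missing for float rasters).
    """

    values: np.ndarray
    grid: GridSpec
    nodata: float = NODATA_DEFAULT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"raster shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    def mask_valid(self) -> np.ndarray:
        v = self.values
        valid = v != self.nodata
        if np.issubdtype(v.dtype, np.floating):
            valid &= np.isfinite(v)
        return valid

    def sample(self, x, y, outside="raise"):
        """Nearest-cell extraction at point coordinates.

        Returns (values, valid_mask); ``valid_mask`` is False for points in
        nodata cells.  ``outside`` is 'raise' or 'nan' for points off-grid.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        inside = self.grid.contains(x, y)
        if outside == "raise" and not inside.all():
            n_bad = int((~inside).sum())
            raise ValueError(f"{n_bad} point(s) outside raster extent {self.grid.extent}")
        ix, iy = self.grid.cell_index(x, y)
        out = np.full(x.shape, np.nan)
        valid = np.zeros(x.shape, dtype=bool)
        ok = inside
        out[ok] = self.values[iy[ok], ix[ok]].astype(float)
        vm = self.mask_valid()
        valid[ok] = vm[iy[ok], ix[ok]]
        out[~valid] = np.nan
        return out, valid


def write_ascii_grid(raster: Raster, path) -> None:
    """Write an ESRI ASCII grid (.asc), rows north to south."""
    g = raster.grid
    header = (
        f"ncols {g.nx}\n"
        f"nrows {g.ny}\n"
        f"xllcorner {g.x0!r}\n"
        f"yllcorner {g.y0!r}\n"
        f"cellsize {g.cell!r}\n"
        f"NODATA_value {raster.nodata!r}\n"
    )
    vals = np.where(raster.mask_valid(), raster.values, raster.nodata)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals[::-1], fmt="%.8g")


def read_ascii_grid(path) -> Raster:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, val = line.split()
            meta[key.lower()] = float(val)
            pos = fh.tell()
        fh.seek(pos)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)[::-1]
    grid = GridSpec(
        x0=meta["xllcorner"],
        y0=meta["yllcorner"],
        cell=meta["cellsize"],
        nx=int(meta["ncols"]),
        ny=int(meta["nrows"]),
    )
    return Raster(vals, grid, nodata=meta.get("nodata_value", NODATA_DEFAULT))


def resample_to(raster: Raster, coarse_cell: float, categorical: bool = False) -> Raster:
    """Aggregate to a coarser grid whose cell is an integer multiple of the fine cell.

    Continuous rasters aggregate by the mean of valid fine cells; categorical
    rasters by majority vote (ties broken by the smallest class code).  Coarse
    cells with no valid fine cell become nodata.
    """
    g = raster.grid
    factor = coarse_cell / g.cell
    k = int(round(factor))
    if abs(factor - k) > 1e-9 or k < 1:
        raise ValueError("coarse cell must be an integer multiple of the fine cell")
    ny, nx = g.ny // k, g.nx // k
    if nx == 0 or ny == 0:
        raise ValueError("coarse cell larger than raster extent")
    v = raster.values[: ny * k, : nx * k]
    valid = raster.mask_valid()[: ny * k, : nx * k]
    blocks = v.reshape(ny, k, nx, k).swapaxes(1, 2).reshape(ny, nx, k * k)
    bvalid = valid.reshape(ny, k, nx, k).swapaxes(1, 2).reshape(ny, nx, k * k)
    out = np.full((ny, nx), NODATA_DEFAULT)
    any_valid = bvalid.any(axis=2)
    if categorical:
        codes = np.unique(v[valid]) if valid.any() else np.array([])
        counts = np.zeros((ny, nx, len(codes)), dtype=int)
        for i, c in enumerate(codes):
            counts[:, :, i] = ((blocks == c) & bvalid).sum(axis=2)
        if len(codes):
            # argmax takes the first (= smallest code) on ties
            win = codes[np.argmax(counts, axis=2)]
            out[any_valid] = win[any_valid]
    else:
        s = np.where(bvalid, blocks, 0.0).sum(axis=2)
        n = bvalid.sum(axis=2)
        out[any_valid] = s[any_valid] / n[any_valid]
    grid = GridSpec(g.x0, g.y0, coarse_cell, nx, ny)
    return Raster(out, grid, nodata=NODATA_DEFAULT)
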