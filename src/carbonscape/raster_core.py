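"""Land-use raster data model and bookkeeping.

Categorical land-use maps are held as integer-coded matrices with an
upper-left origin and square cells in an equal-area projection, so areas
follow from cell counts alone.  Seven classes are used throughout:

    1 farmland, 2 forests, 3 grassland, 4 wetland, 5 waters,
    6 construction land, 7 unused land.

I/O covers ESRI ASCII grids (plain text, integer round-trip exact) and
single-band GeoTIFF via :mod:`tifffile` with ModelPixelScale /
ModelTiepoint geo tags.  Nodata cells (basin boundary) are frozen
everywhere: never transitioned, never counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

#: default legend for the seven-class scheme
DEFAULT_LEGEND: dict[int, str] = {
    1: "farmland",
    2: "forests",
    3: "grassland",
    4: "wetland",
    5: "waters",
    6: "construction",
    7: "unused",
}

CLASS_CODES: tuple[int, ...] = tuple(DEFAULT_LEGEND)


@dataclass
class LandUseGrid:
    """Integer-coded categorical raster.

    Parameters
    ----------
    codes
        2-D integer array; non-nodata values must appear in ``legend``.
    cell_size
        Square cell edge length in metres (> 0).
    origin
        (x, y) map coordinates of the upper-left corner.
    nodata_code
        Integer marking cells outside the mapped region.
    legend
        Mapping code -> class name.
    """

    codes: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_code: int = -9999
    legend: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2 or min(self.codes.shape) < 1:
            raise ValueError("codes must be a 2-D matrix of at least 1x1")
        if not np.issubdtype(self.codes.dtype, np.integer):
            if not np.all(np.mod(self.codes[~np.isnan(self.codes)], 1) == 0):
                raise ValueError("land-use codes must be integer-valued")
            self.codes = np.where(np.isnan(self.codes), self.nodata_code, self.codes)
            self.codes = self.codes.astype(np.int32)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        valid = self.codes != self.nodata_code
        bad = valid & ~np.isin(self.codes, list(self.legend))
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} cells carry values outside the legend "
                f"{sorted(self.legend)}"
            )

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def cell_area_ha(self) -> float:
        """Area of one cell in hectares: (cell_size/100)**2."""
        return (self.cell_size / 100.0) ** 2

    @property
    def valid_mask(self) -> np.ndarray:
        return self.codes != self.nodata_code

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of every cell center."""
        rows, cols = np.indices(self.shape)
        x = self.origin[0] + (cols + 0.5) * self.cell_size
        y = self.origin[1] - (rows + 0.5) * self.cell_size
        return x, y

    def copy_with(self, codes: np.ndarray) -> "LandUseGrid":
        return LandUseGrid(
            codes=np.asarray(codes, dtype=self.codes.dtype),
            cell_size=self.cell_size,
            origin=self.origin,
            nodata_code=self.nodata_code,
            legend=dict(self.legend),
        )

    def class_counts(self) -> dict[int, int]:
        """Cell count per legend code (nodata excluded)."""
        valid = self.codes[self.valid_mask]
        return {c: int(np.sum(valid == c)) for c in sorted(self.legend)}


@dataclass
class DriverStack:
    """Co-registered covariate layers for development-probability models."""

    layers: dict[str, np.ndarray]
    categorical: dict[str, bool] = field(default_factory=dict)
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("driver stack needs at least one layer")
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) != 1:
            raise ValueError(f"driver layers disagree in shape: {shapes}")
        for name, arr in self.layers.items():
            if np.all(~np.isfinite(arr)):
                raise ValueError(f"driver layer {name!r} is entirely nodata")
            self.categorical.setdefault(name, False)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def as_feature_matrix(self) -> np.ndarray:
        """Stack layers to an (n_cells, n_layers) design matrix (C order)."""
        return np.column_stack([self.layers[n].ravel() for n in self.names])


# ---------------------------------------------------------------------------
# tables


def _class_name(code: int, legend: Mapping[int, str]) -> str:
    return legend.get(code, str(code))


@dataclass
class AreaTable:
    """Per-class areas (ha and km²) per date/scenario label."""

    table: pd.DataFrame  # index: class code, columns: labels, values: ha

    @classmethod
    def from_dict(cls, areas_ha: Mapping[int, float], label: str = "area") -> "AreaTable":
        s = pd.Series(dict(areas_ha), name=label).sort_index()
        if (s < 0).any():
            raise ValueError("areas must be non-negative")
        return cls(table=s.to_frame())

    def ha(self, label: str | None = None) -> pd.Series:
        col = label if label is not None else self.table.columns[0]
        return self.table[col]

    def km2(self, label: str | None = None) -> pd.Series:
        return self.ha(label) / 100.0

    def total_ha(self, label: str | None = None) -> float:
        return float(self.ha(label).sum())

    def to_frame(self, legend: Mapping[int, str] = DEFAULT_LEGEND) -> pd.DataFrame:
        out = self.table.copy()
        out.index = [_class_name(c, legend) for c in out.index]
        return out

    def write(self, path: str | Path, legend: Mapping[int, str] = DEFAULT_LEGEND) -> None:
        df = self.table.copy()
        df.insert(0, "class_name", [_class_name(c, legend) for c in df.index])
        df.index.name = "class_code"
        df.to_csv(path)


@dataclass
class TransitionCrosstab:
    """Class-to-class transition areas in hectares.

    ``matrix[i, j]`` is the area of cells coded ``codes[i]`` at the first
    date and ``codes[j]`` at the second; the diagonal is persistence.
    """

    matrix: np.ndarray  # (K, K) areas in ha
    codes: tuple[int, ...] = CLASS_CODES

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.codes)
        if self.matrix.shape != (k, k):
            raise ValueError(f"crosstab must be {k}x{k}")
        if (self.matrix < 0).any():
            raise ValueError("crosstab entries must be non-negative")

    def row_areas(self) -> pd.Series:
        return pd.Series(self.matrix.sum(axis=1), index=list(self.codes))

    def col_areas(self) -> pd.Series:
        return pd.Series(self.matrix.sum(axis=0), index=list(self.codes))

    def total(self) -> float:
        return float(self.matrix.sum())

    def to_frame(self, legend: Mapping[int, str] = DEFAULT_LEGEND) -> pd.DataFrame:
        names = [_class_name(c, legend) for c in self.codes]
        return pd.DataFrame(self.matrix, index=names, columns=names)


# ---------------------------------------------------------------------------
# I/O


def _read_ascii_grid(path: Path) -> tuple[np.ndarray, float, tuple[float, float], float]:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                "yllcenter", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    data = np.asarray(data, dtype=float).reshape(nrows, ncols)
    cell = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    else:  # cell-center registration
        xll = header["xllcenter"] - cell / 2
        yll = header["yllcenter"] - cell / 2
    origin = (xll, yll + nrows * cell)  # upper-left corner
    return data, cell, origin, nodata


def _write_ascii_grid(
    path: Path, data: np.ndarray, cell_size: float, origin: tuple[float, float], nodata: float
) -> None:
    nrows, ncols = data.shape
    yll = origin[1] - nrows * cell_size
    fmt = "%d" if np.issubdtype(data.dtype, np.integer) else "%.8g"
    with open(path, "w") as fh:
        fh.write(
            f"ncols {ncols}\nnrows {nrows}\n"
            f"xllcorner {origin[0]:.6f}\nyllcorner {yll:.6f}\n"
            f"cellsize {cell_size:.6f}\nNODATA_value {nodata:g}\n"
        )
        np.savetxt(fh, data, fmt=fmt)


_TIFF_PIXELSCALE = 33550
_TIFF_TIEPOINT = 33922


def _read_geotiff(path: Path) -> tuple[np.ndarray, float, tuple[float, float], float | None]:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        cell = 1.0
        origin = (0.0, 0.0)
        tags = page.tags
        if _TIFF_PIXELSCALE in tags:
            sx, sy = tags[_TIFF_PIXELSCALE].value[:2]
            cell = float(sx)
        if _TIFF_TIEPOINT in tags:
            tp = tags[_TIFF_TIEPOINT].value
            origin = (float(tp[3]), float(tp[4]))
        nodata = None
        if "GDAL_NODATA" in tags:
            nodata = float(tags["GDAL_NODATA"].value)
    return np.asarray(data), cell, origin, nodata


def _write_geotiff(
    path: Path, data: np.ndarray, cell_size: float, origin: tuple[float, float], nodata: float
) -> None:
    import tifffile

    extratags = [
        (_TIFF_PIXELSCALE, "d", 3, (cell_size, cell_size, 0.0)),
        (_TIFF_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, origin[0], origin[1], 0.0)),
        (42113, "s", 0, str(nodata)),  # GDAL_NODATA
    ]
    tifffile.imwrite(str(path), data, extratags=extratags)


def read_landuse(
    path: str | Path,
    legend: Mapping[int, str] = DEFAULT_LEGEND,
    nodata_code: int = -9999,
) -> LandUseGrid:
    """Read a land-use map from an ESRI ASCII grid or single-band GeoTIFF.

    Values outside the legend are mapped to nodata; the count is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        data, cell, origin, file_nodata = _read_geotiff(path)
    else:
        data, cell, origin, file_nodata = _read_ascii_grid(path)
    if not np.all(np.mod(data[np.isfinite(data)], 1) == 0):
        raise ValueError(f"{path}: band 1 is not integer-valued")
    codes = np.where(np.isfinite(data), data, nodata_code).astype(np.int32)
    if file_nodata is not None:
        codes[codes == int(file_nodata)] = nodata_code
    out_of_legend = (codes != nodata_code) & ~np.isin(codes, list(legend))
    if out_of_legend.any():
        logger.warning(
            "%s: %d cells outside legend %s mapped to nodata",
            path, int(out_of_legend.sum()), sorted(legend),
        )
        codes[out_of_legend] = nodata_code
    if not (codes != nodata_code).any():
        raise ValueError(f"{path}: raster is entirely nodata")
    return LandUseGrid(codes, cell, origin, nodata_code, dict(legend))


def write_landuse(grid: LandUseGrid, path: str | Path) -> None:
    """Write a land-use map (format chosen by extension: .asc/.txt or .tif)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        _write_geotiff(path, grid.codes.astype(np.int32), grid.cell_size, grid.origin,
                       grid.nodata_code)
    else:
        _write_ascii_grid(path, grid.codes, grid.cell_size, grid.origin, grid.nodata_code)


def write_mask(mask: np.ndarray, grid: LandUseGrid, path: str | Path) -> None:
    """Save a boolean mask as a 0/1 raster aligned with ``grid``."""
    write_landuse(
        LandUseGrid(mask.astype(np.int32), grid.cell_size, grid.origin,
                    nodata_code=-9999, legend={0: "outside", 1: "inside"}),
        path,
    )


# ---------------------------------------------------------------------------
# bookkeeping operations


def class_areas(grid: LandUseGrid, label: str = "area") -> AreaTable:
    """Per-class area: cell count x cell area (ha); nodata excluded."""
    counts = grid.class_counts()
    return AreaTable.from_dict({c: n * grid.cell_area_ha for c, n in counts.items()}, label)


def _check_aligned(a: LandUseGrid, b: LandUseGrid) -> None:
    if a.shape != b.shape:
        raise ValueError(f"grid shapes differ: {a.shape} vs {b.shape}")
    if a.cell_size != b.cell_size:
        raise ValueError("grid cell sizes differ")


def crosstab(
    grid_a: LandUseGrid, grid_b: LandUseGrid, intersect_nodata: bool = True
) -> TransitionCrosstab:
    """Cross-tabulate transition areas between two aligned maps.

    Nodata masks that disagree are intersected with a warning when
    ``intersect_nodata`` is true, otherwise an error is raised.
    """
    _check_aligned(grid_a, grid_b)
    valid = grid_a.valid_mask & grid_b.valid_mask
    if not np.array_equal(grid_a.valid_mask, grid_b.valid_mask):
        if not intersect_nodata:
            raise ValueError("nodata masks differ between grids")
        logger.warning("nodata masks differ; intersecting them for the crosstab")
    codes = CLASS_CODES
    k = len(codes)
    idx = {c: i for i, c in enumerate(codes)}
    a = grid_a.codes[valid]
    b = grid_b.codes[valid]
    ai = np.vectorize(idx.get)(a) if a.size else np.empty(0, int)
    bi = np.vectorize(idx.get)(b) if b.size else np.empty(0, int)
    counts = np.bincount(ai * k + bi, minlength=k * k).reshape(k, k)
    return TransitionCrosstab(counts * grid_a.cell_area_ha, codes)


def buffer_mask(grid: LandUseGrid, target_class: int, radius: float) -> np.ndarray:
    """Cells whose center lies within ``radius`` metres of a target-class cell.

    Distances are Euclidean, cell-center to cell-center; a radius of zero
    returns exactly the target-class cells.  An absent target class yields
    an all-false mask with a warning.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    target = grid.codes == target_class
    if not target.any():
        logger.warning("class %s absent; buffer mask is empty", target_class)
        return np.zeros(grid.shape, dtype=bool)
    dist = ndimage.distance_transform_edt(~target, sampling=grid.cell_size)
    return dist <= radius + 1e-9


def block_aggregate(
    values: np.ndarray,
    cell_size: float,
    block: float,
    how: str = "sum",
    valid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate a fine matrix onto a coarse block grid.

    Each coarse cell takes the sum or mean of the fine cells whose centers
    fall inside the block; edge blocks may be partial.  Returns the coarse
    matrix and an array of block bounds ``(row0, row1, col0, col1)`` in
    fine-cell indices.

    Parameters
    ----------
    values : fine-resolution matrix
    cell_size : fine cell edge (m)
    block : block edge (m), must be >= cell_size
    how : 'sum' or 'mean'
    valid : optional boolean matrix; False cells are excluded
    """
    if block < cell_size:
        raise ValueError("block must be at least one cell")
    if how not in {"sum", "mean"}:
        raise ValueError("how must be 'sum' or 'mean'")
    nrows, ncols = values.shape
    # a fine cell belongs to the block containing its center
    step = block / cell_size
    row_block = ((np.arange(nrows) + 0.5) // step).astype(int)
    col_block = ((np.arange(ncols) + 0.5) // step).astype(int)
    nbr, nbc = row_block[-1] + 1, col_block[-1] + 1
    vals = np.asarray(values, dtype=float)
    ok = np.isfinite(vals)
    if valid is not None:
        ok &= valid
    flat_idx = (row_block[:, None] * nbc + col_block[None, :]).ravel()
    w = ok.ravel().astype(float)
    sums = np.bincount(flat_idx, weights=np.where(ok, vals, 0.0).ravel(),
                       minlength=nbr * nbc)
    counts = np.bincount(flat_idx, weights=w, minlength=nbr * nbc)
    if how == "mean":
        with np.errstate(invalid="ignore", divide="ignore"):
            coarse = np.where(counts > 0, sums / counts, np.nan)
    else:
        coarse = np.where(counts > 0, sums, np.nan)
    coarse = coarse.reshape(nbr, nbc)
    bounds = np.empty((nbr, nbc, 4), dtype=int)
    for br in range(nbr):
        rows = np.flatnonzero(row_block == br)
        for bc in range(nbc):
            cols = np.flatnonzero(col_block == bc)
            bounds[br, bc] = (rows[0], rows[-1] + 1, cols[0], cols[-1] + 1)
    return coarse, bounds


def block_class_areas(
    grid: LandUseGrid, block: float
) -> dict[int, np.ndarray]:
    """Per-block area (ha) of every class, on the block_aggregate layout."""
    out: dict[int, np.ndarray] = {}
    for code in grid.legend:
        indicator = (grid.codes == code).astype(float) * grid.cell_area_ha
        coarse, _ = block_aggregate(indicator, grid.cell_size, block, how="sum")
        out[code] = np.nan_to_num(coarse)
    return out
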