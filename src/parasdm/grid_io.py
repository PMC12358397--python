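"""Raster grid container and ESRI ASCII grid I/O.

All analyses in this package run on a single co-registered geographic grid
(corner-registered, square cells, row 0 = northernmost row).  The ESRI ASCII
grid (``.asc``) is the canonical interchange format; cell areas are computed
on a sphere so class areas can be reported in km².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GridLayer",
    "GridParseError",
    "CoregistrationError",
    "read_ascii_grid",
    "write_ascii_grid",
    "assert_coregistered",
    "cell_area_layer",
    "AUTHALIC_RADIUS_KM",
]

#: Authalic (equal-area) Earth radius in kilometres.
AUTHALIC_RADIUS_KM = 6371.0072

#: Header tolerance for co-registration checks, in degrees.
COREG_TOL = 1e-9

VALID_KINDS = ("continuous", "binary", "class4", "categorical")


class GridParseError(ValueError):
    """Raised when an ASCII grid file violates the format."""


class CoregistrationError(ValueError):
    """Raised when layers that must share a grid do not."""


@dataclass
class GridLayer:
    """A single raster layer on a geographic (longitude/latitude) grid.

    Parameters
    ----------
    nrows, ncols
        Grid shape; ``values[0]`` is the **northernmost** row.
    xll, yll
        Longitude / latitude of the lower-left *corner*, in degrees.
    cellsize
        Cell edge length in degrees (square cells).
    nodata_value
        Sentinel written to file for missing cells.  In memory, missing
        cells are NaN in ``values``.
    values
        ``(nrows, ncols)`` float array; NaN marks nodata.
    kind
        One of ``continuous``, ``binary``, ``class4``, ``categorical``.
    """

    nrows: int
    ncols: int
    xll: float
    yll: float
    cellsize: float
    values: np.ndarray
    nodata_value: float = -9999.0
    kind: str = "continuous"
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.nrows, self.ncols):
            raise ValueError(
                f"values shape {self.values.shape} != ({self.nrows}, {self.ncols})"
            )
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")
        if not (-180.0 <= self.xll and self.xll + self.ncols * self.cellsize <= 360.0 + 1e-9):
            raise ValueError("grid longitude extent outside [-180, 360]")
        if not (-90.0 - 1e-9 <= self.yll and self.yll + self.nrows * self.cellsize <= 90.0 + 1e-9):
            raise ValueError("grid latitude extent outside [-90, 90]")
        finite = self.values[np.isfinite(self.values)]
        if self.kind == "binary" and finite.size and not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("binary layer has values outside {0, 1}")
        if self.kind == "class4" and finite.size and not np.isin(finite, (0.0, 1.0, 2.0, 3.0)).all():
            raise ValueError("class4 layer has values outside {0, 1, 2, 3}")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells that carry data."""
        return np.isfinite(self.values)

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell ``(i, j)`` (i = row from north)."""
        lon = self.xll + (j + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - i - 0.5) * self.cellsize
        return lon, lat

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (lons of shape ncols, lats of shape nrows)."""
        lons = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        lats = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        return lons, lats

    def cell_index(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Row/col of the cell containing a point, or None outside the grid.

        Half-open convention: a point on a shared vertical edge belongs to
        the cell to its east ([west, east)); on a horizontal edge, to the
        cell below it ((south, north]).  The grid's outer west and south
        edges are inclusive so every point in the bounding box maps to
        exactly one cell.
        """
        x = (lon - self.xll) / self.cellsize
        y = (lat - self.yll) / self.cellsize
        if not (0.0 <= x < self.ncols) or not (0.0 < y <= self.nrows):
            # allow the south edge itself
            if not (0.0 <= x < self.ncols and y == 0.0):
                return None
        j = int(math.floor(x))
        # (south, north]: points on a horizontal edge go to the cell below
        i_from_south = int(math.ceil(y)) - 1
        i_from_south = min(max(i_from_south, 0), self.nrows - 1)
        i = self.nrows - 1 - i_from_south
        return i, j

    def copy_with(self, values: np.ndarray, kind: str | None = None,
                  name: str | None = None) -> "GridLayer":
        """New layer on the same grid with different values."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            kind=kind if kind is not None else self.kind,
            name=name if name is not None else self.name,
        )


# -- ASCII grid I/O ----------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path, kind: str = "continuous", name: str = "") -> GridLayer:
    """Read an ESRI ASCII grid file.

    The header must provide ncols, nrows, xllcorner, yllcorner and cellsize
    (NODATA_value optional, default -9999); data rows follow north to south.
    Malformed files raise :class:`GridParseError` naming the line number.
    """
    header: dict[str, float] = {}
    nodata = -9999.0
    data_rows: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.readlines()

    lineno = 0
    n_header = 0
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        parts = stripped.split()
        key = parts[0].lower()
        if key in _HEADER_KEYS or key == "nodata_value":
            if len(parts) != 2:
                raise GridParseError(f"{path}: line {lineno}: malformed header line {stripped!r}")
            try:
                val = float(parts[1])
            except ValueError as exc:
                raise GridParseError(
                    f"{path}: line {lineno}: non-numeric header value {parts[1]!r}"
                ) from exc
            if key == "nodata_value":
                nodata = val
            else:
                header[key] = val
            n_header += 1
            continue
        # first data line
        break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise GridParseError(f"{path}: missing header keys: {', '.join(missing)}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    if ncols != header["ncols"] or nrows != header["nrows"] or ncols < 1 or nrows < 1:
        raise GridParseError(f"{path}: ncols/nrows must be positive integers")

    data_lines = [(ln, s) for ln, s in enumerate(lines, start=1)
                  if s.strip() and ln > n_header]
    # values may wrap across lines; accumulate tokens but report errors by line
    tokens: list[float] = []
    for ln, s in data_lines:
        for tok in s.split():
            try:
                tokens.append(float(tok))
            except ValueError as exc:
                raise GridParseError(f"{path}: line {ln}: non-numeric cell value {tok!r}") from exc
        if len(tokens) % ncols != 0 and len(data_lines) == nrows:
            raise GridParseError(
                f"{path}: line {ln}: row has {len(tokens) % ncols} values, expected {ncols}"
            )
    if len(tokens) != nrows * ncols:
        raise GridParseError(
            f"{path}: expected {nrows * ncols} data values, found {len(tokens)}"
        )
    arr = np.array(tokens, dtype=float).reshape(nrows, ncols)
    arr[arr == nodata] = np.nan
    return GridLayer(
        nrows=nrows,
        ncols=ncols,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata_value=nodata,
        values=arr,
        kind=kind,
        name=name,
    )


def write_ascii_grid(layer: GridLayer, path) -> None:
    """Write a layer as an ESRI ASCII grid; round-trips via read_ascii_grid."""
    vals = layer.values.copy()
    vals[~np.isfinite(vals)] = layer.nodata_value
    with open(path, "w") as fh:
        fh.write(f"ncols {layer.ncols}\n")
        fh.write(f"nrows {layer.nrows}\n")
        fh.write(f"xllcorner {layer.xll:.12g}\n")
        fh.write(f"yllcorner {layer.yll:.12g}\n")
        fh.write(f"cellsize {layer.cellsize:.12g}\n")
        fh.write(f"NODATA_value {layer.nodata_value:.12g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")


def assert_coregistered(layers: list[GridLayer]) -> None:
    """Check that all layers share one grid; raise naming the mismatch."""
    if not layers:
        raise ValueError("need at least one layer")
    ref = layers[0]
    for idx, lyr in enumerate(layers[1:], start=1):
        for fld in ("nrows", "ncols"):
            if getattr(lyr, fld) != getattr(ref, fld):
                raise CoregistrationError(
                    f"layer {idx}: {fld}={getattr(lyr, fld)} != {getattr(ref, fld)}"
                )
        for fld in ("xll", "yll", "cellsize"):
            if abs(getattr(lyr, fld) - getattr(ref, fld)) > COREG_TOL:
                raise CoregistrationError(
                    f"layer {idx}: {fld}={getattr(lyr, fld)!r} != {getattr(ref, fld)!r}"
                )


def cell_area_layer(template: GridLayer, radius_km: float = AUTHALIC_RADIUS_KM) -> GridLayer:
    """Spherical area in km² of each cell of ``template``.

    A cell spanning latitudes [φ_b, φ_t] and Δλ of longitude has area
    R²·Δλ_rad·(sin φ_t − sin φ_b); it depends only on the row.
    """
    lat_top = template.yll + (template.nrows - np.arange(template.nrows)) * template.cellsize
    lat_bot = lat_top - template.cellsize
    if lat_top.max() > 90.0 + 1e-9 or lat_bot.min() < -90.0 - 1e-9:
        raise ValueError("cells extend beyond the poles")
    dlam = math.radians(template.cellsize)
    band = radius_km ** 2 * dlam * (np.sin(np.radians(lat_top)) - np.sin(np.radians(lat_bot)))
    vals = np.repeat(band[:, None], template.ncols, axis=1)
    return template.copy_with(vals, kind="continuous", name="cell_area_km2")
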