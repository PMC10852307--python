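"""Categorical rasters, PLEL reclassification, area accounting, transitions.

The production–living–ecological land (PLEL) scheme collapses a national
land-use classification into eight functional classes:

====  ====  ==========  =========================================
code  name  tier        source land-use types
====  ====  ==========  =========================================
1     APL   production  paddy field, dry land
2     IPL   production  industrial and mining construction land
3     ULL   living      urban residential land
4     RLL   living      rural residential land
5     FEL   ecological  woodland, shrub land, sparse/other woodland
6     GEL   ecological  high/medium/low coverage grassland
7     WEL   ecological  canals, lakes, reservoirs, glaciers, flats
8     OEL   ecological  sandy land, Gobi, saline-alkali, bare land
====  ====  ==========  =========================================

All areas are reported in hectares (hm²): ``cells × cell_size² / 10_000``.
Rasters are row-major with the origin at the top-left corner, addressed
``(row, col)`` 0-based; on-disk interchange uses the ESRI ASCII grid format,
which is plain text and round-trips exactly for integer class codes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: PLEL class codes in canonical order.
PLEL_CODES = (1, 2, 3, 4, 5, 6, 7, 8)
PLEL_NAMES = ("APL", "IPL", "ULL", "RLL", "FEL", "GEL", "WEL", "OEL")
CODE_TO_NAME = dict(zip(PLEL_CODES, PLEL_NAMES))
NAME_TO_CODE = dict(zip(PLEL_NAMES, PLEL_CODES))

#: First-level tier of each class: production / living / ecological.
TIERS = {
    "APL": "production",
    "IPL": "production",
    "ULL": "living",
    "RLL": "living",
    "FEL": "ecological",
    "GEL": "ecological",
    "WEL": "ecological",
    "OEL": "ecological",
}
TIER_CODES = {
    "production": (1, 2),
    "living": (3, 4),
    "ecological": (5, 6, 7, 8),
}

#: Chinese national secondary land-use codes → PLEL class code.  Paddy/dry land
#: (11, 12) → APL; woodland family (21–24) → FEL; grassland (31–33) → GEL;
#: water bodies (41–46) → WEL; urban 51 → ULL; rural 52 → RLL; other
#: construction 53 → IPL; unused land (61–67) → OEL.
DEFAULT_LANDUSE_MAPPING = {
    11: 1, 12: 1,
    53: 2,
    51: 3,
    52: 4,
    21: 5, 22: 5, 23: 5, 24: 5,
    31: 6, 32: 6, 33: 6,
    41: 7, 42: 7, 43: 7, 44: 7, 45: 7, 46: 7,
    61: 8, 62: 8, 63: 8, 64: 8, 65: 8, 66: 8, 67: 8,
}


@dataclass
class CategoricalRaster:
    """A grid of integer class codes with a validity mask and geometry.

    Parameters
    ----------
    values
        2-D integer array of class codes, row-major, top-left origin.
    mask
        2-D boolean array, ``True`` where the cell is valid (inside the
        study area).  Values under ``False`` are ignored everywhere.
    cell_size
        Cell edge in meters (square cells).
    origin
        ``(x, y)`` map coordinates of the top-left corner.
    epoch_label
        Free-text label, e.g. a year.
    """

    values: np.ndarray
    mask: np.ndarray | None = None
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    epoch_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_hm2(self) -> float:
        """Area of a single cell in hm²."""
        return self.cell_size**2 / 10_000.0

    def same_grid(self, other: "CategoricalRaster") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin == other.origin
        )

    def copy(self, **changes) -> "CategoricalRaster":
        out = replace(self, **changes)
        if "values" not in changes:
            out.values = self.values.copy()
        if "mask" not in changes:
            out.mask = self.mask.copy()
        return out


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_ascii_grid(raster: CategoricalRaster, path: str | Path, nodata: int = -9999) -> None:
    """Write a raster as an ESRI ASCII grid (.asc)."""
    nrows, ncols = raster.shape
    x0, y0 = raster.origin
    vals = np.where(raster.mask, raster.values, nodata)
    buf = io.StringIO()
    buf.write(f"ncols {ncols}\n")
    buf.write(f"nrows {nrows}\n")
    buf.write(f"xllcorner {x0!r}\n")
    # yllcorner is the *bottom*-left corner; origin stores the top-left.
    buf.write(f"yllcorner {y0 - nrows * raster.cell_size!r}\n")
    buf.write(f"cellsize {raster.cell_size!r}\n")
    buf.write(f"NODATA_value {nodata}\n")
    np.savetxt(buf, vals, fmt="%d")
    Path(path).write_text(buf.getvalue())


def read_ascii_grid(path: str | Path, epoch_label: str = "") -> CategoricalRaster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid` (or any
    conforming .asc file with integer values)."""
    text = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(text):
        parts = text[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    vals = np.loadtxt(io.StringIO("\n".join(text[i:])))
    vals = np.atleast_2d(vals)
    nodata = int(header.get("nodata_value", -9999))
    cell = float(header["cellsize"])
    nrows = int(header["nrows"])
    origin = (float(header["xllcorner"]), float(header["yllcorner"]) + nrows * cell)
    ivals = vals.astype(int)
    return CategoricalRaster(
        values=ivals,
        mask=ivals != nodata,
        cell_size=cell,
        origin=origin,
        epoch_label=epoch_label,
    )


# ---------------------------------------------------------------------------
# Reclassification and accounting


def reclassify(lu: CategoricalRaster, mapping: dict[int, int] | None = None) -> CategoricalRaster:
    """Map land-use codes to PLEL classes.

    Every code present under the mask must have a mapping entry; an
    unmapped code raises ``KeyError`` naming the offending code.
    """
    if mapping is None:
        mapping = DEFAULT_LANDUSE_MAPPING
    present = np.unique(lu.values[lu.mask])
    missing = [int(c) for c in present if int(c) not in mapping]
    if missing:
        raise KeyError(f"no PLEL mapping for land-use code(s) {missing}")
    out = np.zeros_like(lu.values)
    for code in present:
        out[lu.values == code] = mapping[int(code)]
    return lu.copy(values=np.where(lu.mask, out, lu.values))


def tabulate_areas(r: CategoricalRaster, codes: tuple[int, ...] = PLEL_CODES) -> pd.Series:
    """Per-class area in hm², indexed by class name, zero for absent classes.

    A fully masked raster yields an all-zero table.
    """
    valid = r.values[r.mask]
    counts = np.array([(valid == c).sum() for c in codes], dtype=float)
    areas = counts * r.cell_area_hm2
    return pd.Series(areas, index=[CODE_TO_NAME.get(c, str(c)) for c in codes], name="area_hm2")


def cross_tabulate(
    r1: CategoricalRaster, r2: CategoricalRaster, codes: tuple[int, ...] = PLEL_CODES
) -> pd.DataFrame:
    """Epoch-to-epoch transition matrix in hm² (rows = from, cols = to).

    Cells masked in either epoch are excluded, so row sums equal the
    epoch-1 area table and column sums the epoch-2 table on the shared mask.
    """
    if not r1.same_grid(r2):
        raise ValueError("rasters are not on the same grid")
    both = r1.mask & r2.mask
    a = r1.values[both]
    b = r2.values[both]
    k = len(codes)
    code_arr = np.asarray(codes)
    order = np.argsort(code_arr)
    ai = order[np.searchsorted(code_arr[order], a)]
    bi = order[np.searchsorted(code_arr[order], b)]
    joint = np.bincount(ai * k + bi, minlength=k * k).reshape(k, k).astype(float)
    names = [CODE_TO_NAME.get(c, str(c)) for c in codes]
    return pd.DataFrame(joint * r1.cell_area_hm2, index=names, columns=names)


def area_table_to_csv(areas: pd.Series, path: str | Path) -> None:
    areas.rename_axis("class").to_csv(path, header=["area_hm2"])


def transition_to_csv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.rename_axis("from_class").to_csv(path)
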