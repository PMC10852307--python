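"""Grid-based landscape ecological risk: metrics, vulnerability, ERI.

The study area is tiled into square evaluation units (3 km edge by
default).  Within each unit k and for each landscape class i present:

    fragmentation  C_ki = n_ki / A_ki
    separation     S_ki = (A_k / (2 A_ki)) * sqrt(n_ki / A_k)
    disturbance    E_ki = a*C_ki + b*S_ki + c*D_i      (a,b,c = 0.5,0.3,0.2)
    loss           R_ki = E_ki * F_i

where n_ki is the patch count of class i clipped to the unit, A_ki its
area, A_k the unit's valid area (all areas in hm²), D_i the dominance of
class i, and F_i its vulnerability weight.  The unit's landscape ecological
risk index is the area-weighted sum

    ERI_k = Σ_i (A_ki / A_k) * R_ki

and U1/U2/U3 are the same sum restricted to the production, living and
ecological tiers, so ERI_k = U1 + U2 + U3 identically.

Dominance combines presence, patch share and area share:

    D_i = (Q_i + M_i)/4 + L_i/2

with Q_i the fraction of units containing class i, M_i its share of all
patches, and L_i its share of total area.  By default D is computed once
per epoch over the whole landscape ("global" scope); a per-unit variant is
available.

Vulnerability weights are normalized ranks (rank / Σ ranks, rounded to two
decimals).  The canonical ranking orders the eight classes from least to
most sensitive — urban living land 1 up to other (desert) ecological land
8 — giving weights 0.03, 0.06, 0.08, 0.11, 0.14, 0.17, 0.19, 0.22.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .plel_core import (
    CategoricalRaster,
    CODE_TO_NAME,
    NAME_TO_CODE,
    PLEL_CODES,
    PLEL_NAMES,
    TIER_CODES,
)

logger = logging.getLogger(__name__)

#: Canonical sensitivity ranking (least → most vulnerable).
DEFAULT_RANKS = {
    "ULL": 1, "RLL": 2, "FEL": 3, "GEL": 4, "APL": 5, "WEL": 6, "IPL": 7, "OEL": 8,
}

_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


def vulnerability_weights(ranks: dict[str, int] | None = None, decimals: int = 2) -> pd.Series:
    """Normalized vulnerability weights F_i = rank_i / Σ ranks, rounded.

    With the default ranking the rounded weights are exactly
    (ULL 0.03, RLL 0.06, FEL 0.08, GEL 0.11, APL 0.14, WEL 0.17,
    IPL 0.19, OEL 0.22), which sum to 1.00.
    """
    if ranks is None:
        ranks = DEFAULT_RANKS
    vals = np.array([ranks[name] for name in ranks], dtype=float)
    if np.any(vals <= 0) or np.any(vals != np.round(vals)):
        raise ValueError("ranks must be positive integers")
    weights = np.round(vals / vals.sum(), decimals)
    return pd.Series(weights, index=list(ranks), name="F")


@dataclass
class EvaluationUnit:
    """One square evaluation unit: raster window plus clipped valid area."""

    unit_id: int
    row0: int
    col0: int
    n_cells_edge: int
    area_hm2: float
    centroid: tuple[float, float]


@dataclass
class EvaluationGrid:
    units: list[EvaluationUnit]
    unit_edge: float
    grid_shape: tuple[int, int]  # units per (row, col) before coverage filter

    def __len__(self) -> int:
        return len(self.units)

    def unit_index(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": [u.unit_id for u in self.units],
                "row0": [u.row0 for u in self.units],
                "col0": [u.col0 for u in self.units],
                "A_k": [u.area_hm2 for u in self.units],
                "centroid_x": [u.centroid[0] for u in self.units],
                "centroid_y": [u.centroid[1] for u in self.units],
            }
        ).set_index("unit_id")


def build_grid(
    r: CategoricalRaster, unit_edge: float = 3000.0, min_coverage: float = 0.1
) -> EvaluationGrid:
    """Tile the raster into square units of ``unit_edge`` meters.

    ``unit_edge`` must be an integer multiple of the cell size.  Units whose
    valid-cell fraction is below ``min_coverage`` are dropped; edge units
    are kept (clipped) and their A_k reflects only valid cells.
    """
    ratio = unit_edge / r.cell_size
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(
            f"unit_edge {unit_edge} is not a multiple of cell_size {r.cell_size}"
        )
    nrows, ncols = r.shape
    n_ur = int(np.ceil(nrows / k))
    n_uc = int(np.ceil(ncols / k))
    x0, y0 = r.origin
    units: list[EvaluationUnit] = []
    uid = 0
    for ur in range(n_ur):
        for uc in range(n_uc):
            r0, c0 = ur * k, uc * k
            sub = r.mask[r0 : r0 + k, c0 : c0 + k]
            frac = sub.mean()
            uid += 1
            if frac < min_coverage or not sub.any():
                continue
            area = float(sub.sum()) * r.cell_area_hm2
            cx = x0 + (c0 + sub.shape[1] / 2.0) * r.cell_size
            cy = y0 - (r0 + sub.shape[0] / 2.0) * r.cell_size
            units.append(EvaluationUnit(uid, r0, c0, k, area, (cx, cy)))
    return EvaluationGrid(units=units, unit_edge=unit_edge, grid_shape=(n_ur, n_uc))


def label_patches(
    r: CategoricalRaster, unit: EvaluationUnit, connectivity: int = 8
) -> dict[int, int]:
    """Per-class patch counts within the unit clip.

    Patches are connected components at 8- (default, the Fragstats
    convention) or 4-connectivity, cut at unit borders.
    """
    struct = _STRUCT8 if connectivity == 8 else _STRUCT4
    k = unit.n_cells_edge
    vals = r.values[unit.row0 : unit.row0 + k, unit.col0 : unit.col0 + k]
    mask = r.mask[unit.row0 : unit.row0 + k, unit.col0 : unit.col0 + k]
    counts: dict[int, int] = {}
    for code in np.unique(vals[mask]):
        _, n = ndimage.label((vals == code) & mask, structure=struct)
        counts[int(code)] = int(n)
    return counts


def _unit_class_stats(
    r: CategoricalRaster, grid: EvaluationGrid, connectivity: int
) -> pd.DataFrame:
    """Long table: one row per (unit, class present) with n_ki and A_ki."""
    rows = []
    for u in grid.units:
        k = u.n_cells_edge
        vals = r.values[u.row0 : u.row0 + k, u.col0 : u.col0 + k]
        mask = r.mask[u.row0 : u.row0 + k, u.col0 : u.col0 + k]
        patch = label_patches(r, u, connectivity)
        for code, n in patch.items():
            a = float(((vals == code) & mask).sum()) * r.cell_area_hm2
            rows.append((u.unit_id, code, n, a))
    return pd.DataFrame(rows, columns=["unit_id", "code", "n", "A"])


def global_dominance(
    r: CategoricalRaster, grid: EvaluationGrid, connectivity: int = 8
) -> pd.DataFrame:
    """Landscape-level dominance D_i = (Q_i + M_i)/4 + L_i/2 per class.

    Q_i: fraction of evaluation units where class i occurs; M_i: share of
    all (unit-clipped) patches; L_i: share of total valid area.
    """
    if len(grid) == 0:
        raise ValueError("empty evaluation grid")
    stats = _unit_class_stats(r, grid, connectivity)
    total_patches = stats["n"].sum()
    total_area = stats["A"].sum()
    n_units = len(grid)
    out = []
    for code in PLEL_CODES:
        sub = stats[stats["code"] == code]
        q = sub["unit_id"].nunique() / n_units
        m = sub["n"].sum() / total_patches if total_patches else 0.0
        l = sub["A"].sum() / total_area if total_area else 0.0
        out.append((CODE_TO_NAME[code], q, m, l, (q + m) / 4.0 + l / 2.0))
    return pd.DataFrame(out, columns=["class", "Q", "M", "L", "D"]).set_index("class")


def _dominance_for_unit(stats_u: pd.DataFrame) -> pd.Series:
    """Per-unit dominance (scope="unit"): Q degenerates to presence (1)."""
    total_patches = stats_u["n"].sum()
    total_area = stats_u["A"].sum()
    d = {}
    for _, row in stats_u.iterrows():
        m = row["n"] / total_patches if total_patches else 0.0
        l = row["A"] / total_area if total_area else 0.0
        d[CODE_TO_NAME[int(row["code"])]] = (1.0 + m) / 4.0 + l / 2.0
    return pd.Series(d, name="D")


def unit_eri(
    r: CategoricalRaster,
    unit: EvaluationUnit,
    dominance: pd.DataFrame,
    vulnerability: pd.Series,
    weights: tuple[float, float, float] = (0.5, 0.3, 0.2),
    connectivity: int = 8,
) -> dict:
    """Metrics, loss indices and ERI for one evaluation unit.

    Returns a flat record with per-class n/A/C/S/E/R plus ERI and the tier
    partial sums U1 (production), U2 (living), U3 (ecological).
    """
    a, b, c = weights
    if abs(a + b + c - 1.0) > 1e-9:
        raise ValueError("disturbance weights must sum to 1")
    if unit.area_hm2 <= 0:
        logger.warning("unit %d has zero valid area; skipped", unit.unit_id)
        return {}
    k = unit.n_cells_edge
    vals = r.values[unit.row0 : unit.row0 + k, unit.col0 : unit.col0 + k]
    mask = r.mask[unit.row0 : unit.row0 + k, unit.col0 : unit.col0 + k]
    patch = label_patches(r, unit, connectivity)
    A_k = unit.area_hm2
    rec: dict = {"unit_id": unit.unit_id, "A_k": A_k}
    eri = 0.0
    tier_sum = {"production": 0.0, "living": 0.0, "ecological": 0.0}
    for code, n in sorted(patch.items()):
        name = CODE_TO_NAME[code]
        A_ki = float(((vals == code) & mask).sum()) * r.cell_area_hm2
        C = n / A_ki
        S = (A_k / (2.0 * A_ki)) * np.sqrt(n / A_k)
        D = float(dominance.loc[name, "D"])
        E = a * C + b * S + c * D
        R = E * float(vulnerability[name])
        term = (A_ki / A_k) * R
        eri += term
        for tier, codes in TIER_CODES.items():
            if code in codes:
                tier_sum[tier] += term
        rec.update({f"n_{name}": n, f"A_{name}": A_ki, f"C_{name}": C,
                    f"S_{name}": S, f"E_{name}": E, f"R_{name}": R})
    rec["ERI"] = eri
    rec["U1"] = tier_sum["production"]
    rec["U2"] = tier_sum["living"]
    rec["U3"] = tier_sum["ecological"]
    return rec


def compute_unit_table(
    r: CategoricalRaster,
    grid: EvaluationGrid,
    vulnerability: pd.Series | None = None,
    weights: tuple[float, float, float] = (0.5, 0.3, 0.2),
    connectivity: int = 8,
    dominance_scope: str = "global",
) -> pd.DataFrame:
    """ERI and tier risks for every unit of the grid.

    ``dominance_scope`` selects whether D_i is computed once per epoch over
    the whole landscape ("global", default) or within each unit ("unit").
    """
    if vulnerability is None:
        vulnerability = vulnerability_weights()
    if dominance_scope not in ("global", "unit"):
        raise ValueError("dominance_scope must be 'global' or 'unit'")
    dom = global_dominance(r, grid, connectivity)
    stats = _unit_class_stats(r, grid, connectivity) if dominance_scope == "unit" else None
    records = []
    for u in grid.units:
        if dominance_scope == "unit":
            d_unit = _dominance_for_unit(stats[stats["unit_id"] == u.unit_id])
            dom_u = dom.copy()
            for name, v in d_unit.items():
                dom_u.loc[name, "D"] = v
        else:
            dom_u = dom
        rec = unit_eri(r, u, dom_u, vulnerability, weights, connectivity)
        if rec:
            cx, cy = u.centroid
            rec["centroid_x"], rec["centroid_y"] = cx, cy
            records.append(rec)
    df = pd.DataFrame(records).set_index("unit_id")
    lead = ["centroid_x", "centroid_y", "A_k", "ERI", "U1", "U2", "U3"]
    return df[lead + [c for c in df.columns if c not in lead]]
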