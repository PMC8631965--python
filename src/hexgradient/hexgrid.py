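"""Hexagonal tessellation of the slide plane and per-hexagon aggregates.

Cells are assigned to the hexagon whose center is nearest (implemented by
fractional axial coordinates plus cube rounding, which is exactly the
nearest-center rule for a regular hexagonal tessellation).  Tiles are indexed
by axial coordinates (q, r); the default orientation is flat-top.

Two grids are used in practice: a coarse grid (side 257 um) for
intratumoral-heterogeneity texture, on which hexagons with fewer than 50
cells are regarded as insufficient sampling and excluded, and a fine grid
(side 65 um) for the tumor-stroma interface zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from hexgradient.cell_io import CellTable
from hexgradient.errors import ParameterError, UndefinedIndicatorError

SQRT3 = np.sqrt(3.0)

#: axial offsets of the 6 hexagon neighbors (same for both orientations)
HEX_NEIGHBOR_OFFSETS = ((1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1))

#: markers whose per-hexagon percentage is computed over tumor cells
MARKERS = ("ER", "PR", "Ki67", "HER2", "HER2_MC")

_FLAG_OF = {"ER": "er_pos", "PR": "pr_pos", "Ki67": "ki67_pos", "CD8": "cd8_pos"}


@dataclass(frozen=True)
class HexGridSpec:
    """Geometry of a hexagonal tessellation.

    side_um
        Hexagon side length in micrometres.  257 um for the coarse
        heterogeneity grid, 65 um for the fine interface-zone grid.
    orientation
        ``flat_top`` (default) or ``pointy_top``.
    origin
        (x, y) of the (0, 0) tile center, in micrometres.
    """

    side_um: float = 257.0
    orientation: Literal["flat_top", "pointy_top"] = "flat_top"
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.side_um <= 0:
            raise ParameterError("side_um must be positive")

    @property
    def area_mm2(self) -> float:
        """Hexagon area (3*sqrt(3)/2) * side^2 in mm^2."""
        s_mm = self.side_um / 1000.0
        return 1.5 * SQRT3 * s_mm * s_mm

    def centers(self, q: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cartesian centers (um) of tiles at axial coordinates (q, r)."""
        q = np.asarray(q, dtype=float)
        r = np.asarray(r, dtype=float)
        ox, oy = self.origin
        if self.orientation == "flat_top":
            x = ox + 1.5 * self.side_um * q
            y = oy + SQRT3 * self.side_um * (r + q / 2.0)
        else:
            x = ox + SQRT3 * self.side_um * (q + r / 2.0)
            y = oy + 1.5 * self.side_um * r
        return x, y

    def axial_of_points(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Axial (q, r) of the hexagon containing each point (nearest center).

        Boundary points (equidistant centers) resolve deterministically via
        cube rounding, which breaks ties by the largest fractional residual.
        """
        x = np.asarray(x, dtype=float) - self.origin[0]
        y = np.asarray(y, dtype=float) - self.origin[1]
        s = self.side_um
        if self.orientation == "flat_top":
            qf = (2.0 / 3.0) * x / s
            rf = (-x / 3.0 + SQRT3 / 3.0 * y) / s
        else:
            qf = (SQRT3 / 3.0 * x - y / 3.0) / s
            rf = (2.0 / 3.0) * y / s
        return _cube_round(qf, rf)


def _cube_round(qf: np.ndarray, rf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Round fractional axial coordinates to the nearest hexagon."""
    sf = -qf - rf
    q = np.round(qf)
    r = np.round(rf)
    s = np.round(sf)
    dq = np.abs(q - qf)
    dr = np.abs(r - rf)
    ds = np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q = np.where(fix_q, -r - s, q)
    r = np.where(fix_r, -q - s, r)
    return q.astype(np.int64), r.astype(np.int64)


@dataclass
class HexStatTable:
    """Per-hexagon aggregates for one slide on one grid.

    ``tiles`` has one row per non-empty hexagon, sorted by (q, r):

    q, r, center_x, center_y, n_total, n_tumor, n_stroma, n_background,
    n_analyzable, er_pos, pr_pos, ki67_pos, her2_pos (tumor cells with IHC
    class 2/3), mc_sum / mc_n (HER2 membrane completeness over tumor cells),
    cd8_count, retained.

    ``cell_tile`` maps each input cell (row order of the CellTable) to its
    tile row index.
    """

    grid: HexGridSpec
    tiles: pd.DataFrame = field(repr=False)
    cell_tile: np.ndarray = field(repr=False)
    min_cells: int | None = None
    filter_on: str = "all"

    def __len__(self) -> int:
        return len(self.tiles)

    @property
    def area_mm2(self) -> float:
        return self.grid.area_mm2

    def tile_index(self) -> dict[tuple[int, int], int]:
        """(q, r) -> row position lookup."""
        return {
            (int(q), int(r)): i
            for i, (q, r) in enumerate(zip(self.tiles["q"], self.tiles["r"]))
        }

    def neighbor_pairs(self) -> np.ndarray:
        """Unordered adjacent tile pairs as an (m, 2) array of row positions.

        Adjacency is the 6-neighborhood of the hexagonal tessellation; only
        pairs where both tiles are materialized (non-empty) appear.
        """
        idx = self.tile_index()
        pairs = []
        for (q, r), i in idx.items():
            for dq, dr in HEX_NEIGHBOR_OFFSETS[:3]:  # half the offsets: each pair once
                j = idx.get((q + dq, r + dr))
                if j is not None:
                    pairs.append((i, j))
        return np.array(pairs, dtype=np.int64).reshape(-1, 2)


def assign_cells(cells: CellTable, grid: HexGridSpec) -> HexStatTable:
    """Assign every cell to its nearest hexagon center and aggregate.

    Each cell maps to exactly one hexagon; tiles with zero cells are not
    materialized.  The returned table is unfiltered (``retained`` true for
    every tile) until :func:`apply_sampling_filter` is applied.
    """
    df = cells.df
    q, r = grid.axial_of_points(df["x_um"].to_numpy(), df["y_um"].to_numpy())

    key = pd.DataFrame({"q": q, "r": r})
    uniq, inverse = np.unique(key.to_numpy(), axis=0, return_inverse=True)
    n_tiles = len(uniq)

    def count_where(mask: np.ndarray) -> np.ndarray:
        return np.bincount(inverse[mask], minlength=n_tiles)

    tumor = (df["tissue_class"] == "tumor").to_numpy()
    stroma = (df["tissue_class"] == "stroma").to_numpy()
    background = (df["tissue_class"] == "background").to_numpy()
    analyzable = df["analyzable"].to_numpy()

    tiles = pd.DataFrame({"q": uniq[:, 0], "r": uniq[:, 1]})
    cx, cy = grid.centers(tiles["q"].to_numpy(), tiles["r"].to_numpy())
    tiles["center_x"] = cx
    tiles["center_y"] = cy
    tiles["n_total"] = np.bincount(inverse, minlength=n_tiles)
    tiles["n_tumor"] = count_where(tumor)
    tiles["n_stroma"] = count_where(stroma)
    tiles["n_background"] = count_where(background)
    tiles["n_analyzable"] = count_where(analyzable)

    for marker, flag in (("er", "er_pos"), ("pr", "pr_pos"), ("ki67", "ki67_pos")):
        pos = df[flag].to_numpy().astype(bool)
        tiles[f"{marker}_pos"] = count_where(pos & tumor)
        tiles[f"{marker}_pos_all"] = count_where(pos & analyzable)

    her2 = df["her2_class"].to_numpy()
    her2_pos = np.isin(her2, (2.0, 3.0))
    tiles["her2_pos"] = count_where(her2_pos & tumor)
    tiles["her2_pos_all"] = count_where(her2_pos & analyzable)
    tiles["her2_scored"] = count_where(np.isfinite(her2) & tumor)

    mc = df["her2_mc_pct"].to_numpy()
    has_mc = np.isfinite(mc) & tumor
    tiles["mc_sum"] = np.bincount(
        inverse[has_mc], weights=mc[has_mc], minlength=n_tiles
    )
    tiles["mc_n"] = count_where(has_mc)

    tiles["cd8_count"] = count_where(df["cd8_pos"].to_numpy().astype(bool) & analyzable)
    tiles["retained"] = True

    order = np.lexsort((tiles["r"].to_numpy(), tiles["q"].to_numpy()))
    remap = np.empty(n_tiles, dtype=np.int64)
    remap[order] = np.arange(n_tiles)
    tiles = tiles.iloc[order].reset_index(drop=True)
    return HexStatTable(grid=grid, tiles=tiles, cell_tile=remap[inverse])


def apply_sampling_filter(
    stats: HexStatTable, min_cells: int = 50, count: Literal["all", "analyzable"] = "all"
) -> HexStatTable:
    """Flag hexagons with fewer than ``min_cells`` cells as insufficient
    sampling.

    Excluded tiles stay in the table (adjacency bookkeeping needs them) but
    are barred from ranking, co-occurrence and density statistics.  By
    default all cells count toward the threshold; ``count="analyzable"``
    restricts to non-background cells.
    """
    if min_cells < 1:
        raise ParameterError("min_cells must be >= 1")
    tiles = stats.tiles.copy()
    col = "n_total" if count == "all" else "n_analyzable"
    tiles["retained"] = tiles[col] >= min_cells
    return replace(stats, tiles=tiles, min_cells=min_cells, filter_on=count)


def marker_percentage(
    tile: pd.Series, marker: str, denominator: Literal["tumor", "all"] = "tumor"
) -> float:
    """Percentage of marker-positive cells in one hexagon.

    For ER/PR/Ki67/HER2 the default denominator is the tile's tumor cells
    (IHC scoring convention); HER2 counts IHC classes 2+/3+ as positive.
    ``HER2_MC`` returns the mean membrane completeness over tumor cells
    (already a percentage).  Returns NaN when the denominator is zero.
    """
    if marker == "HER2_MC":
        return float(tile["mc_sum"] / tile["mc_n"]) if tile["mc_n"] > 0 else float("nan")
    col = {"ER": "er_pos", "PR": "pr_pos", "Ki67": "ki67_pos", "HER2": "her2_pos"}.get(marker)
    if col is None:
        raise ParameterError(f"unknown marker {marker!r}")
    if marker == "HER2" and tile["her2_scored"] == 0:
        return float("nan")
    if denominator == "tumor":
        num, den = tile[col], tile["n_tumor"]
    else:
        num, den = tile[f"{col}_all"], tile["n_analyzable"]
    return float(100.0 * num / den) if den > 0 else float("nan")


def tile_marker_percentages(
    stats: HexStatTable, marker: str, denominator: Literal["tumor", "all"] = "tumor"
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-tile marker percentage.

    Returns (values, denominators); values are NaN where the denominator is
    zero.  Denominators are tumor-cell counts (or analyzable counts), used by
    the texture stage's minimum-denominator rule.
    """
    t = stats.tiles
    if marker == "HER2_MC":
        den = t["mc_n"].to_numpy().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(den > 0, t["mc_sum"].to_numpy() / den, np.nan)
        return vals, den
    col = {"ER": "er_pos", "PR": "pr_pos", "Ki67": "ki67_pos", "HER2": "her2_pos"}.get(marker)
    if col is None:
        raise ParameterError(f"unknown marker {marker!r}")
    if denominator == "tumor":
        num = t[col].to_numpy().astype(float)
        den = t["n_tumor"].to_numpy().astype(float)
    else:
        num = t[f"{col}_all"].to_numpy().astype(float)
        den = t["n_analyzable"].to_numpy().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(den > 0, 100.0 * num / den, np.nan)
    if marker == "HER2":
        # slides without HER2 staining carry no intensity classes at all;
        # an unstained tile is undefined, not 0% positive
        vals = np.where(t["her2_scored"].to_numpy() > 0, vals, np.nan)
    return vals, den


def cd8_density(tile: pd.Series, grid: HexGridSpec) -> float:
    """CD8-positive cells per mm^2 in one hexagon."""
    return float(tile["cd8_count"] / grid.area_mm2)


def tile_cd8_densities(stats: HexStatTable) -> np.ndarray:
    """Vectorized CD8 density (cells/mm^2) for every tile."""
    return stats.tiles["cd8_count"].to_numpy() / stats.grid.area_mm2


def slide_summary(stats: HexStatTable, cells: CellTable) -> dict[str, float]:
    """Slide-level indicators computed over all analyzable cells.

    Marker percentages are cell-level (not averages of hexagon percentages):
    ER/PR/Ki67 percent positive of tumor cells, HER2 percent of tumor cells
    with IHC class 2+/3+, HER2 MC the mean membrane completeness over tumor
    cells.  CD8 density per tissue class divides the class CD8 count by an
    approximate class area (retained-tile area weighted by the class's cell
    fraction in each tile).
    """
    df = cells.df
    tumor = df[df["tissue_class"] == "tumor"]
    if len(tumor) == 0:
        raise UndefinedIndicatorError("slide has no tumor cells")
    out: dict[str, float] = {}
    n_t = len(tumor)
    out["ER_pct"] = 100.0 * tumor["er_pos"].sum() / n_t
    out["PR_pct"] = 100.0 * tumor["pr_pos"].sum() / n_t
    out["Ki67_pct"] = 100.0 * tumor["ki67_pos"].sum() / n_t
    out["HER2_pct"] = (
        100.0 * tumor["her2_class"].isin((2.0, 3.0)).sum() / n_t
        if tumor["her2_class"].notna().any()
        else float("nan")
    )
    mc = tumor["her2_mc_pct"].dropna()
    out["HER2_MC"] = float(mc.mean()) if len(mc) else float("nan")

    ret = stats.tiles[stats.tiles["retained"]]
    area = stats.grid.area_mm2
    for cls in ("tumor", "stroma"):
        frac = np.where(
            ret["n_total"] > 0, ret[f"n_{cls}"] / ret["n_total"], 0.0
        )
        cls_area = float((area * frac).sum())
        cls_cd8 = int(
            df.loc[(df["tissue_class"] == cls) & (df["cd8_pos"] == 1)].shape[0]
        )
        out[f"CD8_density_{cls}"] = cls_cd8 / cls_area if cls_area > 0 else float("nan")
    return out
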