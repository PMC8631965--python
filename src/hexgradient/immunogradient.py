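"""Tumor-stroma interface zone (IZ) and CD8 Immunogradient indicators.

On a fine hexagonal grid (side 65 um by default), tiles are labeled tumor or
stroma by majority cell class.  The IZ is a band of seven ranks centered on
the tumor edge: rank 0 tiles are tumor tiles touching stroma; positive ranks
grow by breadth-first layers into the tumor and negative ranks into the
stroma.  Three aspects partition the zone: S (ranks -3..-1), TE (rank 0) and
T (ranks +1..+3).

The Immunogradient indicators summarize the CD8 density profile across the
zone: per-aspect mean densities and SDs, the center of mass CM (a
density-weighted mean rank; positive values mean infiltration shifted toward
the tumor), its variability CM_sd over local profiles, and the immunodrop ID
(the density ratio between rank -1 and rank +1, measuring an abrupt drop
across the tumor edge).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hexgradient.errors import ParameterError, UndefinedIndicatorError
from hexgradient.hexgrid import (
    HEX_NEIGHBOR_OFFSETS,
    HexGridSpec,
    HexStatTable,
    tile_cd8_densities,
)

#: sentinel rank for tiles outside the interface zone
NOT_IN_IZ = -999

#: default minimum cells for a fine-grid tile to be labeled
FINE_MIN_CELLS = 5

#: default majority fraction for tumor/stroma tile labeling
TAU = 0.5


@dataclass
class InterfaceZone:
    """Labeled fine-grid tiles with signed IZ ranks.

    ``labels`` and ``ranks`` align with the tile rows of the source
    HexStatTable.  ``ranks`` holds integers in -w..+w inside the zone
    (w = (width-1)/2) and NOT_IN_IZ elsewhere.
    """

    grid: HexGridSpec
    labels: np.ndarray = field(repr=False)  # 'tumor' | 'stroma' | 'excluded'
    ranks: np.ndarray = field(repr=False)
    width: int = 7

    @property
    def in_iz(self) -> np.ndarray:
        return self.ranks != NOT_IN_IZ

    def aspect_of(self) -> np.ndarray:
        """Per-tile aspect: 'S', 'TE', 'T', or '' outside the zone."""
        out = np.full(len(self.ranks), "", dtype=object)
        out[(self.ranks != NOT_IN_IZ) & (self.ranks < 0)] = "S"
        out[self.ranks == 0] = "TE"
        out[(self.ranks != NOT_IN_IZ) & (self.ranks > 0)] = "T"
        return out


@dataclass
class ImmunogradientProfile:
    """Per-rank and per-aspect CD8 density statistics across the IZ."""

    ranks: np.ndarray
    mean_density: np.ndarray
    sd_density: np.ndarray
    n_tiles: np.ndarray
    aspects: dict[str, float]

    def density_at(self, rank: int) -> float:
        pos = np.flatnonzero(self.ranks == rank)
        return float(self.mean_density[pos[0]]) if len(pos) else float("nan")


def label_tiles(
    stats: HexStatTable, tau: float = TAU, min_cells: int = FINE_MIN_CELLS
) -> np.ndarray:
    """Label each fine-grid tile tumor/stroma/excluded by majority cell class.

    A tile is tumor if its tumor fraction of analyzable cells is >= tau
    (ties break toward tumor), stroma if the stroma fraction is >= tau,
    excluded otherwise or when it holds fewer than ``min_cells`` cells.
    """
    if not 0 < tau <= 1:
        raise ParameterError("tau must be in (0, 1]")
    t = stats.tiles
    n = t["n_analyzable"].to_numpy().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tumor_frac = np.where(n > 0, t["n_tumor"] / n, 0.0)
        stroma_frac = np.where(n > 0, t["n_stroma"] / n, 0.0)
    labels = np.full(len(t), "excluded", dtype=object)
    enough = t["n_total"].to_numpy() >= min_cells
    labels[enough & (stroma_frac >= tau)] = "stroma"
    labels[enough & (tumor_frac >= tau)] = "tumor"  # last wins: tie -> tumor
    if not (labels == "tumor").any() or not (labels == "stroma").any():
        raise UndefinedIndicatorError(
            "interface zone undefined: slide lacks tumor or stroma tiles"
        )
    return labels


def extract_iz(
    labels: np.ndarray, stats: HexStatTable, width: int = 7
) -> InterfaceZone:
    """Extract the interface zone as signed hexagon ranks.

    Rank 0 = tumor tiles with at least one stroma 6-neighbor.  Rank k
    (k >= 1) = tumor tiles adjacent to rank k-1 and not yet ranked; rank -k
    symmetrically through stroma tiles.  Excluded tiles block propagation.
    Ranks are limited to +/- (width-1)/2.
    """
    if width < 1 or width % 2 == 0:
        raise ParameterError("width must be a positive odd number of ranks")
    half = (width - 1) // 2
    idx = stats.tile_index()
    q = stats.tiles["q"].to_numpy()
    r = stats.tiles["r"].to_numpy()
    n = len(labels)

    neighbors: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for dq, dr in HEX_NEIGHBOR_OFFSETS:
            j = idx.get((int(q[i]) + dq, int(r[i]) + dr))
            if j is not None:
                neighbors[i].append(j)

    ranks = np.full(n, NOT_IN_IZ, dtype=np.int64)
    is_tumor = labels == "tumor"
    is_stroma = labels == "stroma"

    frontier = [
        i
        for i in range(n)
        if is_tumor[i] and any(is_stroma[j] for j in neighbors[i])
    ]
    if not frontier:
        raise UndefinedIndicatorError("no tumor-stroma adjacency: IZ undefined")
    ranks[frontier] = 0

    # positive ranks: breadth-first layers into the tumor
    layer = frontier
    for k in range(1, half + 1):
        nxt = sorted(
            {
                j
                for i in layer
                for j in neighbors[i]
                if is_tumor[j] and ranks[j] == NOT_IN_IZ
            }
        )
        ranks[nxt] = k
        layer = nxt
    # negative ranks: layers into the stroma
    layer = frontier
    for k in range(1, half + 1):
        nxt = sorted(
            {
                j
                for i in layer
                for j in neighbors[i]
                if is_stroma[j] and ranks[j] == NOT_IN_IZ
            }
        )
        ranks[nxt] = -k
        layer = nxt

    return InterfaceZone(grid=stats.grid, labels=labels, ranks=ranks, width=width)


def density_profile(zone: InterfaceZone, stats: HexStatTable) -> ImmunogradientProfile:
    """Per-rank and per-aspect CD8 density means and SDs across the IZ.

    Per-rank values are means/SDs over the tiles of that rank; aspect
    statistics pool all tiles of the aspect's ranks.  SDs are population
    SDs across tiles (0 for a single tile).  An aspect with no tiles is
    reported NaN.
    """
    dens = tile_cd8_densities(stats)
    half = (zone.width - 1) // 2
    rank_values = np.arange(-half, half + 1)
    mean = np.full(len(rank_values), np.nan)
    sd = np.full(len(rank_values), np.nan)
    n_tiles = np.zeros(len(rank_values), dtype=np.int64)
    for pos, rk in enumerate(rank_values):
        d = dens[zone.ranks == rk]
        n_tiles[pos] = len(d)
        if len(d):
            mean[pos] = d.mean()
            sd[pos] = d.std(ddof=0)
    aspects: dict[str, float] = {}
    aspect_tiles = zone.aspect_of()
    for name in ("S", "TE", "T"):
        d = dens[aspect_tiles == name]
        aspects[f"CD8_d_{name}"] = float(d.mean()) if len(d) else float("nan")
        aspects[f"CD8_d_{name}_sd"] = float(d.std(ddof=0)) if len(d) else float("nan")
    return ImmunogradientProfile(
        ranks=rank_values, mean_density=mean, sd_density=sd, n_tiles=n_tiles,
        aspects=aspects,
    )


def _hex_distance(q1: int, r1: int, q2: np.ndarray, r2: np.ndarray) -> np.ndarray:
    dq = q2 - q1
    dr = r2 - r1
    return (np.abs(dq) + np.abs(dr) + np.abs(dq + dr)) // 2


def center_of_mass(zone: InterfaceZone, stats: HexStatTable) -> tuple[float, float]:
    """CD8 center of mass across the IZ and its SD over local profiles.

    Every IZ tile is assigned to its nearest rank-0 tile (hexagon-metric
    distance; ties broken by Euclidean center distance, then smallest (q, r)).
    For each rank-0 tile whose local group spans at least one negative and
    one positive rank with positive total density, the local CM is
    sum_r r * d_r / sum_r d_r over the group's per-rank mean densities.
    CD8_CM is the mean of local CMs and CD8_CM_sd their population SD.
    """
    dens = tile_cd8_densities(stats)
    iz = np.flatnonzero(zone.in_iz)
    r0 = np.flatnonzero(zone.ranks == 0)
    if len(r0) == 0:
        raise UndefinedIndicatorError("no rank-0 tiles: CM undefined")
    q = stats.tiles["q"].to_numpy()
    r = stats.tiles["r"].to_numpy()
    cx = stats.tiles["center_x"].to_numpy()
    cy = stats.tiles["center_y"].to_numpy()

    assigned: dict[int, list[int]] = {int(i): [] for i in r0}
    for i in iz:
        hd = _hex_distance(q[i], r[i], q[r0], r[r0])
        cand = r0[hd == hd.min()]
        if len(cand) > 1:
            ed = (cx[cand] - cx[i]) ** 2 + (cy[cand] - cy[i]) ** 2
            cand = cand[ed == ed.min()]
            if len(cand) > 1:
                order = np.lexsort((r[cand], q[cand]))
                cand = cand[order[:1]]
        assigned[int(cand[0])].append(int(i))

    local_cms = []
    for members in assigned.values():
        members = np.asarray(members, dtype=np.int64)
        rks = zone.ranks[members]
        if not ((rks < 0).any() and (rks > 0).any()):
            continue
        uniq = np.unique(rks)
        d_r = np.array([dens[members[rks == k]].mean() for k in uniq])
        total = d_r.sum()
        if total <= 0:
            continue
        local_cms.append(float((uniq * d_r).sum() / total))
    if not local_cms:
        raise UndefinedIndicatorError("all local profiles invalid: CM undefined")
    arr = np.asarray(local_cms)
    return float(arr.mean()), float(arr.std(ddof=0))


#: pseudocount added to both densities in the immunodrop ratio (cells/mm^2)
ID_EPSILON = 1.0


def immunodrop(
    zone: InterfaceZone, stats: HexStatTable, eps: float = ID_EPSILON
) -> float:
    """Immunodrop: CD8 density ratio between rank -1 and rank +1.

    CD8_ID = (d_-1 + eps) / (d_+1 + eps) with a 1 cell/mm^2 pseudocount so
    the ratio stays defined on sparse slides.  Values > 1 indicate an abrupt
    density drop from stroma into the tumor across the tumor edge.
    """
    profile = density_profile(zone, stats)
    d_minus = profile.density_at(-1)
    d_plus = profile.density_at(+1)
    if not (np.isfinite(d_minus) and np.isfinite(d_plus)):
        raise UndefinedIndicatorError("rank -1 or +1 empty: immunodrop undefined")
    return float((d_minus + eps) / (d_plus + eps))


def immunogradient_indicators(
    stats: HexStatTable,
    width: int = 7,
    tau: float = TAU,
    min_cells: int = FINE_MIN_CELLS,
) -> dict[str, float]:
    """All Immunogradient indicators for one slide's fine-grid statistics.

    Returns CD8_d_S, CD8_d_S_sd, CD8_d_TE, CD8_d_TE_sd, CD8_d_T, CD8_d_T_sd,
    CD8_CM, CD8_CM_sd and CD8_ID.  Raises UndefinedIndicatorError if the
    slide has no tumor-stroma interface.
    """
    labels = label_tiles(stats, tau=tau, min_cells=min_cells)
    zone = extract_iz(labels, stats, width=width)
    profile = density_profile(zone, stats)
    out = dict(profile.aspects)
    cm, cm_sd = center_of_mass(zone, stats)
    out["CD8_CM"] = cm
    out["CD8_CM_sd"] = cm_sd
    out["CD8_ID"] = immunodrop(zone, stats)
    return out


def zone_table(zone: InterfaceZone, stats: HexStatTable) -> pd.DataFrame:
    """IZ export: one row per tile with label, rank, aspect and CD8 density."""
    dens = tile_cd8_densities(stats)
    aspect = zone.aspect_of()
    t = stats.tiles
    return pd.DataFrame(
        {
            "q": t["q"],
            "r": t["r"],
            "label": zone.labels,
            "rank": np.where(zone.in_iz, zone.ranks, np.nan),
            "aspect": aspect,
            "cd8_count": t["cd8_count"],
            "cd8_density": dens,
        }
    )
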