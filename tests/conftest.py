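"""Shared fixtures and builders for planted hexagon fields."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hexgradient.cell_io import CellTable
from hexgradient.hexgrid import HexGridSpec, apply_sampling_filter, assign_cells
from hexgradient.synthetic import fixture_suite


def build_planted_cells(
    tile_spec: dict[tuple[int, int], dict], grid: HexGridSpec, slide_id: str = "planted"
) -> CellTable:
    """Cell table with planted per-tile composition.

    ``tile_spec[(q, r)] = {"cls": "tumor", "n": 20, "cd8": 0}`` places ``n``
    cells of the class plus ``cd8`` CD8-positive cells of the same class,
    all exactly at the tile center (guaranteeing assignment to that tile).
    """
    rows = []
    for (q, r), spec in tile_spec.items():
        cx, cy = grid.centers(np.array([q]), np.array([r]))
        cls = spec.get("cls", "tumor")
        for _ in range(spec.get("n", 0)):
            rows.append((float(cx[0]), float(cy[0]), cls, 0))
        for _ in range(spec.get("cd8", 0)):
            rows.append((float(cx[0]), float(cy[0]), cls, 1))
    df = pd.DataFrame(rows, columns=["x_um", "y_um", "tissue_class", "cd8_pos"])
    df["slide_id"] = slide_id
    return CellTable.from_dataframe(df, slide_id=slide_id)


def planted_stats(
    tile_spec: dict[tuple[int, int], dict],
    grid: HexGridSpec | None = None,
    min_cells: int = 5,
):
    """assign + filter in one step for planted tile specs."""
    grid = grid or HexGridSpec(side_um=65.0)
    cells = build_planted_cells(tile_spec, grid)
    return apply_sampling_filter(assign_cells(cells, grid), min_cells=min_cells)


def line_zone_spec(
    cd8_counts: list[int],
    n_stroma_tiles: int = 4,
    base_cells: int = 20,
    r: int = 4,
) -> dict[tuple[int, int], dict]:
    """A straight line of adjacent tiles crossing a tumor-stroma boundary.

    Tiles (0, r) .. (len-1, r); the first ``n_stroma_tiles`` are stroma, the
    rest tumor, each holding ``base_cells`` cells plus the requested CD8
    count.  With 4 stroma + 4 tumor tiles the interface zone is exactly one
    tile per rank -3..+3 and tile 0 stays outside the zone.
    """
    spec = {}
    for q, cd8 in enumerate(cd8_counts):
        cls = "stroma" if q < n_stroma_tiles else "tumor"
        spec[(q, r)] = {"cls": cls, "n": base_cells, "cd8": cd8}
    return spec


@pytest.fixture(scope="session")
def fixtures_dir(tmp_path_factory):
    """The generated synthetic fixture suite (slides + ground truth)."""
    out = tmp_path_factory.mktemp("fixtures")
    fixture_suite(out, seed=0)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
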