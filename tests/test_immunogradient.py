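"""Interface-zone extraction and Immunogradient indicators."""

import numpy as np
import pytest

from hexgradient.errors import ParameterError, UndefinedIndicatorError
from hexgradient.hexgrid import HexGridSpec
from hexgradient.immunogradient import (
    NOT_IN_IZ,
    center_of_mass,
    density_profile,
    extract_iz,
    immunodrop,
    immunogradient_indicators,
    label_tiles,
)
from hexgradient.synthetic import CD8GradientSpec, SlideSimConfig, simulate_slide
from hexgradient.hexgrid import apply_sampling_filter, assign_cells
from tests.conftest import line_zone_spec, planted_stats


FINE = HexGridSpec(side_um=65.0, origin=(300.0, 300.0))


def line_stats(cd8_counts, n_stroma_tiles=4):
    return planted_stats(
        line_zone_spec(cd8_counts, n_stroma_tiles=n_stroma_tiles), grid=FINE
    )


# ----------------------------------------------------------------- labeling


def test_label_majority_and_tie_convention():
    stats = planted_stats(
        {
            (0, 4): {"cls": "tumor", "n": 10},
            (1, 4): {"cls": "stroma", "n": 10},
        },
        grid=FINE,
    )
    labels = label_tiles(stats)
    assert set(labels) == {"tumor", "stroma"}

    # 50/50 tile breaks toward tumor under the >= convention
    mixed = planted_stats(
        {
            (0, 4): {"cls": "tumor", "n": 5},
            (1, 4): {"cls": "stroma", "n": 10},
        },
        grid=FINE,
    )
    mixed.tiles.loc[0, "n_stroma"] = 5
    mixed.tiles.loc[0, "n_tumor"] = 5
    mixed.tiles.loc[0, "n_analyzable"] = 10
    mixed.tiles.loc[0, "n_total"] = 10
    labels = label_tiles(mixed)
    assert labels[0] == "tumor"


def test_label_needs_both_compartments():
    stats = planted_stats({(0, 4): {"cls": "tumor", "n": 10}}, grid=FINE)
    with pytest.raises(UndefinedIndicatorError):
        label_tiles(stats)


def test_undersampled_tiles_excluded():
    stats = planted_stats(
        {
            (0, 4): {"cls": "tumor", "n": 3},  # below fine-grid min of 5
            (1, 4): {"cls": "tumor", "n": 10},
            (2, 4): {"cls": "stroma", "n": 10},
        },
        grid=FINE,
    )
    labels = label_tiles(stats)
    assert labels[0] == "excluded"


# ---------------------------------------------------------------- iz ranks


def test_halfplane_ranks_form_parallel_bands():
    # columns q=0..8 of a fine axial lattice; stroma q<=3, tumor q>=4
    spec = {}
    for q in range(9):
        for r in range(12):
            cls = "stroma" if q <= 3 else "tumor"
            spec[(q, r)] = {"cls": cls, "n": 10}
    stats = planted_stats(spec, grid=FINE)
    labels = label_tiles(stats)
    zone = extract_iz(labels, stats, width=7)
    q = stats.tiles["q"].to_numpy()
    expected = q - 4  # rank 0 at the first tumor column
    expected = np.where(np.abs(expected) <= 3, expected, NOT_IN_IZ)
    assert (zone.ranks == expected).all()


def test_isolated_tumor_tile_is_rank_zero():
    spec = {(q, r): {"cls": "stroma", "n": 10} for q in range(3) for r in range(3, 6)}
    spec[(1, 4)] = {"cls": "tumor", "n": 10}
    stats = planted_stats(spec, grid=FINE)
    labels = label_tiles(stats)
    zone = extract_iz(labels, stats, width=7)
    idx = stats.tile_index()
    assert zone.ranks[idx[(1, 4)]] == 0
    for nb in [(2, 4), (2, 3), (1, 3), (0, 4), (0, 5), (1, 5)]:
        assert zone.ranks[idx[nb]] == -1


def test_width_parameter_limits_ranks():
    stats = line_stats([10] * 8)
    labels = label_tiles(stats)
    zone = extract_iz(labels, stats, width=3)
    got = sorted(set(zone.ranks) - {NOT_IN_IZ})
    assert got == [-1, 0, 1]
    with pytest.raises(ParameterError):
        extract_iz(labels, stats, width=4)


def test_rank_band_conservation():
    stats = line_stats([10] * 8)
    labels = label_tiles(stats)
    zone = extract_iz(labels, stats, width=7)
    aspects = zone.aspect_of()
    n_iz = int(zone.in_iz.sum())
    assert n_iz == 7  # one tile per rank on the 8-tile line
    assert sum(aspects[i] != "" for i in range(len(aspects))) == n_iz
    # each IZ tile has exactly one rank
    assert len(set(zone.ranks[zone.in_iz])) == 7


# ----------------------------------------------------------------- profile


def test_flat_profile_means_sds_cm_immunodrop():
    stats = line_stats([10] * 8)
    labels = label_tiles(stats)
    zone = extract_iz(labels, stats, width=7)
    prof = density_profile(zone, stats)
    assert np.allclose(prof.mean_density, prof.mean_density[0])
    assert np.allclose(prof.sd_density, 0.0)
    assert prof.aspects["CD8_d_S"] == pytest.approx(prof.aspects["CD8_d_T"])
    cm, cm_sd = center_of_mass(zone, stats)
    assert cm == pytest.approx(0.0, abs=1e-12)
    assert cm_sd == 0.0
    assert immunodrop(zone, stats) == pytest.approx(1.0)


def test_planted_aspect_densities():
    # ranks -3..+3 get densities prop. to 100,100,100,50,10,10,10
    counts = [0, 100, 100, 100, 50, 10, 10, 10]  # tile 0 outside the zone
    stats = line_stats(counts)
    labels = label_tiles(stats)
    zone = extract_iz(labels, stats, width=7)
    prof = density_profile(zone, stats)
    area = stats.grid.area_mm2
    assert prof.aspects["CD8_d_S"] == pytest.approx(100 / area)
    assert prof.aspects["CD8_d_TE"] == pytest.approx(50 / area)
    assert prof.aspects["CD8_d_T"] == pytest.approx(10 / area)
    assert prof.aspects["CD8_d_S_sd"] == pytest.approx(0.0)


def test_center_of_mass_hand_sum():
    # one tile per rank with density prop. to rank + 4 (weights 1..7)
    counts = [0] + [10 * (r + 4) for r in range(-3, 4)]
    stats = line_stats(counts)
    labels = label_tiles(stats)
    zone = extract_iz(labels, stats, width=7)
    cm, cm_sd = center_of_mass(zone, stats)
    # sum r * w_r = 28, sum w_r = 280 in tile counts -> 28*10/280 = 1.0
    assert cm == pytest.approx(1.0)
    assert cm_sd == 0.0


def test_cm_scale_invariance():
    counts = [0, 30, 40, 50, 60, 70, 80, 90]
    stats_a = line_stats(counts)
    stats_b = line_stats([0] + [3 * c for c in counts[1:]])
    labels_a = label_tiles(stats_a)
    zone_a = extract_iz(labels_a, stats_a, width=7)
    labels_b = label_tiles(stats_b)
    zone_b = extract_iz(labels_b, stats_b, width=7)
    cm_a, _ = center_of_mass(zone_a, stats_a)
    cm_b, _ = center_of_mass(zone_b, stats_b)
    assert cm_b == pytest.approx(cm_a, rel=1e-9)


def test_immunodrop_hand_ratio():
    area = HexGridSpec(side_um=65.0).area_mm2
    # counts 100 and 25 at ranks -1/+1 give a 4:1 density ratio
    stats = line_stats([0, 10, 10, 100, 50, 25, 10, 10])
    labels = label_tiles(stats)
    zone = extract_iz(labels, stats, width=7)
    d_minus = 100 / area
    d_plus = 25 / area
    expected = (d_minus + 1.0) / (d_plus + 1.0)
    assert immunodrop(zone, stats) == pytest.approx(expected, rel=1e-12)
    # with the pseudocount suppressed the ratio is exactly 4
    assert immunodrop(zone, stats, eps=0.0) == pytest.approx(4.0)


def test_mirror_swap_negates_cm_and_reciprocates_immunodrop():
    # linear density ramp across an 8-tile line; swapping compartments
    # reverses the profile up to the one-rank shift of the edge convention
    counts = [100 + 10 * t for t in range(8)]
    stats = line_stats(counts, n_stroma_tiles=4)
    labels = label_tiles(stats)
    zone = extract_iz(labels, stats, width=7)
    cm, _ = center_of_mass(zone, stats)
    idrop = immunodrop(zone, stats)

    swapped = planted_stats(
        {
            (q, 4): {
                "cls": "tumor" if q < 4 else "stroma",
                "n": 20,
                "cd8": counts[q],
            }
            for q in range(8)
        },
        grid=FINE,
    )
    labels_s = label_tiles(swapped)
    zone_s = extract_iz(labels_s, swapped, width=7)
    cm_s, _ = center_of_mass(zone_s, swapped)
    idrop_s = immunodrop(zone_s, swapped)
    assert abs(cm_s + cm) < 0.05
    assert idrop_s * idrop == pytest.approx(1.0, abs=0.05)


# ------------------------------------------------- simulated slide recovery


def test_poisson_profile_recovery():
    """Per-rank densities on a simulated half-plane slide recover the
    planted plateau-transition-plateau intensity within 3 SE."""
    cfg = SlideSimConfig(
        extent_mm=(2.0, 2.0),
        lambda_tumor=1500.0,
        lambda_stroma=1500.0,
        cd8=CD8GradientSpec(stroma_density=600.0, tumor_density=150.0,
                            transition_um=200.0),
        seed=11,
    )
    cells, truth = simulate_slide(cfg)
    stats = apply_sampling_filter(
        assign_cells(cells, HexGridSpec(side_um=65.0)), min_cells=5
    )
    labels = label_tiles(stats)
    zone = extract_iz(labels, stats, width=7)
    prof = density_profile(zone, stats)
    area = stats.grid.area_mm2
    # plateau ranks +/-3 sit beyond the transition half-width
    for rank, planted in ((-3, 600.0), (3, 150.0)):
        pos = list(prof.ranks).index(rank)
        n = prof.n_tiles[pos]
        se = np.sqrt(planted / area / n)  # Poisson SE of a mean tile density
        assert abs(prof.mean_density[pos] - planted) < 3 * se
    # stroma-retained pattern: immunodrop > 1 and CM < 0
    assert immunodrop(zone, stats) > 1.0
    cm, _ = center_of_mass(zone, stats)
    assert cm < 0


def test_indicator_bundle_keys():
    cfg = SlideSimConfig(extent_mm=(1.2, 1.2), seed=5)
    cells, _ = simulate_slide(cfg)
    stats = apply_sampling_filter(
        assign_cells(cells, HexGridSpec(side_um=65.0)), min_cells=5
    )
    out = immunogradient_indicators(stats)
    assert set(out) == {
        "CD8_d_S", "CD8_d_S_sd", "CD8_d_TE", "CD8_d_TE_sd",
        "CD8_d_T", "CD8_d_T_sd", "CD8_CM", "CD8_CM_sd", "CD8_ID",
    }
    assert all(np.isfinite(v) for v in out.values())
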