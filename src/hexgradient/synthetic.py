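"""Synthetic virtual slides and cohorts with known ground truth.

Real whole-slide-image cohorts for this kind of analysis are rarely
shareable, so the generator emulates the data structure the pipeline
consumes: a tumor/stroma spatial partition, Poisson cell placement per
compartment, spatially structured marker-positivity fields (uniform, patchy,
bimodal), a HER2 membrane-completeness field, CD8 cells placed with an
intensity that depends on the signed distance to the tumor boundary
(plateau in the stroma, plateau in the tumor, linear transition), and
survival times from an exponential proportional-hazards model tied to the
indicators the pipeline itself computes.

Every fixture carries its planted ground truth so tests can check recovery
rather than regression against opaque numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from hexgradient.cell_io import CellTable, write_cell_table
from hexgradient.errors import ParameterError
from hexgradient.hexgrid import HexGridSpec, apply_sampling_filter, assign_cells
from hexgradient.immunogradient import immunogradient_indicators

#: refuse slides whose expected cell count exceeds this (desk-scale guard)
MAX_EXPECTED_CELLS = 5_000_000


@dataclass
class MarkerField:
    """Spatial positivity field for one nuclear marker.

    kind='uniform': every tumor cell positive with probability ``p``.
    kind='patchy': the slide is divided into square patches of side
    ``patch_mm``; each patch draws its own positivity from
    Uniform(p_low, p_high).
    kind='bimodal': per patch, positivity is ``p_high`` with probability
    ``mixing`` and ``p_low`` otherwise (two spatially segregated expression
    modes).
    """

    kind: str = "uniform"
    p: float = 0.3
    p_low: float = 0.1
    p_high: float = 0.9
    mixing: float = 0.5
    patch_mm: float = 0.6

    @property
    def expected_rate(self) -> float:
        if self.kind == "uniform":
            return self.p
        if self.kind == "patchy":
            return (self.p_low + self.p_high) / 2.0
        return self.mixing * self.p_high + (1 - self.mixing) * self.p_low


@dataclass
class CD8GradientSpec:
    """CD8 intensity as a function of signed distance to the tumor boundary
    (positive into the tumor).

    mode='linear' (default): ``stroma_density`` for d <= -w/2,
    ``tumor_density`` for d >= +w/2, linear in between (w = transition_um).
    ``edge_sd`` adds patchwise lognormal density modulation (SD of log)
    everywhere, emulating heterogeneous infiltration.

    mode='bands': piecewise-constant per hexagon-column band of width
    ``band_pitch_um`` (the fine-grid column pitch): ``stroma_density`` on all
    stroma-side bands, ``te_density`` on the tumor-edge band (d in
    (0, pitch)), ``tumor_density`` on all deeper tumor bands.  This decouples
    the tumor-aspect level from the edge level, so edge variability can be
    planted without moving the edge's Poisson noise floor.
    ``te_mod_amplitude`` A > 0 multiplies the edge band patchwise by the
    mean-preserving two-point factor {1-A, 1+A} (patch side
    ``te_mod_patch_mm``), planting high density variance along the tumor
    edge."""

    stroma_density: float = 300.0  # cells/mm^2
    tumor_density: float = 300.0
    transition_um: float = 300.0
    edge_sd: float = 0.0
    edge_patch_mm: float = 0.4
    mode: str = "linear"
    te_density: float | None = None
    band_pitch_um: float = 97.5
    te_mod_amplitude: float = 0.0
    te_mod_patch_mm: float = 0.12


@dataclass
class SlideSimConfig:
    """Everything needed to generate one virtual slide reproducibly."""

    extent_mm: tuple[float, float] = (2.0, 2.0)
    geometry: str = "half_plane"  # 'half_plane' | 'disks' | 'blob'
    boundary_frac: float = 0.5  # half_plane: tumor where x <= frac * width
    n_disks: int = 3
    disk_radius_mm: tuple[float, float] = (0.3, 0.5)
    blob_scale_mm: float = 0.5
    lambda_tumor: float = 2000.0  # cells/mm^2
    lambda_stroma: float = 1500.0
    markers: dict[str, MarkerField] = field(default_factory=dict)
    her2: MarkerField | None = None
    mc_mean: float = 50.0
    mc_sd: float = 15.0
    mc_patch_mm: float = 0.6
    mc_patch_sd: float = 0.0  # SD of per-patch mean shifts
    cd8: CD8GradientSpec = field(default_factory=CD8GradientSpec)
    seed: int = 0
    slide_id: str = "sim"

    def __post_init__(self) -> None:
        if self.extent_mm[0] <= 0 or self.extent_mm[1] <= 0:
            raise ParameterError("slide extent must be positive")
        if self.lambda_tumor < 0 or self.lambda_stroma < 0:
            raise ParameterError("cell intensities must be nonnegative")


# ---------------------------------------------------------------- geometry


def _signed_distance_fn(config: SlideSimConfig, rng: np.random.Generator):
    """Return f(x_um, y_um) -> signed distance to the tumor boundary in um
    (positive inside the tumor), plus a geometry-truth dict."""
    w_um = config.extent_mm[0] * 1000.0
    h_um = config.extent_mm[1] * 1000.0
    if config.geometry == "half_plane":
        bx = config.boundary_frac * w_um

        def sdist(x, y):
            return bx - np.asarray(x, dtype=float)

        return sdist, {"geometry": "half_plane", "boundary_x_um": bx}
    if config.geometry == "disks":
        r_lo, r_hi = (r * 1000.0 for r in config.disk_radius_mm)
        radii = rng.uniform(r_lo, r_hi, size=config.n_disks)
        # rejection placement keeping disks separated (signed distance exact)
        centers = []
        for k in range(config.n_disks):
            for _ in range(200):
                c = rng.uniform([radii[k], radii[k]], [w_um - radii[k], h_um - radii[k]])
                if all(
                    np.hypot(*(c - c2)) > radii[k] + r2 + 50.0
                    for c2, r2 in zip(centers, radii)
                ):
                    centers.append(c)
                    break
            else:
                centers.append(rng.uniform([r_lo, r_lo], [w_um - r_lo, h_um - r_lo]))
        centers = np.asarray(centers)

        def sdist(x, y):
            x = np.asarray(x, dtype=float)[:, None]
            y = np.asarray(y, dtype=float)[:, None]
            d = np.hypot(x - centers[None, :, 0], y - centers[None, :, 1])
            return (radii[None, :] - d).max(axis=1)

        return sdist, {
            "geometry": "disks",
            "centers_um": centers.tolist(),
            "radii_um": radii.tolist(),
        }
    if config.geometry == "blob":
        # thresholded smooth noise; signed distance by distance transform
        # on a 4-um raster (distance accurate to about the raster step)
        step = 4.0
        nx, ny = int(w_um / step), int(h_um / step)
        noise = rng.standard_normal((ny, nx))
        sigma = config.blob_scale_mm * 1000.0 / step
        smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
        mask = smooth > np.median(smooth)
        d_in = ndimage.distance_transform_edt(mask) * step
        d_out = ndimage.distance_transform_edt(~mask) * step
        sd_grid = np.where(mask, d_in, -d_out)

        def sdist(x, y):
            ix = np.clip((np.asarray(x) / step).astype(int), 0, nx - 1)
            iy = np.clip((np.asarray(y) / step).astype(int), 0, ny - 1)
            return sd_grid[iy, ix]

        return sdist, {"geometry": "blob", "tumor_fraction": float(mask.mean())}
    raise ParameterError(f"unknown geometry {config.geometry!r}")


def _poisson_points(
    rng: np.random.Generator, intensity: float, w_um: float, h_um: float
) -> tuple[np.ndarray, np.ndarray]:
    """Homogeneous Poisson point process over the full extent."""
    area_mm2 = (w_um / 1000.0) * (h_um / 1000.0)
    n = rng.poisson(intensity * area_mm2)
    return rng.uniform(0, w_um, n), rng.uniform(0, h_um, n)


def _patch_values(
    rng: np.random.Generator, w_um: float, h_um: float, patch_mm: float, draw
) -> tuple[np.ndarray, float]:
    """Lattice of square patches with independently drawn per-patch values."""
    patch_um = max(patch_mm * 1000.0, 1.0)
    nx = int(np.ceil(w_um / patch_um))
    ny = int(np.ceil(h_um / patch_um))
    return draw(rng, (ny, nx)), patch_um


def _field_probability(
    field_spec: MarkerField, x: np.ndarray, y: np.ndarray,
    w_um: float, h_um: float, rng: np.random.Generator,
) -> np.ndarray:
    if field_spec.kind == "uniform":
        return np.full(len(x), field_spec.p)
    if field_spec.kind == "patchy":
        grid, patch_um = _patch_values(
            rng, w_um, h_um, field_spec.patch_mm,
            lambda r, shape: r.uniform(field_spec.p_low, field_spec.p_high, shape),
        )
    elif field_spec.kind == "bimodal":
        grid, patch_um = _patch_values(
            rng, w_um, h_um, field_spec.patch_mm,
            lambda r, shape: np.where(
                r.random(shape) < field_spec.mixing, field_spec.p_high, field_spec.p_low
            ),
        )
    else:
        raise ParameterError(f"unknown marker field kind {field_spec.kind!r}")
    ix = np.clip((x / patch_um).astype(int), 0, grid.shape[1] - 1)
    iy = np.clip((y / patch_um).astype(int), 0, grid.shape[0] - 1)
    return grid[iy, ix]


# ---------------------------------------------------------------- slides


def simulate_slide(config: SlideSimConfig) -> tuple[CellTable, dict]:
    """Generate one virtual slide and its ground truth.

    Tumor and stroma cells are independent homogeneous Poisson processes
    restricted to their compartments; marker flags are Bernoulli draws from
    the configured field at each cell position; CD8 cells are an
    inhomogeneous Poisson process with intensity g(signed distance to the
    tumor boundary).  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    w_um = config.extent_mm[0] * 1000.0
    h_um = config.extent_mm[1] * 1000.0
    area = (w_um / 1000.0) * (h_um / 1000.0)
    levels = [config.cd8.stroma_density, config.cd8.tumor_density]
    if config.cd8.mode == "bands" and config.cd8.te_density is not None:
        levels.append(config.cd8.te_density)
    cd8_max = max(levels) * float(np.exp(2.5 * config.cd8.edge_sd))
    cd8_max *= 1.0 + config.cd8.te_mod_amplitude
    expected = (config.lambda_tumor + config.lambda_stroma + cd8_max) * area
    if expected > MAX_EXPECTED_CELLS:
        raise ParameterError(
            f"expected cell count {expected:.0f} exceeds guard {MAX_EXPECTED_CELLS}"
        )
    sdist, geo_truth = _signed_distance_fn(config, rng)

    # compartment cells by thinning a full-extent Poisson process
    xt, yt = _poisson_points(rng, config.lambda_tumor, w_um, h_um)
    keep = sdist(xt, yt) > 0
    xt, yt = xt[keep], yt[keep]
    xs, ys = _poisson_points(rng, config.lambda_stroma, w_um, h_um)
    keep = sdist(xs, ys) <= 0
    xs, ys = xs[keep], ys[keep]

    # CD8 cells: inhomogeneous Poisson by thinning at the max intensity
    cd8_x = cd8_y = np.empty(0)
    if cd8_max > 0:
        cx, cy = _poisson_points(rng, cd8_max, w_um, h_um)
        d = sdist(cx, cy)
        g = _cd8_intensity(d, config.cd8)
        if config.cd8.edge_sd > 0:
            grid, patch_um = _patch_values(
                rng, w_um, h_um, config.cd8.edge_patch_mm,
                lambda r, shape: np.exp(
                    np.clip(config.cd8.edge_sd * r.standard_normal(shape), None, 2.5)
                    - config.cd8.edge_sd**2 / 2.0
                ),
            )
            ix = np.clip((cx / patch_um).astype(int), 0, grid.shape[1] - 1)
            iy = np.clip((cy / patch_um).astype(int), 0, grid.shape[0] - 1)
            g = g * grid[iy, ix]
        if config.cd8.mode == "bands" and config.cd8.te_mod_amplitude > 0:
            # mean-preserving two-point modulation of the tumor-edge band
            A = config.cd8.te_mod_amplitude
            grid, patch_um = _patch_values(
                rng, w_um, h_um, config.cd8.te_mod_patch_mm,
                lambda r, shape: np.where(r.random(shape) < 0.5, 1.0 - A, 1.0 + A),
            )
            in_te = np.floor(d / config.cd8.band_pitch_um) == 0
            ix = np.clip((cx / patch_um).astype(int), 0, grid.shape[1] - 1)
            iy = np.clip((cy / patch_um).astype(int), 0, grid.shape[0] - 1)
            g = np.where(in_te, g * grid[iy, ix], g)
        keep = rng.random(len(cx)) < g / cd8_max
        cd8_x, cd8_y = cx[keep], cy[keep]
    n_cd8 = len(cd8_x)

    x = np.concatenate([xt, xs, cd8_x])
    y = np.concatenate([yt, ys, cd8_y])
    tissue = np.concatenate(
        [
            np.repeat("tumor", len(xt)),
            np.repeat("stroma", len(xs)),
            np.where(sdist(cd8_x, cd8_y) > 0, "tumor", "stroma"),
        ]
    ).astype(object)
    cd8_flag = np.zeros(len(x), dtype=np.int8)
    cd8_flag[len(xt) + len(xs):] = 1
    tumor_mask = tissue == "tumor"
    n_tum = int(tumor_mask.sum())
    tx, ty = x[tumor_mask], y[tumor_mask]

    # marker fields evaluated at every tumor cell (CD8-carrying included),
    # so the realized positivity matches the planted rate
    truth: dict = {"seed": config.seed, **geo_truth, "marker_rates": {}}
    flag_cols = {
        "er_pos": np.zeros(len(x), dtype=np.int8),
        "pr_pos": np.zeros(len(x), dtype=np.int8),
        "ki67_pos": np.zeros(len(x), dtype=np.int8),
    }
    for name, spec in (config.markers or {}).items():
        p = _field_probability(spec, tx, ty, w_um, h_um, rng)
        col = {"ER": "er_pos", "PR": "pr_pos", "Ki67": "ki67_pos"}[name]
        flag_cols[col][tumor_mask] = (rng.random(n_tum) < p).astype(np.int8)
        truth["marker_rates"][name] = spec.expected_rate
        truth.setdefault("marker_regimes", {})[name] = spec.kind

    her2_class = np.full(len(x), np.nan)
    mc = np.full(len(x), np.nan)
    if config.her2 is not None:
        p = _field_probability(config.her2, tx, ty, w_um, h_um, rng)
        pos = rng.random(n_tum) < p
        her2_class[tumor_mask] = np.where(
            pos, rng.integers(2, 4, n_tum), rng.integers(0, 2, n_tum)
        )
        truth["marker_rates"]["HER2"] = config.her2.expected_rate
        truth.setdefault("marker_regimes", {})["HER2"] = config.her2.kind
        # membrane completeness: patchwise mean + cell-level noise
        grid, patch_um = _patch_values(
            rng, w_um, h_um, config.mc_patch_mm,
            lambda r, shape: config.mc_mean + config.mc_patch_sd * r.standard_normal(shape),
        )
        ix = np.clip((tx / patch_um).astype(int), 0, grid.shape[1] - 1)
        iy = np.clip((ty / patch_um).astype(int), 0, grid.shape[0] - 1)
        mc[tumor_mask] = np.clip(
            grid[iy, ix] + config.mc_sd * rng.standard_normal(n_tum), 0.0, 100.0
        )
        truth["mc_mean"] = config.mc_mean

    df = pd.DataFrame(
        {
            "slide_id": config.slide_id,
            "x_um": x,
            "y_um": y,
            "tissue_class": tissue,
            "er_pos": flag_cols["er_pos"],
            "pr_pos": flag_cols["pr_pos"],
            "ki67_pos": flag_cols["ki67_pos"],
            "cd8_pos": cd8_flag,
            "her2_class": her2_class,
            "her2_mc_pct": mc,
        }
    )
    truth["cd8"] = {
        "mode": config.cd8.mode,
        "stroma_density": config.cd8.stroma_density,
        "tumor_density": config.cd8.tumor_density,
        "te_density": config.cd8.te_density,
        "transition_um": config.cd8.transition_um,
        "edge_sd": config.cd8.edge_sd,
        "te_mod_amplitude": config.cd8.te_mod_amplitude,
        "gradient_sign": int(
            np.sign(config.cd8.tumor_density - config.cd8.stroma_density)
        ),
    }
    truth["n_cells"] = int(len(df))
    return CellTable.from_dataframe(df, slide_id=config.slide_id), truth


def _cd8_intensity(d_um: np.ndarray, spec: CD8GradientSpec) -> np.ndarray:
    """CD8 intensity over signed distance (plateau-transition-plateau, or
    per-band piecewise constant in 'bands' mode)."""
    d = np.asarray(d_um, dtype=float)
    if spec.mode == "bands":
        band = np.floor(d / spec.band_pitch_um)
        te = spec.te_density if spec.te_density is not None else (
            (spec.stroma_density + spec.tumor_density) / 2.0
        )
        return np.where(
            band < 0, spec.stroma_density, np.where(band == 0, te, spec.tumor_density)
        )
    half = spec.transition_um / 2.0
    frac = np.clip((d + half) / (2 * half), 0.0, 1.0)
    return spec.stroma_density + frac * (spec.tumor_density - spec.stroma_density)


# ---------------------------------------------------------------- cohorts


def _default_indicators(cells: CellTable, fine_side_um: float = 65.0) -> dict[str, float]:
    """Fine-grid Immunogradient indicators plus whole-slide compartment CD8
    densities (the default hazard covariates)."""
    stats = apply_sampling_filter(
        assign_cells(cells, HexGridSpec(side_um=fine_side_um)), min_cells=5
    )
    out = immunogradient_indicators(stats)
    ret = stats.tiles[stats.tiles["retained"]]
    area = stats.grid.area_mm2
    df = cells.df
    for cls in ("tumor", "stroma"):
        frac = np.where(ret["n_total"] > 0, ret[f"n_{cls}"] / ret["n_total"], 0.0)
        cls_area = float((area * frac).sum())
        cls_cd8 = int(((df["tissue_class"] == cls) & (df["cd8_pos"] == 1)).sum())
        out[f"CD8_density_{cls}"] = cls_cd8 / cls_area if cls_area > 0 else float("nan")
    return out


def simulate_cohort(
    n_patients: int,
    slide_config_fn,
    hazard: dict,
    censoring: tuple[float, float] = (12.0, 120.0),
    seed: int = 0,
    indicator_fn=_default_indicators,
) -> tuple[pd.DataFrame, dict]:
    """Generate a cohort of virtual slides with survival tied to computed
    indicators.

    ``slide_config_fn(i, rng)`` returns the SlideSimConfig for patient i (its
    ``seed`` is overwritten with a per-slide stream derived from ``seed``).
    ``hazard`` is ``{"baseline": h0 per month, "coefficients": {name: beta}}``;
    the linear predictor uses cohort-standardized indicator values, survival
    times are exponential with rate h0*exp(beta.z), and censoring is uniform
    over the given window (months).
    """
    master = np.random.default_rng(seed)
    records = []
    for i in range(n_patients):
        cfg = slide_config_fn(i, master)
        cfg.seed = int(np.random.default_rng([seed, i]).integers(2**31 - 1))
        cfg.slide_id = f"P{i:04d}"
        cells, truth = simulate_slide(cfg)
        rec = {"patient_id": f"P{i:04d}", "slide_id": cfg.slide_id}
        rec.update(indicator_fn(cells))
        rec["_truth_gradient_sign"] = truth["cd8"]["gradient_sign"]
        records.append(rec)
    frame = pd.DataFrame(records)

    coeffs = hazard.get("coefficients", {})
    z = np.zeros(n_patients)
    for name, beta in coeffs.items():
        v = frame[name].to_numpy(dtype=float)
        sd = v.std()
        z = z + beta * (v - v.mean()) / (sd if sd > 0 else 1.0)
    rate = hazard.get("baseline", 0.01) * np.exp(z)
    t_event = master.exponential(1.0 / rate)
    t_cens = master.uniform(censoring[0], censoring[1], n_patients)
    frame["followup_months"] = np.minimum(t_event, t_cens)
    frame["death"] = (t_event <= t_cens).astype(int)
    truth_out = {
        "baseline": hazard.get("baseline", 0.01),
        "coefficients": dict(coeffs),
        "censoring": list(censoring),
        "event_fraction": float(frame["death"].mean()),
    }
    return frame, truth_out


#: per-score exponential hazards (per month) for the score-ordered cohort;
#: chosen so 5-year survival is roughly 0.97 / 0.80 / 0.50 for scores 3/2/1
SCORE_HAZARDS = {3: 0.0005, 2: 0.0037, 1: 0.0116}


def score_ordered_cohort(
    n_patients: int = 300,
    seed: int = 0,
    extent_mm: tuple[float, float] = (1.2, 1.2),
    base_density: float = 1500.0,
) -> tuple[pd.DataFrame, dict]:
    """Cohort whose hazard decreases in a planted 3-component score.

    Each patient is assigned a planted score in {1, 2, 3}: the number of
    favorable CD8 spatial features (inward gradient for CM, high tumor-aspect
    density for d_T, homogeneous edge for low d_TE_sd).  The slide's CD8
    field uses the per-band profile with a FIXED tumor-edge level for every
    patient, so the edge's Poisson noise floor is identical across the
    cohort and planted edge modulation is the only source of extra edge
    variance; stroma/tumor plateau levels encode the CM and d_T regimes
    independently of the edge.  Indicators are then computed by the pipeline
    and survival times follow score-ordered exponential hazards.
    """
    rng = np.random.default_rng(seed)
    # planted regimes: (cm favorable, d_T favorable, d_TE_sd favorable)
    combos = {
        3: [(True, True, True)],
        2: [(False, True, True), (True, True, False), (True, False, True)],
        1: [(False, True, False), (True, False, False), (False, False, True)],
    }
    te_level = 800.0
    # boundary on a column midpoint of the fine grid, so tile labels are clean
    pitch = 97.5
    boundary_frac = (5.5 * pitch) / (extent_mm[0] * 1000.0)
    records = []
    for i in range(n_patients):
        planted = int(rng.integers(1, 4))
        cm_f, dt_f, sd_f = combos[planted][int(rng.integers(len(combos[planted])))]
        t_plateau = 800.0 if dt_f else 150.0
        s_plateau = t_plateau / 4.0 if cm_f else t_plateau * 2.5
        cfg = SlideSimConfig(
            extent_mm=extent_mm,
            boundary_frac=boundary_frac,
            lambda_tumor=base_density,
            lambda_stroma=base_density,
            cd8=CD8GradientSpec(
                mode="bands",
                stroma_density=s_plateau,
                tumor_density=t_plateau,
                te_density=te_level,
                band_pitch_um=pitch,
                te_mod_amplitude=0.0 if sd_f else 0.9,
            ),
            seed=int(np.random.default_rng([seed, i]).integers(2**31 - 1)),
            slide_id=f"P{i:04d}",
        )
        cells, _ = simulate_slide(cfg)
        rec = {"patient_id": f"P{i:04d}", "slide_id": cfg.slide_id,
               "planted_score": planted}
        rec.update(_default_indicators(cells))
        records.append(rec)
    frame = pd.DataFrame(records)
    h = np.array([SCORE_HAZARDS[s] for s in frame["planted_score"]])
    t_event = rng.exponential(1.0 / h)
    t_cens = rng.uniform(60.0, 120.0, n_patients)
    frame["followup_months"] = np.minimum(t_event, t_cens)
    frame["death"] = (t_event <= t_cens).astype(int)
    truth = {"hazards_by_score": dict(SCORE_HAZARDS), "n_patients": n_patients}
    return frame, truth


# ---------------------------------------------------------------- fixtures


def planted_tile_counts_table(
    grid: HexGridSpec,
    tile_counts: dict[tuple[int, int], int],
    seed: int = 0,
    slide_id: str = "sparse",
) -> CellTable:
    """Cell table with exactly the requested number of cells per hexagon.

    Cells are jittered uniformly within 0.4 side lengths of each tile
    center, guaranteeing assignment to the planted tile.  Used to plant
    sub-threshold tiles for sampling-filter tests.
    """
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for (q, r), n in tile_counts.items():
        cx, cy = grid.centers(np.array([q]), np.array([r]))
        rad = rng.uniform(0, 0.4 * grid.side_um, n)
        ang = rng.uniform(0, 2 * np.pi, n)
        xs.append(cx[0] + rad * np.cos(ang))
        ys.append(cy[0] + rad * np.sin(ang))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.min() < 0 or y.min() < 0:
        raise ParameterError(
            "planted tiles extend to negative coordinates; move the grid origin"
        )
    df = pd.DataFrame(
        {"slide_id": slide_id, "x_um": x, "y_um": y, "tissue_class": "tumor"}
    )
    return CellTable.from_dataframe(df, slide_id=slide_id)


def fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the named regression fixtures with their ground-truth JSON.

    Fixtures: uniform_marker, bimodal_marker, halfplane_gradient_up,
    halfplane_gradient_down, sparse_hexagons, score_ordered_cohort.
    Regeneration with the same seed is idempotent.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, cells: CellTable | None, truth: dict,
             frame: pd.DataFrame | None = None) -> None:
        d = out_dir / name
        d.mkdir(exist_ok=True)
        if cells is not None:
            write_cell_table(cells, d / "cells.csv")
        if frame is not None:
            frame.to_csv(d / "cohort.csv", index=False)
        (d / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
        written[name] = d

    # texture fixtures: larger tumor area so the coarse grid holds enough tiles;
    # uniform positivity 0.25 sits mid-interval (rank 3), away from rank edges
    tex_base = dict(extent_mm=(4.0, 4.0), boundary_frac=0.75,
                    lambda_tumor=2000.0, lambda_stroma=1500.0)
    cells, truth = simulate_slide(SlideSimConfig(
        **tex_base, markers={"ER": MarkerField(kind="uniform", p=0.25)},
        seed=seed, slide_id="uniform_marker",
    ))
    emit("uniform_marker", cells, truth)

    cells, truth = simulate_slide(SlideSimConfig(
        **tex_base,
        markers={"ER": MarkerField(kind="bimodal", p_low=0.15, p_high=0.85,
                                   mixing=0.5, patch_mm=0.6)},
        seed=seed + 1, slide_id="bimodal_marker",
    ))
    emit("bimodal_marker", cells, truth)

    base = dict(extent_mm=(2.0, 2.0), lambda_tumor=2000.0, lambda_stroma=1500.0)
    for name, (s_d, t_d) in {
        "halfplane_gradient_up": (200.0, 800.0),
        "halfplane_gradient_down": (800.0, 200.0),
    }.items():
        cells, truth = simulate_slide(SlideSimConfig(
            **base,
            cd8=CD8GradientSpec(stroma_density=s_d, tumor_density=t_d,
                                transition_um=300.0),
            seed=seed + 2, slide_id=name,
        ))
        emit(name, cells, truth)

    grid = HexGridSpec(side_um=257.0, origin=(600.0, 600.0))
    counts = {(0, 0): 40, (1, 0): 60, (0, 1): 40, (1, 1): 60, (2, 0): 49, (2, 1): 50}
    cells = planted_tile_counts_table(grid, counts, seed=seed, slide_id="sparse_hexagons")
    emit("sparse_hexagons", cells, {
        "tile_counts": {f"{q},{r}": n for (q, r), n in counts.items()},
        "n_below_50": sum(1 for n in counts.values() if n < 50),
        "grid_side_um": 257.0, "grid_origin_um": [600.0, 600.0],
    })

    frame, truth = score_ordered_cohort(n_patients=30, seed=seed)
    emit("score_ordered_cohort", None, truth, frame=frame)
    return written
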