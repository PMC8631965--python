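"""End-to-end orchestration: slide -> indicators -> cohort analyses.

``run_slide`` executes the coarse-grid texture stage and the fine-grid
Immunogradient stage on one cell table and emits a flat indicator record.
``run_cohort`` joins per-slide records with the patient table and runs the
survival stack: per-indicator optimal cutpoints, a univariate Cox table, a
multivariate model from a preset variable pool with leave-one-out subset
selection, and the combined CD8 Immunogradient prognostic score.

Model presets m1-m6 mirror the two-cohort structure of the original study
design: m1/m4 pathology + IHC + heterogeneity indicators (m4 adds FISH),
m2/m5 add the CD8 density and Immunogradient indicators, m3/m6 use pathology
and CD8 indicators only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from hexgradient.cell_io import CellTable
from hexgradient.errors import HexgradientError, ParameterError
from hexgradient.hexgrid import (
    HexGridSpec,
    apply_sampling_filter,
    assign_cells,
    slide_summary,
)
from hexgradient.immunogradient import immunogradient_indicators
from hexgradient.survival import (
    SCORE_DIRECTIONS,
    cox_fit,
    find_cutoff,
    immunogradient_score,
    loo_subset_select,
)
from hexgradient.texture import texture_profile

log = logging.getLogger("hexgradient")

TEXTURE_NAMES = ("contrast", "dissimilarity", "entropy", "energy", "homogeneity")

PATHOLOGY_VARS = ["pT_high", "pN_pos"]
IHC_VARS = ["ER_pct", "PR_pct", "Ki67_pct", "HER2_pct", "HER2_MC"]
FISH_VARS = ["cep17_copy_number"]
CD8_VARS = [
    "CD8_density_tumor",
    "CD8_density_stroma",
    "CD8_d_S",
    "CD8_d_S_sd",
    "CD8_d_TE",
    "CD8_d_TE_sd",
    "CD8_d_T",
    "CD8_d_T_sd",
    "CD8_CM",
    "CD8_CM_sd",
    "CD8_ID",
]


def _ith_vars(markers: tuple[str, ...]) -> list[str]:
    out = []
    for m in markers:
        out += [f"{m}_{t}" for t in TEXTURE_NAMES]
        out.append(f"{m}_AshD")
    return out


def model_preset_pool(preset: str, markers: tuple[str, ...]) -> list[str]:
    """Variable pool for a multivariate model preset (m1-m6)."""
    ith = _ith_vars(markers)
    pools = {
        "m1": PATHOLOGY_VARS + IHC_VARS + ith,
        "m2": PATHOLOGY_VARS + IHC_VARS + ith + CD8_VARS,
        "m3": PATHOLOGY_VARS + CD8_VARS,
        "m4": PATHOLOGY_VARS + IHC_VARS + ith + FISH_VARS,
        "m5": PATHOLOGY_VARS + IHC_VARS + ith + FISH_VARS + CD8_VARS,
        "m6": PATHOLOGY_VARS + CD8_VARS,
    }
    if preset not in pools:
        raise ParameterError(f"unknown model preset {preset!r}")
    return pools[preset]


@dataclass
class RunConfig:
    """Configuration of an end-to-end run."""

    ith_side_um: float = 257.0
    ith_min_cells: int = 50
    iz_side_um: float = 65.0
    iz_width: int = 7
    iz_min_cells: int = 5
    iz_tau: float = 0.5
    markers: tuple[str, ...] = ("ER", "PR", "Ki67", "HER2", "HER2_MC")
    model_preset: str = "m2"
    min_group_frac: float = 0.10
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_slide(config: RunConfig, cells: CellTable) -> dict:
    """Compute every slide-level indicator for one cell table.

    Stages that are undefined for the slide (e.g. no tumor-stroma interface,
    no rankable tiles for a marker) contribute explicit None values rather
    than aborting; the record always carries the full indicator name set.
    """
    rec: dict = {"slide_id": cells.slide_id}

    coarse = apply_sampling_filter(
        assign_cells(cells, HexGridSpec(side_um=config.ith_side_um)),
        min_cells=config.ith_min_cells,
    )
    n_retained = int(coarse.tiles["retained"].sum())
    log.info(
        "slide %s: %d coarse tiles (%d retained, %d excluded by %d-cell filter)",
        cells.slide_id, len(coarse), n_retained, len(coarse) - n_retained,
        config.ith_min_cells,
    )
    try:
        rec.update(slide_summary(coarse, cells))
    except HexgradientError as exc:
        log.warning("slide %s: summary undefined (%s)", cells.slide_id, exc)
        for k in IHC_VARS + ["CD8_density_tumor", "CD8_density_stroma"]:
            rec.setdefault(k, None)

    for marker in config.markers:
        try:
            prof = texture_profile(coarse, marker, seed=config.seed)
            rec.update({f"{marker}_{k}": v for k, v in prof.items()
                        if k not in ("ashman_d",)})
            rec[f"{marker}_AshD"] = prof["ashman_d"]
        except HexgradientError as exc:
            log.warning("slide %s: %s texture undefined (%s)", cells.slide_id, marker, exc)
            for t in TEXTURE_NAMES:
                rec[f"{marker}_{t}"] = None
            rec[f"{marker}_AshD"] = None

    fine = apply_sampling_filter(
        assign_cells(cells, HexGridSpec(side_um=config.iz_side_um)),
        min_cells=config.iz_min_cells,
    )
    try:
        rec.update(
            immunogradient_indicators(
                fine, width=config.iz_width, tau=config.iz_tau,
                min_cells=config.iz_min_cells,
            )
        )
    except HexgradientError as exc:
        log.warning("slide %s: IZ undefined (%s)", cells.slide_id, exc)
        for k in ("CD8_d_S", "CD8_d_S_sd", "CD8_d_TE", "CD8_d_TE_sd",
                  "CD8_d_T", "CD8_d_T_sd", "CD8_CM", "CD8_CM_sd", "CD8_ID"):
            rec[k] = None
    return rec


def _clinical_binaries(frame: pd.DataFrame) -> pd.DataFrame:
    """Dichotomize staging columns per the usual convention
    (pT1-2 vs pT3-4; pN0 vs pN1-3)."""
    frame = frame.copy()
    if "pT" in frame.columns:
        frame["pT_high"] = frame["pT"].astype(str).isin(("T3", "T4")).astype(int)
    if "pN" in frame.columns:
        frame["pN_pos"] = (
            frame["pN"].astype(str).isin(("N1", "N2", "N3")).astype(int)
        )
    return frame


def run_cohort(
    config: RunConfig,
    indicator_records: pd.DataFrame,
    cohort: pd.DataFrame,
) -> dict:
    """Cohort-level analysis bundle.

    Joins indicator records to the patient table on slide_id, finds the
    optimal cutpoint for every continuous variable of the preset pool,
    builds the univariate Cox table on the dichotomized variables, selects
    the multivariate model by leave-one-out concordance among the
    univariately significant variables, and computes the combined CD8
    Immunogradient prognostic score strata.

    Cutpoint-selected univariate p-values are selection-biased (minimum-p
    scan, uncorrected) and are labeled as such in the output.
    """
    if len(cohort) < 20:
        raise ParameterError("cohort analysis needs >= 20 patients")
    frame = cohort.merge(indicator_records, on="slide_id", how="left")
    frame = _clinical_binaries(frame)
    pool = model_preset_pool(config.model_preset, config.markers)
    missing_pool = [v for v in pool if v not in frame.columns]
    if missing_pool:
        raise ParameterError(
            f"preset {config.model_preset} requires missing indicators: {missing_pool}"
        )
    times = frame["followup_months"].to_numpy(dtype=float)
    events = frame["death"].to_numpy(dtype=int)

    cutpoints: dict[str, dict] = {}
    excluded_patients: dict[str, list[str]] = {}
    univariate_rows = []
    dichotomized = frame.copy()
    for var in pool:
        if var in ("pT_high", "pN_pos"):
            col = var
        else:
            vals = frame[var].to_numpy(dtype=float)
            n_miss = int((~np.isfinite(vals)).sum())
            if n_miss:
                excluded_patients[var] = (
                    frame.loc[~np.isfinite(vals), "patient_id"].astype(str).tolist()
                )
            try:
                cp = find_cutoff(vals, times, events,
                                 min_group_frac=config.min_group_frac)
            except HexgradientError as exc:
                log.warning("cutpoint for %s undefined (%s)", var, exc)
                continue
            cutpoints[var] = {
                "cutoff": cp.cutoff, "direction": cp.direction,
                "logrank_p_selection_biased": cp.p_value,
                "n_low": cp.n_low, "n_high": cp.n_high,
            }
            col = f"{var}_high"
            dichotomized[col] = (frame[var] > cp.cutoff).astype(float)
            dichotomized.loc[~np.isfinite(vals), col] = np.nan
        fit = cox_fit(dichotomized, [col])
        if fit["covariates"] is None:
            continue
        row = fit["covariates"].iloc[0]
        univariate_rows.append(
            {"variable": var, "covariate": col, "HR": row["HR"],
             "CI_low": row["CI_low"], "CI_high": row["CI_high"], "p": row["p"]}
        )
    univariate = pd.DataFrame(univariate_rows)

    candidates = (
        univariate.loc[univariate["p"] < 0.05, "covariate"].tolist()
        if len(univariate)
        else []
    )
    selection = loo_subset_select(dichotomized, candidates)

    score = None
    score_components = ["CD8_CM", "CD8_d_T", "CD8_d_TE_sd"]
    if all(c in cutpoints for c in score_components):
        score = immunogradient_score(
            dichotomized,
            {c: cutpoints[c]["cutoff"] for c in score_components},
            directions=SCORE_DIRECTIONS,
        )

    return {
        "config_hash": config.config_hash(),
        "n_patients": len(frame),
        "cutpoints": cutpoints,
        "univariate": univariate,
        "multivariate": selection,
        "score": score,
        "excluded_patients": excluded_patients,
        "frame": dichotomized,
    }
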