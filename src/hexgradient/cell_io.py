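"""Read, validate and write per-cell tables and patient cohort tables.

Cell tables are delimited text with one row per detected cell.  Coordinates
are micrometres with the origin in the top-left corner and y increasing
downward (scanner convention).  A *dialect* maps the semantic column names
used throughout the package to whatever headers a particular
digital-image-analysis export uses.

Canonical cell-table columns (in serialization order)::

    slide_id, x_um, y_um, tissue_class, er_pos, pr_pos, ki67_pos, cd8_pos,
    her2_class, her2_mc_pct

``tissue_class`` is one of ``tumor``, ``stroma``, ``background``.  Background
cells are retained on read but flagged non-analyzable.  ``her2_class`` is the
IHC intensity class 0/1/2/3 and ``her2_mc_pct`` the HER2 membrane-completeness
percentage; both are optional (CD8 slides carry no HER2 data) and
``her2_mc_pct`` is only valid on tumor cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from hexgradient.errors import EmptyInputError, SchemaError, ValidationError

TISSUE_CLASSES = ("tumor", "stroma", "background")

CELL_COLUMNS = (
    "slide_id",
    "x_um",
    "y_um",
    "tissue_class",
    "er_pos",
    "pr_pos",
    "ki67_pos",
    "cd8_pos",
    "her2_class",
    "her2_mc_pct",
)

#: semantic name -> (mandatory, kind)
_CELL_SCHEMA = {
    "x_um": (True, "coord"),
    "y_um": (True, "coord"),
    "tissue_class": (True, "class"),
    "slide_id": (False, "text"),
    "er_pos": (False, "flag"),
    "pr_pos": (False, "flag"),
    "ki67_pos": (False, "flag"),
    "cd8_pos": (False, "flag"),
    "her2_class": (False, "her2_class"),
    "her2_mc_pct": (False, "pct"),
}

MARKER_FLAGS = ("er_pos", "pr_pos", "ki67_pos", "cd8_pos")

COHORT_COLUMNS = (
    "patient_id",
    "slide_id",
    "followup_months",
    "death",
    "pT",
    "pN",
    "grade",
    "fish_group",
    "cep17_copy_number",
)

PT_LEVELS = ("T1", "T2", "T3", "T4")
PN_LEVELS = ("N0", "N1", "N2", "N3")
FISH_GROUPS = ("non_amplified", "amplified")


@dataclass
class CellTable:
    """A validated per-cell table for a single slide.

    Attributes
    ----------
    slide_id : str
        Identifier shared by all records.
    df : pandas.DataFrame
        One row per cell with the canonical columns.  ``analyzable`` is a
        derived boolean column, false for background-class cells.
    """

    slide_id: str
    df: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) extent in micrometres."""
        x = self.df["x_um"].to_numpy()
        y = self.df["y_um"].to_numpy()
        return float(x.min()), float(y.min()), float(x.max()), float(y.max())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, slide_id: str | None = None) -> "CellTable":
        """Validate a raw dataframe into a CellTable.

        Missing optional columns are filled with defaults (flags 0, HER2
        fields missing).  Raises :class:`ValidationError` on any invariant
        violation, :class:`EmptyInputError` on an empty table.
        """
        if len(df) == 0:
            raise EmptyInputError("cell table contains no rows")
        df = df.copy()
        if "slide_id" not in df.columns:
            df["slide_id"] = slide_id if slide_id is not None else "slide"
        df["slide_id"] = df["slide_id"].astype(str)
        sids = df["slide_id"].unique()
        if len(sids) > 1:
            raise ValidationError(f"multiple slide_ids in one table: {sorted(sids)}")
        sid = str(sids[0])

        for col in ("x_um", "y_um"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() | ~np.isfinite(vals)
            if bad.any():
                line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
                raise ValidationError(f"non-numeric or non-finite {col} at line {line}")
            if (vals < 0).any():
                raise ValidationError(f"negative coordinate in column {col}")
            df[col] = vals.astype(float)

        cls_vals = df["tissue_class"].astype(str).str.strip().str.lower()
        unknown = set(cls_vals.unique()) - set(TISSUE_CLASSES)
        if unknown:
            raise ValidationError(f"unknown tissue_class values: {sorted(unknown)}")
        df["tissue_class"] = cls_vals

        for flag in MARKER_FLAGS:
            if flag not in df.columns:
                df[flag] = 0
            vals = pd.to_numeric(df[flag], errors="coerce").fillna(0)
            if not vals.isin((0, 1)).all():
                raise ValidationError(f"{flag} must be exactly 0 or 1")
            df[flag] = vals.astype(np.int8)

        if "her2_class" not in df.columns:
            df["her2_class"] = np.nan
        h2 = pd.to_numeric(df["her2_class"], errors="coerce")
        present = h2.notna()
        if present.any() and not h2[present].isin((0, 1, 2, 3)).all():
            raise ValidationError("her2_class must be in {0,1,2,3}")
        df["her2_class"] = h2.astype(float)

        if "her2_mc_pct" not in df.columns:
            df["her2_mc_pct"] = np.nan
        mc = pd.to_numeric(df["her2_mc_pct"], errors="coerce")
        present = mc.notna()
        if present.any():
            if ((mc[present] < 0) | (mc[present] > 100)).any():
                raise ValidationError("her2_mc_pct outside [0,100]")
            if (df.loc[present, "tissue_class"] != "tumor").any():
                raise ValidationError("her2_mc_pct present on non-tumor cell")
        df["her2_mc_pct"] = mc.astype(float)

        df["analyzable"] = df["tissue_class"] != "background"
        df = df[[*CELL_COLUMNS, "analyzable"]].reset_index(drop=True)
        return cls(slide_id=sid, df=df)


def read_cell_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> CellTable:
    """Read a delimited cell table (comma or tab, header row) into a
    validated :class:`CellTable`.

    Parameters
    ----------
    dialect : mapping, optional
        Maps semantic column names (``x_um``, ``y_um``, ``tissue_class``,
        marker flags, ...) to the header names used in the file.  Omitted
        semantic names are looked up under their canonical name.

    Raises
    ------
    SchemaError
        If a mandatory column is absent (the message names the column).
    ValidationError
        On row-level content errors (with a line number where possible).
    EmptyInputError
        If the file has no data rows.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if raw.empty and len(raw.columns) == 0:
        raise EmptyInputError(f"{path}: empty file")
    dialect = dict(dialect or {})
    rename: dict[str, str] = {}
    for semantic, (mandatory, _) in _CELL_SCHEMA.items():
        header = dialect.get(semantic, semantic)
        if header in raw.columns:
            rename[header] = semantic
        elif mandatory:
            raise SchemaError(f"{path}: missing mandatory column '{header}' ({semantic})")
    df = raw.rename(columns=rename)
    df = df[[c for c in CELL_COLUMNS if c in df.columns]]
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")
    return CellTable.from_dataframe(df, slide_id=path.stem)


def write_cell_table(table: CellTable, path: str | Path) -> Path:
    """Write a validated CellTable as UTF-8 CSV in canonical column order.

    Coordinates are written with 6 decimals; missing optional values are
    written as empty strings (never the text "NaN").
    """
    path = Path(path)
    out = table.df[list(CELL_COLUMNS)].copy()
    for col in ("x_um", "y_um"):
        out[col] = out[col].map(lambda v: f"{v:.6f}")
    out["her2_class"] = out["her2_class"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    out["her2_mc_pct"] = out["her2_mc_pct"].map(
        lambda v: "" if pd.isna(v) else f"{v:.6g}"
    )
    out.to_csv(path, index=False, encoding="utf-8")
    return path


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a patient cohort table.

    One row per patient: patient_id, slide_id, followup_months, death,
    pT, pN, grade, fish_group, cep17_copy_number (optional).

    Raises ValidationError on duplicate patient ids, death flags outside
    {0,1}, or non-positive follow-up.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")
    missing = [c for c in ("patient_id", "followup_months", "death") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    return validate_cohort(df)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory cohort frame (same rules as read_cohort_table)."""
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    dup = df["patient_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate patient_id: {sorted(df.loc[dup, 'patient_id'].unique())}"
        )
    fu = pd.to_numeric(df["followup_months"], errors="coerce")
    if fu.isna().any() or (fu <= 0).any():
        raise ValidationError("followup_months must be positive for analyzable records")
    df["followup_months"] = fu.astype(float)
    death = pd.to_numeric(df["death"], errors="coerce")
    if death.isna().any() or not death.isin((0, 1)).all():
        raise ValidationError("death flag must be 0 or 1")
    df["death"] = death.astype(np.int8)
    if "pT" in df.columns:
        bad = set(df["pT"].dropna().astype(str)) - set(PT_LEVELS)
        if bad:
            raise ValidationError(f"unknown pT levels: {sorted(bad)}")
    if "pN" in df.columns:
        bad = set(df["pN"].dropna().astype(str)) - set(PN_LEVELS)
        if bad:
            raise ValidationError(f"unknown pN levels: {sorted(bad)}")
    if "grade" in df.columns:
        g = pd.to_numeric(df["grade"], errors="coerce")
        if not g.dropna().isin((1, 2, 3)).all():
            raise ValidationError("grade must be 1, 2 or 3")
    if "fish_group" in df.columns:
        bad = set(df["fish_group"].dropna().astype(str)) - set(FISH_GROUPS)
        if bad:
            raise ValidationError(f"unknown fish_group: {sorted(bad)}")
    if "cep17_copy_number" in df.columns:
        c17 = pd.to_numeric(df["cep17_copy_number"], errors="coerce")
        if (c17.dropna() <= 0).any():
            raise ValidationError("cep17_copy_number must be positive")
    return df.reset_index(drop=True)


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a cohort frame as UTF-8 CSV, canonical columns first."""
    path = Path(path)
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False, encoding="utf-8")
    return path
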