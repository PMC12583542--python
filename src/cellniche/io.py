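"""Tabular data model: loading, validation, writing and spot-level QC.

The pipeline is image-free: a cohort is three tab-delimited tables.

``cells.tsv``    one row per detected cell —
    patient_id, spot_id, x_um, y_um, compartment, and one 0/1 column per
    marker in :data:`cellniche.markers.MARKERS`.
``spots.tsv``    one row per TMA spot —
    patient_id, spot_id, aligned_area_mm2 (QC-passing tissue area),
    tumor_area_mm2 (carcinoma + stroma area), qc_pass.
``patients.tsv`` one row per patient —
    patient_id, center (A/B), subtype (LUAD/LUSC/other), uicc8 (1-4),
    r_status (0/1/unknown), adjuvant (0/1), os_months, event.

Coordinates are spot-local micrometers with the origin at the disk center.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .markers import COMPARTMENTS, MARKERS

CELL_COLUMNS = ["patient_id", "spot_id", "x_um", "y_um", "compartment", *MARKERS]
SPOT_COLUMNS = ["patient_id", "spot_id", "aligned_area_mm2", "tumor_area_mm2", "qc_pass"]
PATIENT_COLUMNS = [
    "patient_id",
    "center",
    "subtype",
    "uicc8",
    "r_status",
    "adjuvant",
    "os_months",
    "event",
]

#: Spot-level aligned-area acceptance window in mm^2. Spots below carry too
#: little well-registered tissue; spots above are shattered into shards that
#: distort spatial statistics. Bounds are inclusive: a spot at exactly the
#: bound passes.
QC_MIN_AREA_MM2 = 0.7
QC_MAX_AREA_MM2 = 3.0


class SchemaError(ValueError):
    """A table violates the documented schema or referential integrity."""


@dataclass
class Dataset:
    """A validated cohort: cells, spots and patients with intact references."""

    cells: pd.DataFrame
    spots: pd.DataFrame
    patients: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the three tables as TSV; returns the written paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [("cells", self.cells), ("spots", self.spots), ("patients", self.patients)]:
            p = out / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            paths[name] = p
        return paths


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {missing}")


def _coerce_bool(series: pd.Series, table: str, column: str) -> pd.Series:
    mapping = {
        "0": 0, "1": 1, 0: 0, 1: 1, False: 0, True: 1,
        "false": 0, "true": 1, "False": 0, "True": 1, 0.0: 0, 1.0: 1,
    }
    out = series.map(mapping)
    if out.isna().any():
        row = int(series.index[out.isna()][0])
        raise SchemaError(f"{table}: non-boolean value in column {column!r} at row {row}")
    return out.astype(np.int8)


def validate_cells(cells: pd.DataFrame) -> pd.DataFrame:
    _require_columns(cells, CELL_COLUMNS, "cells")
    cells = cells.copy()
    for coord in ("x_um", "y_um"):
        vals = pd.to_numeric(cells[coord], errors="coerce")
        if not np.isfinite(vals.to_numpy(dtype=float)).all():
            row = int(cells.index[~np.isfinite(vals.to_numpy(dtype=float))][0])
            raise SchemaError(f"cells: non-finite {coord} at row {row}")
        cells[coord] = vals.astype(float)
    bad = ~cells["compartment"].isin(COMPARTMENTS)
    if bad.any():
        raise SchemaError(
            f"cells: unknown compartment {cells.loc[bad, 'compartment'].iloc[0]!r} "
            f"at row {int(cells.index[bad][0])}"
        )
    for m in MARKERS:
        cells[m] = _coerce_bool(cells[m], "cells", m)
    return cells


def validate_spots(spots: pd.DataFrame) -> pd.DataFrame:
    _require_columns(spots, SPOT_COLUMNS, "spots")
    spots = spots.copy()
    for col in ("aligned_area_mm2", "tumor_area_mm2"):
        spots[col] = pd.to_numeric(spots[col], errors="coerce").astype(float)
        if spots[col].isna().any() or (spots[col] < 0).any():
            raise SchemaError(f"spots: negative or missing {col}")
    if (spots["tumor_area_mm2"] > spots["aligned_area_mm2"] + 1e-12).any():
        raise SchemaError("spots: tumor_area_mm2 exceeds aligned_area_mm2")
    spots["qc_pass"] = _coerce_bool(spots["qc_pass"], "spots", "qc_pass").astype(bool)
    return spots


def validate_patients(patients: pd.DataFrame) -> pd.DataFrame:
    _require_columns(patients, PATIENT_COLUMNS, "patients")
    patients = patients.copy()
    if patients["patient_id"].duplicated().any():
        dup = patients.loc[patients["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise SchemaError(f"patients: duplicated patient_id {dup!r}")
    if not patients["center"].isin(["A", "B"]).all():
        raise SchemaError("patients: center must be 'A' or 'B'")
    if not patients["subtype"].isin(["LUAD", "LUSC", "other"]).all():
        raise SchemaError("patients: subtype must be LUAD, LUSC or other")
    patients["uicc8"] = pd.to_numeric(patients["uicc8"], errors="coerce")
    if not patients["uicc8"].isin([1, 2, 3, 4]).all():
        raise SchemaError("patients: uicc8 must be in {1,2,3,4}")
    patients["uicc8"] = patients["uicc8"].astype(int)
    if not patients["r_status"].astype(str).isin(["0", "1", "unknown"]).all():
        raise SchemaError("patients: r_status must be 0, 1 or unknown")
    patients["r_status"] = patients["r_status"].astype(str)
    patients["adjuvant"] = _coerce_bool(patients["adjuvant"], "patients", "adjuvant").astype(bool)
    patients["os_months"] = pd.to_numeric(patients["os_months"], errors="coerce").astype(float)
    os_vals = patients["os_months"].to_numpy()
    if not np.isfinite(os_vals).all() or (os_vals < 0).any():
        row = int(patients.index[~(np.isfinite(os_vals) & (os_vals >= 0))][0])
        raise SchemaError(f"patients: invalid os_months at row {row}")
    patients["event"] = _coerce_bool(patients["event"], "patients", "event").astype(int)
    return patients


def build_dataset(cells: pd.DataFrame, spots: pd.DataFrame, patients: pd.DataFrame) -> Dataset:
    """Validate three in-memory tables and enforce cell->spot->patient integrity."""
    cells = validate_cells(cells)
    spots = validate_spots(spots)
    patients = validate_patients(patients)

    known_patients = set(patients["patient_id"])
    orphan_spots = set(spots["patient_id"]) - known_patients
    if orphan_spots:
        raise SchemaError(f"spots: unknown patient_id {sorted(orphan_spots)[0]!r}")
    known_spots = set(spots["spot_id"])
    orphan_cells = set(cells["spot_id"]) - known_spots
    if orphan_cells:
        raise SchemaError(f"cells: unknown spot_id {sorted(orphan_cells)[0]!r}")
    return Dataset(cells=cells, spots=spots, patients=patients)


def load_dataset(cells_path: str | Path, spots_path: str | Path, patients_path: str | Path) -> Dataset:
    """Read and validate a cohort from three TSV files."""
    for p in (cells_path, spots_path, patients_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    cells = pd.read_csv(cells_path, sep="\t")
    spots = pd.read_csv(spots_path, sep="\t")
    patients = pd.read_csv(patients_path, sep="\t")
    return build_dataset(cells, spots, patients)


def qc_filter_spots(spots: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split spots into QC-passing and rejected, with reason codes.

    Keeps spots with ``QC_MIN_AREA_MM2 <= aligned_area_mm2 <= QC_MAX_AREA_MM2``
    (bounds inclusive). Rejected spots carry a ``reason`` column with
    ``too_small`` or ``too_large``.
    """
    spots = validate_spots(spots)
    area = spots["aligned_area_mm2"]
    too_small = area < QC_MIN_AREA_MM2
    too_large = area > QC_MAX_AREA_MM2
    kept = spots.loc[~(too_small | too_large)].copy()
    rejected = spots.loc[too_small | too_large].copy()
    rejected["reason"] = np.where(too_small[too_small | too_large], "too_small", "too_large")
    return kept, rejected
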