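"""CSV dialects for curves, specimen metadata, scans and cohort tables.

Raw records stay in bench units on disk (mm, N, mmHg) and are converted to
SI on read; everything in memory is SI.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Iterable

import pandas as pd

from .growth import AorticMeasurement
from .mechanics import ForceDisplacementCurve, LoadingWindow, SpecimenGeometry

CURVE_COLUMNS = ["displacement_mm", "force_N"]
META_GEOMETRY = [f"{dim}{i}_mm" for dim in ("width", "thickness", "length") for i in (1, 2, 3)]
META_COLUMNS = ["patient", "segment", "direction", *META_GEOMETRY,
                "p_sys_mmhg", "p_dia_mmhg", "radius_mm"]
_DIRECTION_ALIASES = {"circ": "circumferential", "long": "longitudinal"}


def read_curve_csv(path) -> ForceDisplacementCurve:
    """Two-column specimen record: displacement_mm, force_N (header required)."""
    df = pd.read_csv(path)
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing curve columns {missing}")
    return ForceDisplacementCurve(
        displacement=df["displacement_mm"].to_numpy(dtype=float) * 1e-3,
        force=df["force_N"].to_numpy(dtype=float),
    )


def write_curve_csv(path, curve: ForceDisplacementCurve) -> None:
    pd.DataFrame(
        {"displacement_mm": curve.displacement * 1e3, "force_N": curve.force}
    ).to_csv(path, index=False)


def read_meta_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    return df


def meta_row_to_objects(row: pd.Series) -> tuple[SpecimenGeometry, LoadingWindow]:
    """Geometry and loading window for one specimen-metadata row."""
    geom = SpecimenGeometry.from_mm(
        width_reads_mm=[row[f"width{i}_mm"] for i in (1, 2, 3)],
        thickness_reads_mm=[row[f"thickness{i}_mm"] for i in (1, 2, 3)],
        length_reads_mm=[row[f"length{i}_mm"] for i in (1, 2, 3)],
    )
    direction = _DIRECTION_ALIASES.get(str(row["direction"]), str(row["direction"]))
    window = LoadingWindow.from_mmhg(
        p_sys_mmhg=float(row["p_sys_mmhg"]),
        p_dia_mmhg=float(row["p_dia_mmhg"]),
        radius_mm=float(row["radius_mm"]),
        thickness_mm=geom.T0 * 1e3,
        direction=direction,
    )
    return geom, window


def read_scans_csv(path) -> list[AorticMeasurement]:
    """Serial CT measurements: patient, location, date (ISO-8601), diameter_mm."""
    df = pd.read_csv(path)
    required = {"patient", "location", "date", "diameter_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing scan columns {sorted(missing)}")
    return [
        AorticMeasurement(
            patient=str(r.patient),
            location=str(r.location),
            date=dt.date.fromisoformat(str(r.date)),
            diameter_mm=float(r.diameter_mm),
        )
        for r in df.itertuples()
    ]


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cohort_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)
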