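"""Annualized aortic growth rates from serial CT diameter measurements.

Serial inner-to-inner diameter measurements at prespecified anatomic
locations are turned into an annualized growth rate per patient-location,
applying two data-quality rules: diameter changes smaller than 2 mm are
attributed to measurement error and zeroed before annualization, and scan
pairs fewer than (strictly) more than 60 days apart are excluded. Donor
controls, who have no serial imaging, are assigned a zero growth rate and a
normative diameter looked up from a user-supplied age/sex/BMI table.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25


class InsufficientDataError(ValueError):
    """Fewer than two scans available at a patient-location."""


class ExclusionError(ValueError):
    """A record fails an inclusion rule; `.reason` carries the audit message."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class ConfigurationError(ValueError):
    """Required configuration (e.g. a normative size table) is missing."""


@dataclass(frozen=True)
class AorticMeasurement:
    """One CT diameter reading (inner-to-inner, mm) at a location and date."""

    patient: str
    location: str
    date: dt.date
    diameter_mm: float

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError(f"diameter must be positive, got {self.diameter_mm}")
        if not isinstance(self.date, dt.date):
            raise TypeError("date must be a datetime.date")


@dataclass(frozen=True)
class GrowthRecord:
    patient: str
    location: str
    rate_mm_per_year: float
    interval_days: int
    n_scans_used: int
    pairwise_rates: tuple[float, ...] = field(default_factory=tuple)  # audit trail


def annualized_growth_rate(
    measurements: Sequence[AorticMeasurement],
    error_threshold_mm: float = 2.0,
    min_interval_days: int = 60,
) -> GrowthRecord:
    """Annualized growth rate for one patient-location.

    Uses the earliest and latest scans; a raw change strictly below
    ``error_threshold_mm`` is recorded as no change before annualization.
    Intervals not exceeding ``min_interval_days`` are excluded.
    """
    ms = sorted(measurements, key=lambda m: m.date)
    if len(ms) < 2:
        raise InsufficientDataError(
            f"need at least two scans, got {len(ms)} "
            f"({ms[0].patient}/{ms[0].location})" if ms else "need at least two scans, got 0"
        )
    keys = {(m.patient, m.location) for m in ms}
    if len(keys) != 1:
        raise ValueError(f"measurements span multiple patient-locations: {sorted(keys)}")

    first, last = ms[0], ms[-1]
    interval = (last.date - first.date).days
    if interval <= min_interval_days:
        raise ExclusionError(
            f"CT scans used were not more than {min_interval_days} days apart "
            f"(interval {interval} days)"
        )

    def _rate(a: AorticMeasurement, b: AorticMeasurement) -> float:
        change = b.diameter_mm - a.diameter_mm
        if abs(change) < error_threshold_mm:  # strict: exactly 2 mm is real change
            change = 0.0
        days = (b.date - a.date).days
        return change / (days / DAYS_PER_YEAR)

    pairwise = tuple(
        _rate(a, b)
        for a, b in zip(ms, ms[1:])
        if (b.date - a.date).days > 0
    )
    return GrowthRecord(
        patient=first.patient,
        location=first.location,
        rate_mm_per_year=_rate(first, last),
        interval_days=interval,
        n_scans_used=len(ms),
        pairwise_rates=pairwise,
    )


def growth_table(
    measurements: Iterable[AorticMeasurement],
    error_threshold_mm: float = 2.0,
    min_interval_days: int = 60,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per patient-location growth rates over a whole measurement set.

    Returns ``(rates, exclusions)``: surviving records and an audit table of
    exclusions with their reasons.
    """
    groups: dict[tuple[str, str], list[AorticMeasurement]] = {}
    for m in measurements:
        groups.setdefault((m.patient, m.location), []).append(m)

    rows, dropped = [], []
    for (patient, location), ms in sorted(groups.items()):
        try:
            rec = annualized_growth_rate(ms, error_threshold_mm, min_interval_days)
        except (ExclusionError, InsufficientDataError) as err:
            dropped.append(
                {"patient": patient, "location": location, "reason": str(err)}
            )
            continue
        rows.append(
            {
                "patient": rec.patient,
                "location": rec.location,
                "rate_mm_per_year": rec.rate_mm_per_year,
                "interval_days": rec.interval_days,
                "n_scans_used": rec.n_scans_used,
            }
        )
    return (
        pd.DataFrame(rows, columns=["patient", "location", "rate_mm_per_year",
                                    "interval_days", "n_scans_used"]),
        pd.DataFrame(dropped, columns=["patient", "location", "reason"]),
    )


class NormativeSizeTable:
    """Normative aortic diameters by age band, sex and BMI band.

    Loaded from a CSV with columns ``age_min, age_max, sex, bmi_min, bmi_max,
    diameter_mm``; bands are half-open ``[min, max)``. No published table is
    bundled — the reference values are external and version-dependent.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"age_min", "age_max", "sex", "bmi_min", "bmi_max", "diameter_mm"}
        missing = required - set(table.columns)
        if missing:
            raise ConfigurationError(f"normative table missing columns {sorted(missing)}")
        self._table = table.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "NormativeSizeTable":
        return cls(pd.read_csv(path))

    def lookup(self, age: float, sex: str, bmi: float) -> float:
        t = self._table
        hit = t[
            (t["age_min"] <= age)
            & (age < t["age_max"])
            & (t["sex"].str.lower() == sex.lower())
            & (t["bmi_min"] <= bmi)
            & (bmi < t["bmi_max"])
        ]
        if hit.empty:
            raise KeyError(f"no normative entry for age={age}, sex={sex!r}, bmi={bmi}")
        return float(hit.iloc[0]["diameter_mm"])


def donor_conventions(
    patient: str,
    location: str,
    *,
    age: float,
    sex: str,
    bmi: float,
    normative_table: NormativeSizeTable | None,
) -> tuple[GrowthRecord, float]:
    """Donor-control conventions: zero growth, size from the normative table.

    Donors lack serial orthogonal measurements, so their growth rate is
    fixed at 0 mm/y and their aortic size is estimated from age, sex and
    body-mass index via the supplied normative lookup.
    """
    if normative_table is None:
        raise ConfigurationError(
            "donor size estimation requires a normative size table (none supplied)"
        )
    size = normative_table.lookup(age, sex, bmi)
    record = GrowthRecord(
        patient=patient,
        location=location,
        rate_mm_per_year=0.0,
        interval_days=0,
        n_scans_used=0,
    )
    return record, size
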