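"""Domain types, tabular I/O and the survey filtering/aggregation rules.

The unit of the detection likelihood is a detected ptarmigan cluster
(:class:`GroupObservation`); the unit of the state model is a transect-year
(:class:`TransectYear`).  Transects are grouped into survey regions, the level
at which rodent occurrence is modelled.

File dialect: UTF-8 CSV with a header row, decimal point, ISO-8601 dates.
Columns: ``transect_id, region_id, length_km`` (transects),
``transect_id, year, distance_m, group_size, detector`` (observations),
``transect_id, year, n_obs, rodent_obs, harvest_prev`` (transect-years),
``transect_id, date, temp_c, snow_cm`` (daily climate).
"""

from __future__ import annotations

import dataclasses
import datetime
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "Transect",
    "GroupObservation",
    "TransectYear",
    "DailyClimateRecord",
    "SchemaError",
    "IntegrityError",
    "RowReport",
    "read_survey_tables",
    "read_climate_table",
    "filter_observations",
    "aggregate_counts",
    "select_transects",
    "write_survey_tables",
]

DETECTORS = ("dog", "surveyor")


class SchemaError(ValueError):
    """A mandatory column is missing or a file is structurally unreadable."""


class IntegrityError(ValueError):
    """Cross-record consistency violated (duplicate keys, unknown transects)."""


@dataclass(frozen=True)
class Transect:
    """A line-transect; belongs to exactly one survey region."""

    transect_id: str
    region_id: str
    length_km: float

    def __post_init__(self) -> None:
        if not (self.length_km > 0):
            raise ValueError(f"length_km must be > 0, got {self.length_km}")


@dataclass(frozen=True)
class GroupObservation:
    """One detected cluster of ptarmigan with its perpendicular distance."""

    transect_id: str
    year: int
    distance_m: float
    group_size: int
    detector: str = "dog"

    def __post_init__(self) -> None:
        if self.distance_m < 0:
            raise ValueError(f"distance_m must be >= 0, got {self.distance_m}")
        if self.group_size < 1:
            raise ValueError(f"group_size must be >= 1, got {self.group_size}")
        if self.detector not in DETECTORS:
            raise ValueError(f"detector must be one of {DETECTORS}")


@dataclass(frozen=True)
class TransectYear:
    """Counts and covariate observations for one transect in one year.

    ``n_obs`` is the total number of individuals counted (``None`` when the
    transect was not surveyed that year); ``rodent_obs`` is the binary rodent
    record (``None`` when missing); ``harvest_prev`` is the standardized
    harvest index of the previous hunting season (``None`` when unavailable).
    """

    transect_id: str
    year: int
    n_obs: Optional[int] = None
    rodent_obs: Optional[int] = None
    harvest_prev: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_obs is not None and self.n_obs < 0:
            raise ValueError("n_obs must be >= 0 or None")
        if self.rodent_obs not in (None, 0, 1):
            raise ValueError("rodent_obs must be 0, 1 or None")


@dataclass(frozen=True)
class DailyClimateRecord:
    transect_id: str
    date: datetime.date
    temp_c: float
    snow_cm: float

    def __post_init__(self) -> None:
        if self.snow_cm < 0:
            raise ValueError("snow_cm must be >= 0")


@dataclass
class RowReport:
    """Row-indexed record of rejected input rows, per file."""

    rejected: list = dataclasses.field(default_factory=list)  # (file, row, reason)

    def add(self, file: str, row: int, reason: str) -> None:
        self.rejected.append((file, row, reason))

    def __len__(self) -> int:
        return len(self.rejected)


_MANDATORY = {
    "transects": ["transect_id", "region_id", "length_km"],
    "observations": ["transect_id", "year", "distance_m", "group_size", "detector"],
    "transect_years": ["transect_id", "year", "n_obs", "rodent_obs"],
    "climate": ["transect_id", "date", "temp_c", "snow_cm"],
}


def _check_columns(df: pd.DataFrame, kind: str, path: str) -> None:
    missing = [c for c in _MANDATORY[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def _opt_int(v) -> Optional[int]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return int(v)


def _opt_float(v) -> Optional[float]:
    if v is None or v == "":
        return None
    v = float(v)
    return None if math.isnan(v) else v


def read_survey_tables(paths: Mapping[str, Path | str]):
    """Read the survey files into typed records.

    Parameters
    ----------
    paths
        Mapping with keys ``transects``, ``observations``, ``transect_years``
        pointing at CSV files in the documented dialect.

    Returns
    -------
    (transects, observations, transect_years, report)
        Lists of typed records plus a :class:`RowReport` of rejected rows.
        Rows whose mandatory fields do not parse, or violate a type invariant,
        are rejected individually; structural problems raise.
    """
    report = RowReport()

    tdf = pd.read_csv(paths["transects"], dtype={"transect_id": str, "region_id": str},
                      float_precision="round_trip")
    _check_columns(tdf, "transects", str(paths["transects"]))
    if tdf["transect_id"].duplicated().any():
        raise IntegrityError("duplicate transect_id in transects table")
    transects = []
    for idx, row in tdf.iterrows():
        try:
            transects.append(Transect(str(row.transect_id), str(row.region_id), float(row.length_km)))
        except (ValueError, TypeError) as e:
            report.add("transects", int(idx), str(e))

    odf = pd.read_csv(paths["observations"], dtype={"transect_id": str},
                      float_precision="round_trip")
    _check_columns(odf, "observations", str(paths["observations"]))
    observations = []
    for idx, row in odf.iterrows():
        try:
            observations.append(
                GroupObservation(
                    str(row.transect_id), int(row.year), float(row.distance_m),
                    int(row.group_size), str(row.detector),
                )
            )
        except (ValueError, TypeError) as e:
            report.add("observations", int(idx), str(e))

    ydf = pd.read_csv(paths["transect_years"], dtype={"transect_id": str},
                      float_precision="round_trip")
    _check_columns(ydf, "transect_years", str(paths["transect_years"]))
    if ydf.duplicated(subset=["transect_id", "year"]).any():
        raise IntegrityError("duplicate (transect_id, year) in transect_years table")
    tyears = []
    for idx, row in ydf.iterrows():
        try:
            tyears.append(
                TransectYear(
                    str(row.transect_id), int(row.year), _opt_int(row.n_obs),
                    _opt_int(row.rodent_obs),
                    _opt_float(row.harvest_prev) if "harvest_prev" in ydf.columns else None,
                )
            )
        except (ValueError, TypeError) as e:
            report.add("transect_years", int(idx), str(e))

    return transects, observations, tyears, report


def read_climate_table(path: Path | str) -> list[DailyClimateRecord]:
    """Read a daily climate CSV; duplicate transect-dates raise."""
    df = pd.read_csv(path, dtype={"transect_id": str}, parse_dates=["date"],
                     float_precision="round_trip")
    _check_columns(df, "climate", str(path))
    if df.duplicated(subset=["transect_id", "date"]).any():
        raise IntegrityError("duplicate (transect_id, date) in climate table")
    return [
        DailyClimateRecord(str(r.transect_id), r.date.date(), float(r.temp_c), float(r.snow_cm))
        for r in df.itertuples()
    ]


def filter_observations(
    obs: Iterable[GroupObservation],
    max_dist_m: float = 200.0,
    surveyor_max_m: float = 10.0,
) -> list[GroupObservation]:
    """Apply the survey truncation rules, preserving order.

    Retains observations within ``max_dist_m`` of the line, and among those
    drops detections made by the surveyor (rather than the dog) beyond
    ``surveyor_max_m`` — such birds were likely flushed by the surveyor off
    the line and are not part of the modelled detection process.
    """
    if max_dist_m < 0 or surveyor_max_m < 0:
        raise ValueError("distance thresholds must be non-negative")
    return [
        o
        for o in obs
        if o.distance_m <= max_dist_m
        and (o.detector == "dog" or o.distance_m <= surveyor_max_m)
    ]


def aggregate_counts(
    obs: Iterable[GroupObservation],
    surveyed: Iterable[tuple[str, int]],
    transects: Optional[Iterable[Transect]] = None,
) -> list[TransectYear]:
    """Sum retained group sizes into transect-year totals.

    A surveyed transect-year with no detections yields ``n_obs = 0`` (zero
    counts are informative in distance sampling); transect-years not listed in
    ``surveyed`` are not emitted.
    """
    surveyed = list(surveyed)
    known = {t.transect_id for t in transects} if transects is not None else None
    totals: dict[tuple[str, int], int] = {key: 0 for key in surveyed}
    for o in obs:
        key = (o.transect_id, o.year)
        if known is not None and o.transect_id not in known:
            raise IntegrityError(f"observation references unknown transect {o.transect_id!r}")
        if key not in totals:
            raise IntegrityError(f"observation on unsurveyed transect-year {key}")
        totals[key] += o.group_size
    return [TransectYear(tid, yr, n_obs=totals[(tid, yr)]) for tid, yr in surveyed]


def select_transects(
    tyears: Iterable[TransectYear],
    transects: Iterable[Transect],
    min_years: int = 6,
) -> list[Transect]:
    """Keep transects surveyed (non-missing ``n_obs``) in at least ``min_years`` years."""
    counts: dict[str, int] = {}
    for ty in tyears:
        if ty.n_obs is not None:
            counts[ty.transect_id] = counts.get(ty.transect_id, 0) + 1
    return [t for t in transects if counts.get(t.transect_id, 0) >= min_years]


def write_survey_tables(
    directory: Path | str,
    transects: Sequence[Transect],
    observations: Sequence[GroupObservation],
    tyears: Sequence[TransectYear],
    climate: Sequence[DailyClimateRecord] = (),
) -> dict[str, Path]:
    """Write records back out in the documented CSV dialect; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["transects"] = directory / "transects.csv"
    pd.DataFrame([dataclasses.asdict(t) for t in transects]).to_csv(
        paths["transects"], index=False, float_format="%.17g"
    )

    paths["observations"] = directory / "observations.csv"
    pd.DataFrame([dataclasses.asdict(o) for o in observations]).to_csv(
        paths["observations"], index=False, float_format="%.17g"
    )

    paths["transect_years"] = directory / "transect_years.csv"
    pd.DataFrame([dataclasses.asdict(y) for y in tyears]).to_csv(
        paths["transect_years"], index=False, float_format="%.17g"
    )

    if climate:
        paths["climate"] = directory / "climate.csv"
        pd.DataFrame(
            [
                {"transect_id": c.transect_id, "date": c.date.isoformat(),
                 "temp_c": c.temp_c, "snow_cm": c.snow_cm}
                for c in climate
            ]
        ).to_csv(paths["climate"], index=False, float_format="%.17g")
    return paths
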