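"""Breeding-habit summaries: remigration, internesting, nest distances.

Works from nest metadata plus a mother assignment (reconstructed or true).
A season is a calendar year (Mediterranean nesting is summer-bounded), so
remigration intervals are year differences and internesting intervals are
day gaps between a female's consecutive clutches within one year.  Distances
are great-circle kilometres on a sphere of radius 6371 km.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, datetime
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NestRecord",
    "IntervalReport",
    "read_nests_csv",
    "nest_records_from_frame",
    "remigration_intervals",
    "internesting_intervals",
    "nest_distance",
    "mother_nest_map",
    "interval_report",
    "philopatry_summary",
]

EARTH_RADIUS_KM = 6371.0
LONG_RANGE_KM = 50.0


@dataclass
class NestRecord:
    """One nest: where and when it was laid, and which hatchlings it holds."""

    nest_id: str
    date: date | None
    lat: float | None
    lon: float | None
    samples: list[str] = field(default_factory=list)
    beach: str | None = None
    mt_haplotype: str | None = None

    def __post_init__(self) -> None:
        if self.lat is not None and not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"nest {self.nest_id}: latitude {self.lat} out of range")
        if self.lon is not None and not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"nest {self.nest_id}: longitude {self.lon} out of range")


def _parse_date(value) -> date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    if isinstance(value, datetime):
        return value.date()
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value))


def nest_records_from_frame(df: pd.DataFrame) -> list[NestRecord]:
    """Collapse a long-format nest table (row per hatchling) to records.

    Expected columns: ``nest_id, sample_id, date, lat, lon`` and optionally
    ``mt_haplotype``/``beach``.
    """
    records: dict[str, NestRecord] = {}
    for _, row in df.iterrows():
        nid = str(row["nest_id"])
        if nid not in records:
            lat = row.get("lat")
            lon = row.get("lon")
            records[nid] = NestRecord(
                nest_id=nid,
                date=_parse_date(row.get("date")),
                lat=None if pd.isna(lat) else float(lat),
                lon=None if pd.isna(lon) else float(lon),
                mt_haplotype=(None if pd.isna(row.get("mt_haplotype"))
                              else str(row.get("mt_haplotype"))),
                beach=(None if pd.isna(row.get("beach", np.nan))
                       else str(row.get("beach"))),
            )
        records[nid].samples.append(str(row["sample_id"]))
    return [records[k] for k in sorted(records)]


def read_nests_csv(path: str | Path) -> list[NestRecord]:
    return nest_records_from_frame(pd.read_csv(path))


def remigration_intervals(
    nest_dates: Mapping[str, Iterable[date]]
) -> dict[str, list[int]]:
    """Per-mother gaps (years) between consecutive nesting seasons.

    Mothers seen in a single season yield an empty list.
    """
    out: dict[str, list[int]] = {}
    for mother, dates in nest_dates.items():
        years = sorted({d.year for d in dates if d is not None})
        out[mother] = [b - a for a, b in zip(years, years[1:])]
    return out


def internesting_intervals(
    nest_dates: Mapping[str, Iterable[date]]
) -> dict[str, list[int]]:
    """Per-mother day gaps between consecutive clutches within one season."""
    out: dict[str, list[int]] = {}
    for mother, dates in nest_dates.items():
        gaps: list[int] = []
        by_year: dict[int, list[date]] = {}
        for d in dates:
            if d is not None:
                by_year.setdefault(d.year, []).append(d)
        for year in sorted(by_year):
            ds = sorted(by_year[year])
            for a, b in zip(ds, ds[1:]):
                gap = (b - a).days
                if gap == 0:
                    warnings.warn(
                        f"{mother}: same-day clutches on {a.isoformat()}", stacklevel=2
                    )
                gaps.append(gap)
        out[mother] = gaps
    return out


def nest_distance(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle (haversine) distance in km, Earth radius 6371 km."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} out of [-90, 90]")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ValueError(f"longitude {lon} out of [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2 - lon1)
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def mother_nest_map(
    mothers: Mapping[str, dict] | Mapping[str, Sequence[str]],
    nests: Sequence[NestRecord],
) -> dict[str, list[NestRecord]]:
    """mother label -> her nest records (accepts ReconstructionResult.mothers)."""
    by_id = {n.nest_id: n for n in nests}
    out: dict[str, list[NestRecord]] = {}
    for mother, info in mothers.items():
        nest_ids = info["nests"] if isinstance(info, Mapping) else info
        out[mother] = [by_id[nid] for nid in nest_ids]
    return out


@dataclass
class IntervalReport:
    """Remigration years, internesting days, and nest distances per mother."""

    remigration: dict[str, list[int]]
    internesting: dict[str, list[int]]
    distances: pd.DataFrame  # mother, nest_a, nest_b, km, same_season

    def all_internesting_days(self) -> list[int]:
        return [g for gaps in self.internesting.values() for g in gaps]

    def all_remigration_years(self) -> list[int]:
        return [g for gaps in self.remigration.values() for g in gaps]


def interval_report(
    mothers_nests: Mapping[str, Sequence[NestRecord]]
) -> IntervalReport:
    """Compute the full interval/distance report from mother -> nests."""
    dates = {m: [n.date for n in ns] for m, ns in mothers_nests.items()}
    rows = []
    for mother, ns in mothers_nests.items():
        for a, b in combinations(ns, 2):
            if None in (a.lat, a.lon, b.lat, b.lon):
                continue
            km = nest_distance(a.lat, a.lon, b.lat, b.lon)
            same = (a.date is not None and b.date is not None
                    and a.date.year == b.date.year)
            rows.append({
                "mother": mother, "nest_a": a.nest_id, "nest_b": b.nest_id,
                "km": km, "same_season": same,
            })
    distances = pd.DataFrame(rows, columns=["mother", "nest_a", "nest_b", "km",
                                            "same_season"])
    return IntervalReport(
        remigration=remigration_intervals(dates),
        internesting=internesting_intervals(dates),
        distances=distances,
    )


def philopatry_summary(
    report: IntervalReport, long_range_km: float = LONG_RANGE_KM
) -> pd.DataFrame:
    """Per-mother nest-displacement descriptors with long-range flags.

    Mothers with a single nest (no pairwise distances) are reported with
    zero distances and no flag; an empty mother set yields an empty table.
    """
    cols = ["mother", "n_pairs", "max_km", "median_km",
            "max_same_season_km", "max_across_season_km", "long_range"]
    if report.distances.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for mother, sub in report.distances.groupby("mother"):
        same = sub[sub["same_season"]]["km"]
        across = sub[~sub["same_season"]]["km"]
        rows.append({
            "mother": mother,
            "n_pairs": int(len(sub)),
            "max_km": float(sub["km"].max()),
            "median_km": float(sub["km"].median()),
            "max_same_season_km": float(same.max()) if len(same) else 0.0,
            "max_across_season_km": float(across.max()) if len(across) else 0.0,
            "long_range": bool((sub["km"] > long_range_km).any()),
        })
    return pd.DataFrame(rows, columns=cols).sort_values("mother").reset_index(drop=True)
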