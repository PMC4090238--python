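"""Reading and preprocessing of origin–destination trip records.

The raw input is one reservation per row: an origin point, a destination
campground point, a visit date and a trip count.  Three preprocessing
steps turn these into the sparse segment table that feeds the network
model:

1. seasonal filtering — keep only trips whose visit date falls inside the
   borer flight window (default 10 weeks) at *both* the origin and the
   destination;
2. low-frequency filtering — drop origin–destination pairs with fewer
   than ``min_trips`` trips (default 4, i.e. "three or fewer" dropped);
3. aggregation onto an equal-area grid, discarding trips whose origin and
   destination fall in the same cell (the travel matrix has a zero
   diagonal).

A fourth augmentation step adds return segments: campers carrying unused
firewood home are modelled by a reverse link j→i weighted at a fixed
fraction (default 0.15) of the forward trips m_ij.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import GridSpec


@dataclass(frozen=True)
class TripRecord:
    """A single reservation: origin point, destination point, date, count."""

    origin_lon: float
    origin_lat: float
    dest_lon: float
    dest_lat: float
    visit_date: dt.date
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("trip count must be >= 1")
        for name, lon, lat in (
            ("origin", self.origin_lon, self.origin_lat),
            ("destination", self.dest_lon, self.dest_lat),
        ):
            if not (-180.0 <= lon <= 180.0) or not (-90.0 <= lat <= 90.0):
                raise ValueError(f"{name} coordinates ({lon}, {lat}) out of lon/lat range")


@dataclass(frozen=True)
class SeasonModel:
    """Per-location late spring–early summer window.

    The window is half-open: a date is inside if
    ``start <= date < start + 7 * weeks`` days.  ``start_fn`` maps a
    (lon, lat) point to the local window start date; the default applies
    one constant start date everywhere.  A per-location lookup can be
    supplied for geographically varying flight seasons.
    """

    start: dt.date = dt.date(2006, 5, 1)
    weeks: int = 10
    start_fn: Callable[[float, float], dt.date] | None = None

    def __post_init__(self) -> None:
        if self.weeks <= 0:
            raise ValueError("window length must be positive")

    def window(self, lon: float, lat: float, year: int | None = None) -> tuple[dt.date, dt.date]:
        start = self.start_fn(lon, lat) if self.start_fn is not None else self.start
        if year is not None:
            start = start.replace(year=year)
        return start, start + dt.timedelta(days=7 * self.weeks)

    def contains(self, lon: float, lat: float, date: dt.date) -> bool:
        start, end = self.window(lon, lat, year=date.year)
        return start <= date < end


@dataclass
class SegmentTable:
    """Sparse ordered-pair (cell i, cell j) → trip weight m_ij.

    This is the content of the travel-frequency matrix **M**: no diagonal
    entries, all stored weights positive.  ``n`` is the number of distinct
    cell ids appearing on either side of any pair.
    """

    entries: dict[tuple[int, int], float] = field(default_factory=dict)
    period: str = ""

    def __post_init__(self) -> None:
        for (i, j), w in self.entries.items():
            if i == j:
                raise ValueError(f"diagonal entry ({i}, {i}) not allowed")
            if w <= 0:
                raise ValueError(f"non-positive weight at ({i}, {j})")

    @property
    def nodes(self) -> list[int]:
        ids: set[int] = set()
        for i, j in self.entries:
            ids.add(i)
            ids.add(j)
        return sorted(ids)

    @property
    def n(self) -> int:
        return len(self.nodes)

    def total_weight(self) -> float:
        return float(sum(self.entries.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.entries.items())
        return pd.DataFrame(
            {
                "cell_i": [i for (i, _), _ in rows],
                "cell_j": [j for (_, j), _ in rows],
                "weight": [w for _, w in rows],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, period: str = "") -> "SegmentTable":
        df = pd.read_csv(path)
        entries = {
            (int(r.cell_i), int(r.cell_j)): float(r.weight) for r in df.itertuples(index=False)
        }
        return cls(entries=entries, period=period)


DEFAULT_COLUMNS: Mapping[str, str] = {
    "origin_lon": "origin_lon",
    "origin_lat": "origin_lat",
    "dest_lon": "dest_lon",
    "dest_lat": "dest_lat",
    "visit_date": "visit_date",
    "count": "count",
}


def read_trips(
    path,
    columns: Mapping[str, str] | None = None,
    sep: str = ",",
) -> list[TripRecord]:
    """Read trip records from delimited text.

    ``columns`` maps the canonical field names (keys of
    ``DEFAULT_COLUMNS``) to the file's column names.  A missing count
    column defaults every record to one trip.  Malformed coordinates or
    dates raise ``ValueError`` naming the offending data row (1-based,
    header excluded).  An empty file yields an empty list.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        return []
    required = ["origin_lon", "origin_lat", "dest_lon", "dest_lat", "visit_date"]
    for key in required:
        if cols[key] not in df.columns:
            raise ValueError(f"missing column {cols[key]!r} in {path}")
    has_count = cols["count"] in df.columns
    records: list[TripRecord] = []
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        try:
            date = pd.Timestamp(row_d[cols["visit_date"]]).date()
            rec = TripRecord(
                origin_lon=float(row_d[cols["origin_lon"]]),
                origin_lat=float(row_d[cols["origin_lat"]]),
                dest_lon=float(row_d[cols["dest_lon"]]),
                dest_lat=float(row_d[cols["dest_lat"]]),
                visit_date=date,
                count=int(row_d[cols["count"]]) if has_count else 1,
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"row {pos}: {exc}") from exc
        records.append(rec)
    return records


def write_trips(records: Iterable[TripRecord], path) -> None:
    """Write trip records to the CSV layout ``read_trips`` consumes."""
    df = pd.DataFrame(
        {
            "origin_lon": [r.origin_lon for r in records],
            "origin_lat": [r.origin_lat for r in records],
            "dest_lon": [r.dest_lon for r in records],
            "dest_lat": [r.dest_lat for r in records],
            "visit_date": [r.visit_date.isoformat() for r in records],
            "count": [r.count for r in records],
        }
    )
    df.to_csv(path, index=False)


def filter_season(trips: Sequence[TripRecord], season: SeasonModel) -> list[TripRecord]:
    """Keep trips inside the seasonal window at both endpoints.

    A trip is retained only when its visit date lies within the flight
    window evaluated at the origin AND at the destination; record order
    is preserved.
    """
    return [
        t
        for t in trips
        if season.contains(t.origin_lon, t.origin_lat, t.visit_date)
        and season.contains(t.dest_lon, t.dest_lat, t.visit_date)
    ]


def filter_low_frequency_trips(
    trips: Sequence[TripRecord], min_trips: int = 4
) -> list[TripRecord]:
    """Drop raw origin–destination point pairs with fewer than ``min_trips`` trips.

    Pairs are keyed on exact origin and destination coordinates, the
    resolution of the raw reservation data; counts are summed over the
    whole collection before filtering.  Order of survivors is preserved.
    """
    if min_trips < 1:
        raise ValueError("min_trips must be >= 1")
    totals: dict[tuple[float, float, float, float], int] = {}
    for t in trips:
        key = (t.origin_lon, t.origin_lat, t.dest_lon, t.dest_lat)
        totals[key] = totals.get(key, 0) + t.count
    return [
        t
        for t in trips
        if totals[(t.origin_lon, t.origin_lat, t.dest_lon, t.dest_lat)] >= min_trips
    ]


def aggregate_to_grid(
    trips: Sequence[TripRecord], grid: GridSpec, period: str = ""
) -> SegmentTable:
    """Sum trip counts onto ordered grid-cell pairs.

    m_ij is the total count of trips whose origin maps to cell i and
    destination to cell j.  Trips whose endpoints fall in the same cell
    are discarded (the travel matrix diagonal is fixed at zero).  A point
    outside the grid extent raises, naming the record.
    """
    if not trips:
        return SegmentTable(period=period)
    o_lon = np.array([t.origin_lon for t in trips])
    o_lat = np.array([t.origin_lat for t in trips])
    d_lon = np.array([t.dest_lon for t in trips])
    d_lat = np.array([t.dest_lat for t in trips])
    try:
        ocell = grid.cell_id(o_lon, o_lat)
    except ValueError as exc:
        raise ValueError(f"trip origin outside grid extent: {exc}") from exc
    try:
        dcell = grid.cell_id(d_lon, d_lat)
    except ValueError as exc:
        raise ValueError(f"trip destination outside grid extent: {exc}") from exc
    entries: dict[tuple[int, int], float] = {}
    for k, t in enumerate(trips):
        i, j = int(ocell[k]), int(dcell[k])
        if i == j:
            continue
        entries[(i, j)] = entries.get((i, j), 0.0) + t.count
    return SegmentTable(entries=entries, period=period)


def filter_low_frequency(segments: SegmentTable, min_trips: int = 4) -> SegmentTable:
    """Keep cell pairs with weight >= ``min_trips``; idempotent."""
    if min_trips < 1:
        raise ValueError("min_trips must be >= 1")
    kept = {k: w for k, w in segments.entries.items() if w >= min_trips}
    return SegmentTable(entries=kept, period=segments.period)


def add_return_segments(
    segments: SegmentTable, return_fraction: float = 0.15
) -> SegmentTable:
    """Augment each forward segment ij with a return segment ji.

    For every input entry (i, j) with weight m_ij, the output weight at
    (j, i) is incremented by ``return_fraction * m_ij`` on top of any
    observed m_ji.  Increments are computed from the input weights only —
    a return increment never generates a further return.  Weights stay
    fractional; they feed transition probabilities, not counts.
    """
    if not (0.0 <= return_fraction <= 1.0):
        raise ValueError("return_fraction must be in [0, 1]")
    out = dict(segments.entries)
    for (i, j), w in segments.entries.items():
        inc = return_fraction * w
        if inc > 0:
            out[(j, i)] = out.get((j, i), 0.0) + inc
    return SegmentTable(entries=out, period=segments.period)


def preprocess(
    trips: Sequence[TripRecord],
    grid: GridSpec,
    season: SeasonModel | None = None,
    min_trips: int = 4,
    return_fraction: float = 0.15,
    low_freq_level: str = "pair",
    period: str = "",
) -> SegmentTable:
    """Full preprocessing pipeline: season → low-frequency → grid → returns.

    ``low_freq_level`` selects whether the low-frequency drop is applied
    to raw point pairs before aggregation (``"pair"``, the default) or to
    aggregated cell pairs afterwards (``"cell"``).
    """
    if low_freq_level not in ("pair", "cell"):
        raise ValueError("low_freq_level must be 'pair' or 'cell'")
    if season is not None:
        trips = filter_season(trips, season)
    if low_freq_level == "pair":
        trips = filter_low_frequency_trips(trips, min_trips)
        table = aggregate_to_grid(trips, grid, period=period)
    else:
        table = aggregate_to_grid(trips, grid, period=period)
        table = filter_low_frequency(table, min_trips)
    return add_return_segments(table, return_fraction)
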