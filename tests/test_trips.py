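"""Trip reading and the three preprocessing steps plus return segments."""

import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

from campnet import (
    GridSpec,
    SeasonModel,
    SegmentTable,
    TripRecord,
    add_return_segments,
    aggregate_to_grid,
    filter_low_frequency,
    filter_low_frequency_trips,
    filter_season,
    read_trips,
)

GRID = GridSpec.from_extent(-10.0, 38.0, 10.0, 50.0, cell_size=15.0)


def trip(olon, olat, dlon, dlat, date=dt.date(2006, 5, 15), count=1):
    return TripRecord(olon, olat, dlon, dlat, date, count)


# --- read_trips -------------------------------------------------------------

def test_read_empty_file(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("origin_lon,origin_lat,dest_lon,dest_lat,visit_date,count\n")
    assert read_trips(p) == []


def test_read_missing_count_defaults_to_one(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text(
        "origin_lon,origin_lat,dest_lon,dest_lat,visit_date\n"
        "0.0,45.0,1.0,45.0,2006-05-15\n"
    )
    (rec,) = read_trips(p)
    assert rec.count == 1


def test_read_bad_coordinate_names_row(tmp_path):
    p = tmp_path / "t.csv"
    rows = ["%f,45.0,1.0,45.0,2006-05-15,1" % (0.1 * k) for k in range(3)]
    rows.append("0.5,999.0,1.0,45.0,2006-05-15,1")
    p.write_text(
        "origin_lon,origin_lat,dest_lon,dest_lat,visit_date,count\n" + "\n".join(rows)
    )
    with pytest.raises(ValueError, match="row 4"):
        read_trips(p)


def test_trip_record_validates():
    with pytest.raises(ValueError):
        trip(0, 45, 1, 45, count=0)
    with pytest.raises(ValueError):
        TripRecord(200.0, 45.0, 1.0, 45.0, dt.date(2006, 5, 15))


# --- seasonal filter --------------------------------------------------------

def test_season_filter_half_open_window():
    """May 1 start, 10 weeks: day 0 kept, day 70 (July 10) dropped."""
    season = SeasonModel(start=dt.date(2006, 5, 1), weeks=10)
    inside = trip(0, 45, 1, 45, date=dt.date(2006, 5, 1))
    boundary = trip(0, 45, 1, 45, date=dt.date(2006, 7, 10))
    assert (dt.date(2006, 7, 10) - dt.date(2006, 5, 1)).days == 70
    kept = filter_season([inside, boundary], season)
    assert kept == [inside]


def test_season_filter_requires_both_endpoints():
    """A trip inside the origin window but outside the destination window goes."""
    # start date depends on latitude: south starts Apr 1, north starts Jun 1
    def start_fn(lon, lat):
        return dt.date(2006, 4, 1) if lat < 45 else dt.date(2006, 6, 1)

    season = SeasonModel(start_fn=start_fn, weeks=10)
    t = trip(0, 40, 1, 49, date=dt.date(2006, 4, 15))  # origin ok, dest not yet
    assert filter_season([t], season) == []
    both = trip(0, 40, 1, 41, date=dt.date(2006, 4, 15))
    assert filter_season([both], season) == [both]


# --- grid aggregation -------------------------------------------------------

def test_aggregate_empty():
    assert aggregate_to_grid([], GRID).entries == {}


def test_aggregate_manual_assignment():
    """Two trips share a cell pair; a same-cell trip is discarded."""
    a = trip(0.0, 45.0, 5.0, 45.0)
    b = trip(0.01, 45.01, 5.01, 45.01)  # same cells as a
    same = trip(0.0, 45.0, 0.01, 45.01)  # origin and dest in one cell
    table = aggregate_to_grid([a, b, same], GRID)
    i = int(GRID.cell_id(0.0, 45.0)[0])
    j = int(GRID.cell_id(5.0, 45.0)[0])
    assert table.entries == {(i, j): 2.0}


def test_aggregate_conserves_counts():
    trips = [trip(0.0, 45.0, 5.0, 45.0, count=3), trip(2.0, 44.0, -3.0, 46.0, count=2)]
    table = aggregate_to_grid(trips, GRID)
    assert table.total_weight() == 5.0


def test_aggregate_outside_extent_names_record():
    with pytest.raises(ValueError, match="origin outside grid extent"):
        aggregate_to_grid([trip(100.0, 45.0, 5.0, 45.0)], GRID)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(perm=st.permutations(range(5)))
def test_aggregate_permutation_invariant(perm):
    trips = [
        trip(0.0 + 0.5 * k, 44.0 + 0.3 * k, 5.0 - 0.4 * k, 45.0, count=k + 1)
        for k in range(5)
    ]
    base = aggregate_to_grid(trips, GRID)
    shuffled = aggregate_to_grid([trips[k] for k in perm], GRID)
    assert base.entries == shuffled.entries


# --- low-frequency filter ---------------------------------------------------

def test_low_frequency_boundary():
    """Three or fewer trips dropped; four retained."""
    t = SegmentTable({(1, 2): 3.0, (3, 4): 4.0})
    out = filter_low_frequency(t, min_trips=4)
    assert out.entries == {(3, 4): 4.0}


def test_low_frequency_enumeration():
    t = SegmentTable({(1, 2): 1.0, (2, 3): 3.0, (3, 4): 4.0, (4, 5): 5.0})
    assert len(filter_low_frequency(t).entries) == 2


def test_low_frequency_empty_and_config_error():
    assert filter_low_frequency(SegmentTable()).entries == {}
    with pytest.raises(ValueError):
        filter_low_frequency(SegmentTable(), min_trips=0)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    weights=st.dictionaries(
        st.tuples(st.integers(0, 8), st.integers(0, 8)).filter(lambda ij: ij[0] != ij[1]),
        st.floats(0.1, 20),
        max_size=20,
    ),
    min_trips=st.integers(1, 6),
)
def test_low_frequency_idempotent(weights, min_trips):
    t = SegmentTable(weights)
    once = filter_low_frequency(t, min_trips)
    twice = filter_low_frequency(once, min_trips)
    assert once.entries == twice.entries


def test_low_frequency_at_raw_pair_level():
    """Pair totals are summed over records before dropping."""
    reps = [trip(0.0, 45.0, 5.0, 45.0) for _ in range(4)]
    rare = [trip(1.0, 44.0, 5.0, 45.0)]
    kept = filter_low_frequency_trips(reps + rare, min_trips=4)
    assert kept == reps


# --- return segments --------------------------------------------------------

def test_return_segment_rule():
    out = add_return_segments(SegmentTable({(1, 2): 100.0}))
    assert out.entries[(2, 1)] == pytest.approx(15.0)
    assert out.entries[(1, 2)] == 100.0


def test_return_fraction_zero_is_identity():
    t = SegmentTable({(1, 2): 100.0, (5, 6): 7.0})
    assert add_return_segments(t, 0.0).entries == t.entries


def test_return_with_observed_reverse():
    """Increments come from input weights only; both directions augment."""
    out = add_return_segments(SegmentTable({(1, 2): 100.0, (2, 1): 20.0}))
    assert out.entries[(2, 1)] == pytest.approx(35.0)
    assert out.entries[(1, 2)] == pytest.approx(103.0)


def test_return_fraction_validation():
    with pytest.raises(ValueError):
        add_return_segments(SegmentTable({(1, 2): 1.0}), 1.5)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    weights=st.dictionaries(
        st.tuples(st.integers(0, 6), st.integers(7, 12)),  # forward-only pairs
        st.floats(0.1, 100),
        min_size=1,
        max_size=15,
    ),
    frac=st.floats(0.0, 1.0),
)
def test_return_total_weight_scaling(weights, frac):
    """No observed reverse entries: total weight scales by (1 + f)."""
    t = SegmentTable(weights)
    out = add_return_segments(t, frac)
    assert out.total_weight() == pytest.approx((1 + frac) * t.total_weight())
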