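"""Track reading, the four preprocessing filters, thinning, coverage, weights."""

import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catscape.tracks import (
    TrackFormatError,
    daily_coverage,
    filter_download_days,
    filter_ehpe,
    filter_elevation,
    filter_first_days,
    outdoor_weight,
    read_tracks,
    read_tracks_lonlat,
    thin_track,
    write_tracks,
)

from conftest import make_track


class TestReadTracks:
    def test_sorts_partitions_and_collapses_duplicates(self, tmp_path):
        rows = [
            "A,2021-05-01T08:00:30Z,1,2,50,3",
            "B,2021-05-01T08:00:00Z,9,9,50,3",
            "A,2021-05-01T08:00:00Z,0,0,50,3",
            "A,2021-05-01T08:00:30Z,5,5,50,3",  # duplicate timestamp for A
            "A,2021-05-01T08:01:00Z,2,3,50,3",
        ]
        p = tmp_path / "fixes.csv"
        p.write_text("cat_id,timestamp,x,y,elevation,ehpe\n" + "\n".join(rows) + "\n")
        tracks = read_tracks(p)
        assert sorted(tracks) == ["A", "B"]
        a = tracks["A"]
        assert a.n_fixes == 3  # duplicate collapsed to first occurrence
        assert a.fixes["timestamp"].is_monotonic_increasing
        assert a.fixes["x"].tolist() == [0.0, 1.0, 2.0]  # first occurrence kept
        assert tracks["B"].n_fixes == 1

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("cat_id,timestamp,x,y,elevation\nA,2021-05-01T08:00:00Z,0,0,50\n")
        with pytest.raises(TrackFormatError, match="ehpe"):
            read_tracks(p)

    def test_unparseable_timestamp_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "cat_id,timestamp,x,y,elevation,ehpe\n"
            "A,2021-05-01T08:00:00Z,0,0,50,3\n"
            "A,not-a-time,0,0,50,3\n"
        )
        with pytest.raises(TrackFormatError, match="line 3"):
            read_tracks(p)

    def test_write_read_roundtrip(self, tmp_path):
        tr = make_track([0, 60, 120], xy=np.arange(6).reshape(3, 2))
        p = tmp_path / "out.csv"
        write_tracks({"cat": tr}, p)
        back = read_tracks(p)["cat"]
        np.testing.assert_allclose(back.xy(), tr.xy(), atol=1e-3)
        assert (back.fixes["timestamp"] == tr.fixes["timestamp"]).all()

    def test_lonlat_reader_projects_to_meters(self, tmp_path):
        # ~1.11 m per 1e-5 degree of latitude
        p = tmp_path / "ll.csv"
        p.write_text(
            "cat_id,timestamp,lon,lat,elevation,ehpe\n"
            "A,2021-05-01T08:00:00Z,10.00000,59.66000,50,3\n"
            "A,2021-05-01T08:00:30Z,10.00000,59.66090,50,3\n"
        )
        tr = read_tracks_lonlat(p)["A"]
        dy = tr.fixes["y"].iloc[1] - tr.fixes["y"].iloc[0]
        assert dy == pytest.approx(0.0009 * 111_195, rel=1e-3)
        assert abs(tr.fixes["x"].iloc[1] - tr.fixes["x"].iloc[0]) < 0.01


class TestFilters:
    def test_elevation_closed_interval(self):
        tr = make_track([0, 60, 120, 180, 240], elevation=[-5, 0, 150, 300, 310])
        out = filter_elevation(tr)
        assert out.fixes["elevation"].tolist() == [0, 150, 300]

    def test_elevation_boundary_example(self):
        tr = make_track([0, 60, 120], elevation=[-5, 299, 310])
        assert filter_elevation(tr).fixes["elevation"].tolist() == [299]

    def test_first_days_removes_first_two_calendar_days(self):
        day = 86400
        tr = make_track([i * 600 for i in range(10)] + [2 * day + i * 600 for i in range(5)])
        out = filter_first_days(tr)
        assert out.n_fixes == 5
        # with deployment start known, fixes from day 2 onward are untouched
        late = make_track([2 * day, 3 * day], deployment_start=dt.date(2021, 5, 1))
        assert filter_first_days(late).n_fixes == 2

    def test_download_days(self):
        day = 86400
        tr = make_track(
            [i * 600 for i in range(13)] + [5 * day + i * 600 for i in range(7)],
            download_dates={dt.date(2021, 5, 6)},
        )
        assert filter_download_days(tr).n_fixes == 13
        tr2 = make_track([0, 600], download_dates=set())
        assert filter_download_days(tr2).n_fixes == 2

    def test_ehpe_cutoff_is_inclusive(self):
        tr = make_track([0, 60], ehpe=[4999.0, 5000.0])
        assert filter_ehpe(tr).fixes["ehpe"].tolist() == [4999.0]

    def test_ehpe_mixed_counts(self):
        ehpe = [3.0] * 7 + [5000.0, 9000.0, 12000.0]
        tr = make_track([i * 60 for i in range(10)], ehpe=ehpe)
        assert filter_ehpe(tr).n_fixes == 7
        assert filter_ehpe(make_track([0, 60], ehpe=0.0)).n_fixes == 2

    def test_removal_rules_commute(self):
        rng = np.random.default_rng(0)
        day = 86400
        offs = np.sort(rng.choice(np.arange(0, 10 * day, 30), size=300, replace=False))
        tr = make_track(
            offs,
            elevation=rng.choice([-10.0, 50.0, 400.0], size=300, p=[0.1, 0.8, 0.1]),
            ehpe=rng.choice([3.0, 6000.0], size=300, p=[0.9, 0.1]),
            download_dates={dt.date(2021, 5, 4)},
        )
        rules = [filter_elevation, filter_download_days, filter_ehpe]
        results = []
        for perm in itertools.permutations(rules):
            out = tr
            for f in perm:
                out = f(out)
            results.append(out.fixes.reset_index(drop=True))
        for r in results[1:]:
            pd.testing.assert_frame_equal(r, results[0])

    @pytest.mark.parametrize(
        "filt",
        [filter_elevation, filter_first_days, filter_download_days, filter_ehpe, thin_track],
    )
    def test_filters_idempotent(self, filt):
        rng = np.random.default_rng(1)
        day = 86400
        offs = np.sort(rng.choice(np.arange(0, 5 * day, 30), size=200, replace=False))
        tr = make_track(
            offs,
            elevation=rng.choice([-10.0, 50.0], size=200),
            ehpe=rng.choice([3.0, 6000.0], size=200),
            download_dates={dt.date(2021, 5, 2)},
        )
        once = filt(tr)
        twice = filt(once)
        pd.testing.assert_frame_equal(once.fixes, twice.fixes)


class TestThinning:
    def test_single_fix_unchanged(self):
        tr = make_track([0])
        assert thin_track(tr).n_fixes == 1

    def test_greedy_scan_small(self):
        tr = make_track([0, 30, 60, 150])
        out = thin_track(tr)
        assert list(out.times_s()) == [0.0, 150.0]

    def test_greedy_scan_30s_over_10min(self):
        tr = make_track([30 * i for i in range(21)])
        out = thin_track(tr)
        assert list(out.times_s()) == [0.0, 120.0, 240.0, 360.0, 480.0, 600.0]

    def test_intervals_at_least_min(self):
        rng = np.random.default_rng(2)
        offs = np.sort(rng.choice(np.arange(0, 86400, 7), size=500, replace=False))
        out = thin_track(make_track(offs), min_interval=120.0)
        assert np.all(np.diff(out.times_s()) >= 120.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        offsets=st.lists(
            st.integers(0, 2 * 86400), min_size=1, max_size=60, unique=True
        ),
        min_interval=st.integers(30, 900),
    )
    def test_thinning_invariants(self, offsets, min_interval):
        """First fix kept, all gaps >= threshold, re-thinning a no-op."""
        tr = make_track(sorted(offsets))
        out = thin_track(tr, float(min_interval))
        t = out.times_s()
        assert t[0] == 0.0
        assert np.all(np.diff(t) >= min_interval)
        again = thin_track(out, float(min_interval))
        assert list(again.times_s()) == list(t)


class TestCoverageAndWeight:
    def test_continuous_morning(self):
        tr = make_track(np.arange(0, 4 * 3600 + 30, 30))
        cov = daily_coverage(tr)
        assert len(cov) == 1
        assert cov[0].outdoor_hours == pytest.approx(4.0)

    def test_single_fix_day_counts_with_zero_hours(self):
        cov = daily_coverage(make_track([0]))
        assert len(cov) == 1 and cov[0].outdoor_hours == 0.0

    def test_gap_cap(self):
        cov = daily_coverage(make_track([0, 2 * 3600]))
        assert cov[0].outdoor_hours == pytest.approx(0.5)

    def test_total_coverage_below_span(self):
        rng = np.random.default_rng(3)
        offs = np.sort(rng.choice(np.arange(0, 3 * 86400, 60), size=400, replace=False))
        tr = make_track(offs)
        total = sum(c.outdoor_hours for c in daily_coverage(tr))
        assert total * 3600 <= offs[-1] - offs[0] + 1e-9

    def test_weight_values(self):
        c1 = daily_coverage(make_track(np.arange(0, 12 * 3600 + 1, 30)))
        assert outdoor_weight(c1).w == pytest.approx(0.5, abs=1e-3)
        day = 86400
        tr = make_track(
            list(np.arange(0, 6 * 3600 + 1, 30)) + list(day + np.arange(0, 12 * 3600 + 1, 30))
        )
        assert outdoor_weight(daily_coverage(tr)).w == pytest.approx(0.375, abs=1e-3)

    def test_weight_requires_data(self):
        with pytest.raises(ValueError):
            outdoor_weight([])
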