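"""EBD-style reading, inclusion filtering and range clipping."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st

from urbantol import (
    FilterConfig,
    clip_to_range,
    filter_checklists,
    load_range_geojson,
    read_checklists,
    resolve_counts,
    write_checklists,
)
from urbantol.exceptions import EmptyRangeError, SchemaError


def make_checklists(**overrides):
    base = dict(
        checklist_id=["C1"],
        lon=[1.0],
        lat=[1.0],
        date=[pd.Timestamp("2015-06-01")],
        time_started_min=[420.0],
        duration_min=[60.0],
        distance_km=[1.0],
        n_observers=[1],
        protocol=["Traveling"],
        complete=[True],
    )
    n = max(len(v) for v in overrides.values()) if overrides else 1
    for k, v in base.items():
        base[k] = v * n
    base.update(overrides)
    return pd.DataFrame(base)


class TestRead:
    def test_rows_grouped_by_checklist(self, tmp_path):
        path = tmp_path / "x.tsv"
        header = (
            "SAMPLING EVENT IDENTIFIER\tSPECIES CODE\tOBSERVATION COUNT\t"
            "LATITUDE\tLONGITUDE\tOBSERVATION DATE\tTIME OBSERVATIONS STARTED\t"
            "DURATION MINUTES\tEFFORT DISTANCE KM\tNUMBER OBSERVERS\t"
            "PROTOCOL TYPE\tALL SPECIES REPORTED"
        )
        row = "S1\t{sp}\t{cnt}\t2.0\t3.0\t2015-01-02\t07:30:00\t60\t1.5\t2\tTraveling\t1"
        lines = [header] + [
            row.format(sp=sp, cnt=c) for sp, c in [("a", "2"), ("b", "X"), ("c", "1")]
        ]
        path.write_text("\n".join(lines) + "\n")
        checklists, obs = read_checklists(path)
        assert len(checklists) == 1
        assert len(obs) == 3
        assert checklists.loc[0, "time_started_min"] == 450.0
        assert obs["presence_only"].tolist() == [False, True, False]

    def test_empty_file_with_header(self, tmp_path, filter_fixture_path):
        header = filter_fixture_path.read_text().splitlines()[0]
        path = tmp_path / "empty.tsv"
        path.write_text(header + "\n")
        checklists, obs = read_checklists(path)
        assert len(checklists) == 0 and len(obs) == 0

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("SAMPLING EVENT IDENTIFIER\tLATITUDE\nS1\t2.0\n")
        with pytest.raises(SchemaError, match="LONGITUDE"):
            read_checklists(path)

    def test_round_trip_preserves_fields(self, tmp_path, filter_fixture_path):
        checklists, obs = read_checklists(filter_fixture_path)
        out = tmp_path / "rt.tsv"
        write_checklists(checklists, obs, out)
        back_cl, back_obs = read_checklists(out)
        pd.testing.assert_frame_equal(
            checklists.sort_values("checklist_id").reset_index(drop=True),
            back_cl.sort_values("checklist_id").reset_index(drop=True),
            check_dtype=False,
        )
        assert back_obs["presence_only"].sum() == obs["presence_only"].sum()
        assert np.allclose(
            back_obs["count"].fillna(-1), obs["count"].fillna(-1)
        )

    def test_malformed_numeric_becomes_missing(self, tmp_path, filter_fixture_path):
        lines = filter_fixture_path.read_text().splitlines()
        broken = lines[1].split("\t")
        broken[7] = "sixty"  # DURATION MINUTES
        path = tmp_path / "m.tsv"
        path.write_text("\n".join([lines[0], "\t".join(broken)]) + "\n")
        checklists, _ = read_checklists(path)
        assert np.isnan(checklists.loc[0, "duration_min"])


class TestFilter:
    def test_duration_boundary(self):
        df = make_checklists(checklist_id=["A", "B"], duration_min=[300.0, 301.0])
        surv, rep = filter_checklists(df)
        assert surv["checklist_id"].tolist() == ["A"]
        assert rep.removed["duration"] == 1

    def test_distance_boundary(self):
        df = make_checklists(checklist_id=["A", "B"], distance_km=[5.0, 5.1])
        surv, rep = filter_checklists(df)
        assert surv["checklist_id"].tolist() == ["A"]
        assert rep.removed["distance"] == 1

    def test_incomplete_removed_regardless(self):
        df = make_checklists(complete=[False])
        surv, rep = filter_checklists(df)
        assert len(surv) == 0 and rep.removed["incomplete"] == 1

    def test_date_window_closed(self):
        df = make_checklists(
            checklist_id=["A", "B", "C", "D"],
            date=[
                pd.Timestamp("2010-01-01"),
                pd.Timestamp("2021-06-30"),
                pd.Timestamp("2009-12-31"),
                pd.Timestamp("2021-07-01"),
            ],
        )
        surv, rep = filter_checklists(df)
        assert surv["checklist_id"].tolist() == ["A", "B"]
        assert rep.removed["date_window"] == 2

    def test_missing_effort_logged_separately(self):
        df = make_checklists(
            checklist_id=["A", "B"],
            duration_min=[np.nan, 60.0],
            distance_km=[1.0, np.nan],
        )
        _, rep = filter_checklists(df)
        assert rep.removed["duration_missing"] == 1
        assert rep.removed["distance_missing"] == 1

    def test_idempotent(self):
        df = make_checklists(
            checklist_id=list("ABCDE"),
            duration_min=[60, 301, 60, 60, 60],
            complete=[True, True, False, True, True],
        )
        once, _ = filter_checklists(df)
        twice, rep2 = filter_checklists(once)
        pd.testing.assert_frame_equal(once, twice)
        assert rep2.n_retained == rep2.n_input

    def test_report_counts_sum_to_input(self):
        df = make_checklists(
            checklist_id=[f"C{i}" for i in range(8)],
            duration_min=[60, 301, np.nan, 60, 60, 60, 400, 60],
            distance_km=[1, 1, 1, 5.5, 1, 1, 9, 1],
            complete=[True, True, True, True, False, True, False, True],
        )
        surv, rep = filter_checklists(df)
        assert rep.n_input == 8
        assert sum(rep.removed.values()) + rep.n_retained == 8

    @settings(max_examples=30, deadline=None)
    @given(
        durations=st.lists(
            st.one_of(st.none(), st.floats(0, 600, allow_nan=False)),
            min_size=1,
            max_size=12,
        )
    )
    def test_survivors_satisfy_all_rules(self, durations):
        df = make_checklists(
            checklist_id=[f"C{i}" for i in range(len(durations))],
            duration_min=[np.nan if d is None else d for d in durations],
        )
        surv, rep = filter_checklists(df)
        assert (surv["duration_min"] <= 300).all()
        assert sum(rep.removed.values()) + rep.n_retained == len(df)


class TestClip:
    def square(self):
        return [shapely.box(0, 0, 10, 10)]

    def test_centroid_retained(self):
        df = make_checklists(lon=[5.0], lat=[5.0])
        assert len(clip_to_range(df, self.square())) == 1

    def test_outside_removed(self):
        df = make_checklists(lon=[11.0], lat=[5.0])
        assert len(clip_to_range(df, self.square())) == 0

    def test_boundary_counts_as_inside(self):
        df = make_checklists(lon=[10.0], lat=[5.0])
        assert len(clip_to_range(df, self.square())) == 1

    def test_empty_polygon_set_raises(self):
        df = make_checklists()
        with pytest.raises(EmptyRangeError):
            clip_to_range(df, [])

    def test_random_points_match_ray_casting_oracle(self, rng):
        # concave polygon to exercise the geometry
        poly = shapely.Polygon(
            [(0, 0), (10, 0), (10, 10), (5, 5), (0, 10)]
        )
        xs = rng.uniform(-2, 12, 1000)
        ys = rng.uniform(-2, 12, 1000)
        df = make_checklists(
            checklist_id=[f"C{i}" for i in range(1000)],
            lon=list(xs),
            lat=list(ys),
        )
        kept = set(clip_to_range(df, [poly])["checklist_id"])
        verts = np.asarray(poly.exterior.coords)
        for i in range(1000):
            inside = _ray_cast(verts, xs[i], ys[i])
            assert (f"C{i}" in kept) == inside

    def test_geojson_loader(self, range_square_path):
        polys = load_range_geojson(range_square_path)
        assert len(polys) == 1
        assert polys[0].area == pytest.approx(100.0)


def _ray_cast(verts, x, y):
    """Independent even-odd point-in-polygon oracle (boundary-safe via
    tiny offset: test points are random, never exactly on an edge)."""
    inside = False
    n = len(verts) - 1
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[i + 1]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


class TestResolveCounts:
    def test_presence_marker_as_one(self):
        obs = pd.DataFrame(
            {
                "checklist_id": ["A", "B"],
                "species_code": ["s", "s"],
                "count": [np.nan, 3.0],
                "presence_only": [True, False],
            }
        )
        out = resolve_counts(obs, "as_one")
        assert out["count"].tolist() == [1.0, 3.0]

    def test_presence_marker_dropped(self):
        obs = pd.DataFrame(
            {
                "checklist_id": ["A", "B"],
                "species_code": ["s", "s"],
                "count": [np.nan, 3.0],
                "presence_only": [True, False],
            }
        )
        out = resolve_counts(obs, "drop")
        assert out["checklist_id"].tolist() == ["B"]
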