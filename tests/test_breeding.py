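"""Incubation overlap, nest neighbourhoods and dispersal records."""
from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plovernet import breeding


def make_nests(rows):
    """Nests table from (nest_id, male, female, x, y, habitat, laid, end, success, year)."""
    return pd.DataFrame(
        rows,
        columns=[
            "nest_id", "male_id", "female_id", "x", "y", "habitat",
            "laid_date", "incubation_end", "success", "year",
        ],
    ).assign(
        laid_date=lambda d: pd.to_datetime(d.laid_date),
        incubation_end=lambda d: pd.to_datetime(d.incubation_end),
    )


class TestIncubationOverlap:
    def test_shared_boundary_day_overlaps(self):
        assert breeding.incubation_overlap(
            "2015-08-10", "2015-08-20", "2015-08-20", "2015-08-25"
        )

    def test_adjacent_intervals_do_not_overlap(self):
        assert not breeding.incubation_overlap(
            "2015-08-10", "2015-08-19", "2015-08-20", "2015-08-25"
        )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 60), st.integers(0, 30), st.integers(0, 60),
           st.integers(0, 30))
    def test_matches_day_set_intersection(self, s1, l1, s2, l2):
        base = date(2015, 8, 1)
        a = (base + timedelta(days=s1), base + timedelta(days=s1 + l1))
        b = (base + timedelta(days=s2), base + timedelta(days=s2 + l2))
        days_a = {a[0] + timedelta(days=k) for k in range(l1 + 1)}
        days_b = {b[0] + timedelta(days=k) for k in range(l2 + 1)}
        assert breeding.incubation_overlap(*a, *b) == bool(days_a & days_b)

    def test_reflexive_and_symmetric(self):
        a = ("2015-09-01", "2015-10-01")
        b = ("2015-09-20", "2015-10-15")
        assert breeding.incubation_overlap(*a, *a)
        assert breeding.incubation_overlap(*a, *b) == breeding.incubation_overlap(*b, *a)


class TestNestDistance:
    def test_identical_coordinates(self):
        a = pd.Series({"x": 5.0, "y": 5.0})
        assert breeding.nest_distance(a, a) == 0.0

    def test_three_four_five(self):
        a = pd.Series({"x": 0.0, "y": 0.0})
        b = pd.Series({"x": 3.0, "y": 4.0})
        assert breeding.nest_distance(a, b) == 5.0

    def test_matches_hypot_on_random_points(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            xa, ya, xb, yb = rng.uniform(-1e3, 1e3, 4)
            got = breeding.nest_distance(
                pd.Series({"x": xa, "y": ya}), pd.Series({"x": xb, "y": yb})
            )
            assert got == pytest.approx(np.hypot(xa - xb, ya - yb))

    def test_missing_coordinates_flagged(self):
        a = pd.Series({"x": np.nan, "y": 0.0})
        b = pd.Series({"x": 0.0, "y": 0.0})
        assert np.isnan(breeding.nest_distance(a, b))


class TestFocalContext:
    def base_rows(self):
        # focal N1 plus three temporally overlapping nests at 50, 150, 90 m
        return [
            ("N1", "M1", "F1", 0, 0, "saltmarsh", "2015-09-01", "2015-09-30", True, 2015),
            ("N2", "M2", "F2", 50, 0, "saltmarsh", "2015-09-05", "2015-09-25", True, 2015),
            ("N3", "M3", "F3", 150, 0, "saltmarsh", "2015-09-10", "2015-10-05", False, 2015),
            ("N4", "M4", "F4", 0, 90, "saltmarsh", "2015-08-20", "2015-09-02", True, 2015),
        ]

    def test_hand_computed_context(self):
        ctx = breeding.focal_context(make_nests(self.base_rows())).set_index("nest_id")
        f = ctx.loc["N1"]
        assert f.n_overlapping == 3
        assert f.min_dist_overlapping == 50.0
        assert f.mean_dist_overlapping == pytest.approx((50 + 150 + 90) / 3)
        assert f.n_overlapping_within_100m == 2
        # neighbours within 100 m: N2 (success) and N4 (success)
        assert f.prop_neighbours_successful == 1.0

    def test_no_overlap_gives_undefined_distances(self):
        rows = [
            ("N1", "M1", "F1", 0, 0, "saltmarsh", "2015-08-01", "2015-08-20", True, 2015),
            ("N2", "M2", "F2", 10, 0, "saltmarsh", "2015-10-01", "2015-10-20", True, 2015),
        ]
        ctx = breeding.focal_context(make_nests(rows)).set_index("nest_id")
        assert ctx.loc["N1", "n_overlapping"] == 0
        assert np.isnan(ctx.loc["N1", "mean_dist_overlapping"])
        assert np.isnan(ctx.loc["N1", "prop_neighbours_successful"])

    def test_own_pair_nests_excluded(self):
        rows = self.base_rows()
        # same female as focal: must not count as neighbour
        rows[1] = ("N2", "M9", "F1", 50, 0, "saltmarsh", "2015-09-05",
                   "2015-09-25", True, 2015)
        ctx = breeding.focal_context(make_nests(rows)).set_index("nest_id")
        assert ctx.loc["N1", "n_overlapping"] == 2

    def test_julian_standardisation(self):
        ctx = breeding.focal_context(make_nests(self.base_rows()))
        assert ctx.julian_std.std(ddof=1) == pytest.approx(1.0)
        assert ctx.julian_std.mean() == pytest.approx(0.0, abs=1e-12)

    def test_mean_at_least_min(self, small_sim):
        ctx = breeding.focal_context(small_sim.nests)
        has = ctx.n_overlapping >= 1
        assert (
            ctx.loc[has, "mean_dist_overlapping"]
            >= ctx.loc[has, "min_dist_overlapping"] - 1e-12
        ).all()
        assert (ctx.n_overlapping_within_100m <= ctx.n_overlapping).all()

    def test_removing_a_nest_never_increases_overlap_counts(self, small_sim):
        nests = small_sim.nests[small_sim.nests.year == small_sim.nests.year.min()]
        full = breeding.focal_context(nests).set_index("nest_id")
        drop = nests.nest_id.iloc[0]
        reduced = breeding.focal_context(
            nests[nests.nest_id != drop]
        ).set_index("nest_id")
        for nid in reduced.index:
            assert reduced.loc[nid, "n_overlapping"] <= full.loc[nid, "n_overlapping"]


class TestDispersal:
    def two_year_rows(self):
        return [
            ("N1", "M1", "F1", 0, 0, "saltmarsh", "2015-09-01", "2015-09-30", True, 2015),
            ("N2", "M1", "F1", 30, 40, "saltmarsh", "2016-09-01", "2016-09-30", True, 2016),
            ("N3", "M2", "F2", 0, 0, "grassland", "2015-09-01", "2015-09-30", False, 2015),
            ("N4", "M2", "F2", 500, 0, "semi-desert", "2016-09-01", "2016-09-30", True, 2016),
        ]

    def test_stay_and_disperse_flags(self):
        recs = breeding.dispersal_records(make_nests(self.two_year_rows()))
        recs = recs.set_index("individual_id")
        assert bool(recs.loc["M1", "stayed_same_habitat"])
        assert recs.loc["M1", "distance_m"] == pytest.approx(50.0)
        assert not bool(recs.loc["M2", "stayed_same_habitat"])
        assert recs.loc["M2", "prev_success"] == False  # noqa: E712

    def test_non_consecutive_years_skipped(self):
        rows = [
            ("N1", "M1", "F1", 0, 0, "saltmarsh", "2015-09-01", "2015-09-30", True, 2015),
            ("N2", "M1", "F1", 0, 0, "saltmarsh", "2017-09-01", "2017-09-30", True, 2017),
        ]
        assert breeding.dispersal_records(make_nests(rows)).empty

    def test_first_only_keeps_first_transition(self):
        rows = self.two_year_rows() + [
            ("N5", "M1", "F1", 0, 0, "grassland", "2017-09-01", "2017-09-30", True, 2017),
        ]
        all_recs = breeding.dispersal_records(make_nests(rows))
        first = breeding.dispersal_records(make_nests(rows), first_only=True)
        assert (all_recs.individual_id == "M1").sum() == 2
        m1 = first[first.individual_id == "M1"]
        assert len(m1) == 1 and m1.year_from.iloc[0] == 2015

    def test_summary_counts(self):
        recs = breeding.dispersal_records(make_nests(self.two_year_rows()))
        s = breeding.dispersal_summary(recs)
        assert s["by_prev_success"][True] == (2, 2)   # M1, F1 stayed
        assert s["by_prev_success"][False] == (0, 2)  # M2, F2 moved
        assert s["by_prev_habitat"]["grassland"] == (0, 2)
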