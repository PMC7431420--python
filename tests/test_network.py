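"""Chain-rule grouping, SRI edges and node metrics."""
from datetime import date
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plovernet import network
from plovernet.network import (
    GroupAssignment,
    assign_groups,
    build_network,
    compute_sri,
    deduplicate_sightings,
    filter_prebreeding,
    node_metrics,
)
from conftest import make_period


def brute_force_groups(xy: np.ndarray, threshold: float) -> list[set[int]]:
    """Independent oracle: union-find over all pairs within threshold."""
    n = len(xy)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, j in combinations(range(n), 2):
        if np.hypot(*(xy[i] - xy[j])) <= threshold:
            parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())


class TestDeduplicate:
    def test_duplicates_collapse_to_mean_coordinate(self):
        df = pd.concat(
            [make_period({"M1": (0, 0)}), make_period({"M1": (10, 0)})],
            ignore_index=True,
        )
        out = deduplicate_sightings(df)
        assert len(out) == 1
        assert out.x.iloc[0] == 5.0 and out.y.iloc[0] == 0.0

    def test_no_duplicates_is_identity(self):
        df = make_period({"M1": (0, 0), "F1": (5, 5)})
        out = deduplicate_sightings(df)
        pd.testing.assert_frame_equal(
            out.sort_values("individual_id").reset_index(drop=True),
            df.sort_values("individual_id").reset_index(drop=True),
        )

    def test_conflicting_sex_rejected(self):
        df = make_period({"M1": (0, 0)})
        df2 = make_period({"M1": (1, 1)}, period_id="P2")
        df2.loc[:, "sex"] = "F"
        with pytest.raises(ValueError, match="M1"):
            deduplicate_sightings(pd.concat([df, df2], ignore_index=True))


class TestFilterPrebreeding:
    def make(self, dates, year=2015):
        rows = []
        for i, d in enumerate(dates):
            rows.append(
                {
                    "individual_id": f"M{i}",
                    "sex": "M",
                    "date": pd.Timestamp(d),
                    "period_id": f"P{i}",
                    "x": 0.0,
                    "y": 0.0,
                    "habitat": "saltmarsh",
                    "year": year,
                }
            )
        return pd.DataFrame(rows)

    def test_exclusion_window_boundaries(self):
        season = {2015: date(2015, 8, 1)}
        df = self.make(["2015-07-19", "2015-07-17"])  # 13 and 15 days before
        out = filter_prebreeding(df, season, exclusion_days=14)
        assert list(out.individual_id) == ["M1"]

    def test_drop_may_removes_exactly_may_rows(self):
        season = {2015: date(2015, 8, 1)}
        df = self.make(["2015-04-30", "2015-05-01", "2015-05-31", "2015-06-01"])
        kept = set(
            filter_prebreeding(df, season, drop_may=True).individual_id
        )
        expected = set(df.individual_id) - set(
            df[pd.to_datetime(df.date).dt.month == 5].individual_id
        )
        assert kept == expected

    def test_missing_season_start_errors(self):
        with pytest.raises(ValueError, match="2015"):
            filter_prebreeding(self.make(["2015-03-01"]), {2014: date(2014, 8, 1)})


class TestAssignGroups:
    def test_two_birds_beyond_chain_distance(self):
        ga = assign_groups(make_period({"M1": (0, 0), "M2": (25, 0)}))
        assert len(ga.groups) == 2

    def test_chain_links_distant_ends(self):
        ga = assign_groups(
            make_period({"A": (0, 0), "B": (15, 0), "C": (30, 0)})
        )
        assert ga.groups == (frozenset({"A", "B", "C"}),)

    def test_single_bird_singleton_group(self):
        ga = assign_groups(make_period({"M1": (3, 4)}))
        assert ga.groups == (frozenset({"M1"}),)

    def test_boundary_inclusive_vs_exclusive(self):
        df = make_period({"A": (0, 0), "B": (20, 0)})
        assert len(assign_groups(df, inclusive=True).groups) == 1
        assert len(assign_groups(df, inclusive=False).groups) == 2

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(2, 50)
            xy = rng.uniform(0, 120, size=(n, 2))
            df = make_period({f"B{i:02d}": tuple(xy[i]) for i in range(n)})
            got = {g for g in assign_groups(df).groups}
            want = {
                frozenset(f"B{i:02d}" for i in g)
                for g in brute_force_groups(xy, 20.0)
            }
            assert got == want


def make_assignments(periods: list[list[list[str]]]) -> list[GroupAssignment]:
    return [
        GroupAssignment(
            period_id=f"P{k}", groups=tuple(frozenset(g) for g in grps)
        )
        for k, grps in enumerate(periods)
    ]


class TestSRI:
    def test_always_together_gives_one(self):
        asg = make_assignments([[["A", "B"]]] * 5)
        assert compute_sri(asg, ("A", "B")) == 1.0

    def test_hand_evaluated_formula(self):
        # x=2 together, y_AB=1 both-seen-apart, y_A=3, y_B=2
        asg = make_assignments(
            [[["A", "B"]]] * 2
            + [[["A"], ["B"]]]
            + [[["A"]]] * 3
            + [[["B"]]] * 2
        )
        assert compute_sri(asg, ("A", "B")) == pytest.approx(2 / 8)

    def test_never_together_gives_zero(self):
        asg = make_assignments([[["A"]]] * 4)
        assert compute_sri(asg, ("A", "B")) == 0.0

    def test_symmetric_and_order_invariant(self):
        asg = make_assignments(
            [[["A", "B"], ["C"]], [["A"], ["B", "C"]], [["C"]]]
        )
        ab = compute_sri(asg, ("A", "B"))
        assert ab == compute_sri(asg, ("B", "A"))
        assert compute_sri(list(reversed(asg)), ("A", "B")) == ab

    def test_unseen_period_leaves_sri_unchanged(self):
        asg = make_assignments([[["A", "B"]], [["A"], ["B"]]])
        with_extra = asg + make_assignments([[["C", "D"]]])
        assert compute_sri(asg, ("A", "B")) == compute_sri(
            with_extra, ("A", "B")
        )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(
        st.lists(st.sampled_from(["A", "B", "C", "D"]), min_size=1, max_size=4,
                 unique=True),
        min_size=1, max_size=12,
    ))
    def test_sri_in_unit_interval(self, period_members):
        # each period: its members split into one group (all associated)
        asg = make_assignments([[m] for m in period_members])
        val = compute_sri(asg, ("A", "B"))
        assert 0.0 <= val <= 1.0


class TestBuildNetwork:
    def test_full_cogrouping_gives_density_one(self):
        df = pd.concat(
            [
                make_period(
                    {"M1": (0, 0), "M2": (5, 0), "F1": (10, 0), "F2": (15, 0)},
                    period_id=f"P{k}",
                )
                for k in range(3)
            ],
            ignore_index=True,
        )
        g = build_network(df, 2015)
        assert g.graph["density"] == 1.0

    def test_density_formula(self, small_bundle):
        for g in small_bundle.networks.values():
            n, e = g.number_of_nodes(), g.number_of_edges()
            assert g.graph["density"] == pytest.approx(2 * e / (n * (n - 1)))

    def test_nodes_are_all_sighted_individuals(self, small_bundle):
        year = small_bundle.network_years[0]
        sub = small_bundle.sightings[small_bundle.sightings.year == year]
        assert set(small_bundle.networks[year].nodes) == set(sub.individual_id)

    def test_degree_sum_equals_twice_edges(self, small_bundle):
        for g in small_bundle.networks.values():
            assert sum(d for _, d in g.degree()) == 2 * g.number_of_edges()


class TestNodeMetrics:
    def test_isolated_node(self):
        df = make_period({"M1": (0, 0), "M2": (500, 500)})
        m = node_metrics(build_network(df, 2015)).set_index("individual_id")
        assert m.loc["M1", "degree"] == 0
        assert m.loc["M1", "strength"] == 0.0
        assert np.isnan(m.loc["M1", "prop_male_associates"])

    def test_hand_summed_metrics(self):
        import networkx as nx

        g = nx.Graph(year=2015)
        g.add_node("F1", sex="F")
        g.add_node("M1", sex="M")
        g.add_node("F2", sex="F")
        g.add_edge("F1", "M1", sri=0.5)
        g.add_edge("F1", "F2", sri=0.25)
        m = node_metrics(g).set_index("individual_id")
        assert m.loc["F1", "degree"] == 2
        assert m.loc["F1", "strength"] == pytest.approx(0.75)
        assert m.loc["F1", "prop_male_associates"] == pytest.approx(0.5)

    def test_strength_never_exceeds_degree(self, small_bundle):
        for g in small_bundle.networks.values():
            m = node_metrics(g)
            assert (m.strength <= m.degree + 1e-12).all()
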