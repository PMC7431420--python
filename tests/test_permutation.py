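"""Randomisation schemes, conserved quantities and permutation p-values."""
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from plovernet import permutation
from plovernet.network import GroupAssignment
from plovernet.permutation import (
    datastream_randomise,
    mate_randomise,
    nest_randomise,
    pvalue_two_tailed,
    run_permutation_test,
)


def ga(period, groups):
    return GroupAssignment(period, tuple(frozenset(g) for g in groups))


class TestDatastream:
    def test_single_singleton_group_unchanged(self):
        asg = [ga("P1", [["A"]])]
        out = datastream_randomise(asg, np.random.default_rng(0))
        assert out[0] == asg[0]

    def test_who_is_alone_uniform(self):
        """Groups {2,1}: each of the 3 'alone' outcomes occurs ~1/3."""
        asg = [ga("P1", [["A", "B"], ["C"]])]
        rng = np.random.default_rng(1)
        counts = Counter()
        n = 6000
        for _ in range(n):
            out = datastream_randomise(asg, rng)[0]
            alone = next(iter(g for g in out.groups if len(g) == 1))
            counts[next(iter(alone))] += 1
        for ind in "ABC":
            assert abs(counts[ind] / n - 1 / 3) < 0.03

    def test_conserved_quantities(self):
        asg = [
            ga("P1", [["A", "B", "C"], ["D"]]),
            ga("P2", [["A", "D"], ["E", "F"], ["G"]]),
        ]
        rng = np.random.default_rng(2)
        for _ in range(200):
            out = datastream_randomise(asg, rng)
            for before, after in zip(asg, out):
                assert sorted(len(g) for g in before.groups) == sorted(
                    len(g) for g in after.groups
                )
                assert before.individuals == after.individuals


class TestMateRandomise:
    def pairs(self):
        return pd.DataFrame(
            {
                "male_id": ["M1", "M2", "M3", "M4"],
                "female_id": ["F1", "F2", "F3", "F4"],
                "year": [2015, 2015, 2015, 2016],
                "habitat": ["a", "a", "b", "a"],
            }
        )

    def test_single_pair_stratum_is_identity(self):
        out = mate_randomise(self.pairs(), np.random.default_rng(0),
                             stratum=("year", "habitat"))
        # strata (2015,b) and (2016,a) have one pair each
        assert out.loc[2, "female_id"] == "F3"
        assert out.loc[3, "female_id"] == "F4"

    def test_two_pair_stratum_swaps_half_the_time(self):
        rng = np.random.default_rng(3)
        swapped = 0
        n = 1000
        for _ in range(n):
            out = mate_randomise(self.pairs(), rng, stratum=("year", "habitat"))
            if out.loc[0, "female_id"] == "F2":
                swapped += 1
        assert abs(swapped / n - 0.5) < 0.05

    def test_multisets_preserved(self):
        rng = np.random.default_rng(4)
        p = self.pairs()
        for _ in range(100):
            out = mate_randomise(p, rng, stratum=("year",))
            assert Counter(zip(out.male_id, out.year)) == Counter(
                zip(p.male_id, p.year)
            )
            assert Counter(zip(out.female_id, out.year)) == Counter(
                zip(p.female_id, p.year)
            )


class TestNestRandomise:
    def nests(self):
        rng = np.random.default_rng(5)
        n = 12
        return pd.DataFrame(
            {
                "nest_id": [f"N{i}" for i in range(n)],
                "male_id": [f"M{i}" for i in range(n)],
                "female_id": [f"F{i}" for i in range(n)],
                "x": rng.uniform(0, 1000, n),
                "y": rng.uniform(0, 1000, n),
                "habitat": ["a"] * 5 + ["b"] * 4 + ["c"] * 3,
                "laid_date": pd.to_datetime(["2015-09-01"] * n)
                + pd.to_timedelta(rng.integers(0, 40, n), unit="D"),
                "incubation_end": pd.to_datetime(["2015-10-05"] * n)
                + pd.to_timedelta(rng.integers(0, 20, n), unit="D"),
                "success": [True, False] * 6,
                "year": [2015] * n,
            }
        )

    def test_singleton_stratum_unchanged(self):
        nests = self.nests()
        single = nests[nests.habitat == "c"].iloc[:1]
        out = nest_randomise(pd.concat([single]), np.random.default_rng(0))
        pd.testing.assert_frame_equal(out.reset_index(drop=True),
                                      single.reset_index(drop=True))

    def test_tuples_never_cross_habitat(self):
        nests = self.nests()
        locs_by_hab = {
            h: set(zip(g.x, g.y)) for h, g in nests.groupby("habitat")
        }
        rng = np.random.default_rng(6)
        for _ in range(100):
            out = nest_randomise(nests, rng)
            for h, g in out.groupby("habitat"):
                assert set(zip(g.x, g.y)) == locs_by_hab[h]

    def test_within_stratum_distance_multiset_preserved(self):
        from scipy.spatial.distance import pdist

        nests = self.nests()
        rng = np.random.default_rng(7)
        out = nest_randomise(nests, rng)
        for h in "abc":
            before = np.sort(pdist(nests[nests.habitat == h][["x", "y"]]))
            after = np.sort(pdist(out[out.habitat == h][["x", "y"]]))
            np.testing.assert_allclose(before, after)

    def test_success_stays_with_pair_row(self):
        nests = self.nests()
        out = nest_randomise(nests, np.random.default_rng(8))
        pd.testing.assert_series_equal(out.success, nests.success)
        pd.testing.assert_series_equal(out.male_id, nests.male_id)


class TestPValue:
    def test_observed_beats_all_nulls(self):
        nulls = np.zeros(9999)
        assert pvalue_two_tailed(1.0, nulls) == pytest.approx(2 / 10000)

    def test_observed_equal_to_all_nulls_capped_at_one(self):
        assert pvalue_two_tailed(0.5, np.full(100, 0.5)) == 1.0

    def test_hand_counted_five_element_null(self):
        nulls = [-2, -1, 0, 1, 2]
        assert pvalue_two_tailed(2.0, nulls) == pytest.approx(2 * (2 / 6))

    def test_never_zero_and_never_above_one(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            nulls = rng.normal(size=rng.integers(1, 40))
            p = pvalue_two_tailed(float(rng.normal()), nulls)
            assert 0.0 < p <= 1.0

    def test_deviation_method(self):
        nulls = [0.0, 0.0, 0.0, 10.0]
        # mean 2.5; |obs-2.5|=7.5 matched only by the 10.0 null
        assert pvalue_two_tailed(10.0, nulls, method="deviation") == pytest.approx(2 / 5)

    def test_non_finite_observed_rejected(self):
        with pytest.raises(ValueError):
            pvalue_two_tailed(float("nan"), [0.0, 1.0])


class TestRunPermutationTest:
    def test_constant_statistic_gives_p_one(self):
        res = run_permutation_test(
            lambda d: 1.0, lambda d, rng: d, None, n_perm=50, seed=0
        )
        assert res.p_two_tailed == 1.0

    def test_reproducible_from_seed(self):
        def stat(d):
            return float(np.sum(d))

        def rand(d, rng):
            return rng.permutation(d) * rng.choice([-1, 1])

        data = np.arange(5.0)
        a = run_permutation_test(stat, rand, data, n_perm=100, seed=7)
        b = run_permutation_test(stat, rand, data, n_perm=100, seed=7)
        assert a.observed == b.observed
        np.testing.assert_array_equal(a.null_values, b.null_values)
        assert a.p_two_tailed == b.p_two_tailed

    def test_excess_failures_abort(self):
        calls = {"n": 0}

        def stat(d):
            calls["n"] += 1
            if calls["n"] > 1:  # fail every replicate, keep observed fine
                raise RuntimeError("boom")
            return 0.0

        with pytest.raises(RuntimeError, match="unreliable"):
            run_permutation_test(stat, lambda d, rng: d, None, n_perm=20, seed=0)

    def test_super_uniform_under_exchangeable_null(self):
        """With the observed drawn from the null, p is super-uniform."""
        rng_data = np.random.default_rng(11)
        ps = []
        for k in range(200):
            data = rng_data.normal(size=12)

            def stat(d):
                return float(d[0])

            res = run_permutation_test(
                stat, lambda d, rng: rng.permutation(d), data,
                n_perm=60, seed=k,
            )
            ps.append(res.p_two_tailed)
        ps = np.asarray(ps)
        for alpha in (0.05, 0.1, 0.25):
            assert np.mean(ps <= alpha) <= alpha + 0.05
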