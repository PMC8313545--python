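"""Bipartite network construction and metric oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fieldmargins.anova import oneway
from fieldmargins.errors import ConfigError, EmptyInputError
from fieldmargins.networks import (build_network, compare_by_median,
                                   connectance, from_edge_list,
                                   interaction_evenness, nodf, robustness,
                                   to_edge_list)


def nodf_brute_force(B):
    """Independent NODF oracle via explicit set logic per line pair."""
    B = np.asarray(B) > 0
    sets_r = [set(np.flatnonzero(row)) for row in B]
    sets_c = [set(np.flatnonzero(col)) for col in B.T]

    def paired(sets):
        vals, pairs = [], 0
        for a, b in itertools.combinations(range(len(sets)), 2):
            pairs += 1
            hi, lo = sets[a], sets[b]
            if len(hi) < len(lo):
                hi, lo = lo, hi
            if len(hi) == len(lo) or len(lo) == 0:
                vals.append(0.0)
            else:
                vals.append(100.0 * len(hi & lo) / len(lo))
        return sum(vals), pairs

    sr, nr = paired(sets_r)
    sc, nc = paired(sets_c)
    if nr + nc == 0:
        return float("nan")
    return (sr + sc) / (nr + nc)


def robustness_exhaustive(W, level="lower"):
    """Average extinction-curve area over every removal order."""
    B = np.asarray(W) > 0
    if level == "higher":
        B = B.T
    n_t, n_o = B.shape
    areas = []
    x = np.arange(n_t + 1) / n_t
    for order in itertools.permutations(range(n_t)):
        y = []
        for k in range(n_t):
            remaining = B[list(order[k:])]
            y.append(remaining.any(axis=0).sum() / n_o)
        y.append(0.0)
        areas.append(np.trapezoid(y, x))
    return float(np.mean(areas))


class TestBuildNetwork:
    def _visits(self, rows):
        return pd.DataFrame(rows, columns=["site_id", "stage",
                                           "visitor_guild", "plant_species",
                                           "visits"])

    def test_aggregation(self):
        v = self._visits([("s", "flowering", "g1", "pA", 2),
                          ("s", "flowering", "g1", "pB", 1),
                          ("s", "flowering", "g2", "pA", 4)])
        net = build_network(v, "s")
        assert net.plants == ["pA", "pB"]
        assert net.visitors == ["g1", "g2"]
        assert net.W.tolist() == [[2, 4], [1, 0]]

    def test_duplicates_summed(self):
        v = self._visits([("s", "flowering", "g1", "pA", 2),
                          ("s", "podding", "g1", "pA", 3)])
        net = build_network(v, "s")
        assert net.W.tolist() == [[5]]

    def test_empty_site_raises(self):
        with pytest.raises(EmptyInputError):
            build_network(self._visits([]), "s")

    def test_edge_list_round_trip(self):
        v = self._visits([("s", "flowering", "g1", "pA", 2),
                          ("s", "flowering", "g2", "pB", 7),
                          ("s", "flowering", "g1", "pB", 1)])
        net = build_network(v, "s")
        back = from_edge_list(to_edge_list(net), "s")
        assert back.plants == net.plants
        assert back.visitors == net.visitors
        assert np.array_equal(back.W, net.W)


class TestSimpleMetrics:
    def test_full_matrix_connectance_one(self):
        assert connectance(np.ones((3, 4))) == 1.0

    def test_identity_connectance_half(self):
        assert connectance(np.eye(2)) == 0.5

    def test_uniform_evenness_is_one(self):
        assert interaction_evenness(np.full((3, 3), 5.0)) == pytest.approx(1)

    def test_single_cell_evenness_missing(self):
        assert math.isnan(interaction_evenness(np.array([[4.0]])))


class TestNODF:
    def test_identity_two_by_two_is_zero(self):
        # equal marginal totals contribute nothing
        assert nodf(np.eye(2)) == 0.0

    def test_nested_two_by_two_is_hundred(self):
        assert nodf(np.array([[1, 1], [1, 0]])) == 100.0

    @given(st.integers(1, 6), st.integers(1, 6), st.integers(0, 10 ** 6))
    @settings(max_examples=100)
    def test_matches_brute_force(self, nr, nc, seed):
        rng = np.random.default_rng(seed)
        W = rng.integers(0, 2, size=(nr, nc))
        got = nodf(W)
        exp = nodf_brute_force(W)
        if math.isnan(exp):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(exp, abs=1e-9)
            assert 0.0 <= got <= 100.0


class TestRobustness:
    def test_single_link_network_is_half(self):
        assert robustness(np.array([[3]]), n_reps=5, seed=0) == 0.5

    def test_one_to_one_specialists_exact_half(self):
        # every removal order gives the same linear curve
        for n in (2, 3, 4):
            assert robustness_exhaustive(np.eye(n)) == pytest.approx(0.5)
            mc = robustness(np.eye(n), n_reps=300, seed=1)
            assert mc == pytest.approx(0.5, abs=1e-9)

    def test_generalist_plant_matches_exhaustive_orders(self):
        # plant 0 visits all three guilds; plants 1-2 are specialists
        W = np.array([[1, 1, 1], [1, 0, 0], [0, 1, 0]])
        exact = robustness_exhaustive(W, "lower")
        mc = robustness(W, "lower", n_reps=4000, seed=7)
        assert mc == pytest.approx(exact, abs=0.01)

    def test_higher_level_removal(self):
        W = np.array([[1, 1], [0, 1]])
        exact = robustness_exhaustive(W, "higher")
        mc = robustness(W, "higher", n_reps=4000, seed=3)
        assert mc == pytest.approx(exact, abs=0.01)

    def test_adding_a_link_never_hurts_opposite_level(self):
        base = np.eye(4)
        r0 = robustness_exhaustive(base, "lower")
        richer = base.copy()
        richer[0, 1] = 1
        assert robustness_exhaustive(richer, "lower") >= r0

    def test_invalid_reps_rejected(self):
        with pytest.raises(ConfigError):
            robustness(np.eye(2), n_reps=0)


class TestMedianComparison:
    def _frames(self, values, feature):
        metrics = pd.DataFrame({"site_id": [f"s{i}" for i in range(len(values))],
                                "connectance": values})
        features = pd.DataFrame({"site_id": metrics["site_id"],
                                 "Trees": feature})
        return metrics, features

    def test_identical_groups_give_zero_f(self):
        m, f = self._frames([0.5] * 8, [0, 0, 0, 0, 3, 3, 3, 3])
        out = compare_by_median(m, f, "Trees", metric_cols=["connectance"])
        assert out.loc[0, "F"] == pytest.approx(0.0)

    def test_separated_groups_detected(self, rng):
        lo = rng.normal(0, 1, 20)
        hi = rng.normal(3, 1, 20)
        m, f = self._frames(np.concatenate([lo, hi]),
                            [0] * 20 + [5] * 20)
        out = compare_by_median(m, f, "Trees", metric_cols=["connectance"])
        assert out.loc[0, "p"] < 0.001
        assert out.loc[0, "F"] > 20

    def test_median_ties_go_below(self):
        m, f = self._frames([1, 2, 3, 4], [1, 2, 2, 3])
        out = compare_by_median(m, f, "Trees", metric_cols=["connectance"])
        # median Trees = 2; the two ties join "below" -> 3 below, 1 above
        assert out.loc[0, "n_below"] == 3
        assert out.loc[0, "n_above"] == 1
        assert np.isnan(out.loc[0, "F"])  # skipped: above group too small
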