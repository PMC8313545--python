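"""Co-occurrence statistic, exclusion rules and top-fraction selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fieldmargins.cooccurrence import (apply_exclusions, cooccurrence_table,
                                       select_top, shortlist)
from fieldmargins.errors import AlignmentError


def _mat(rows, names=None, n=None):
    """Binary presence matrix from lists of occupied point indices."""
    n = n or (max(max(r) for r in rows if r) + 1)
    data = np.zeros((len(rows), n), dtype=int)
    for i, r in enumerate(rows):
        data[i, list(r)] = 1
    names = names or [f"e{i}" for i in range(len(rows))]
    cols = pd.MultiIndex.from_tuples([("s", "margin", j + 1) for j in range(n)],
                                     names=["site_id", "transect",
                                            "point_index"])
    return pd.DataFrame(data, index=names, columns=cols)


def brute_force_stats(plant_pts, guild_pts, n):
    """Independent oracle: enumerate points as sets."""
    p, g = set(plant_pts), set(guild_pts)
    P_plant = len(p) / n
    P_ins = len(g) / n
    P_c = len(p & g) / n
    return P_plant, P_ins, P_c, P_plant * P_ins


class TestStatistic:
    def test_hand_enumerated_example(self):
        # plant at points {1..4}, guild at {3..6} of 10
        plants = _mat([range(0, 4)], ["p"], n=10)
        guilds = _mat([range(2, 6)], ["g"], n=10)
        t = cooccurrence_table(plants, guilds).iloc[0]
        assert t["P_plant"] == pytest.approx(0.4)
        assert t["P_ins"] == pytest.approx(0.4)
        assert t["P_c"] == pytest.approx(0.2)
        assert t["P_pred"] == pytest.approx(0.16)
        assert t["excess"] == pytest.approx(0.04)

    def test_both_ubiquitous(self):
        plants = _mat([range(6)], ["p"], n=6)
        guilds = _mat([range(6)], ["g"], n=6)
        t = cooccurrence_table(plants, guilds).iloc[0]
        assert t["P_c"] == t["P_pred"] == 1.0
        assert t["excess"] == 0.0

    def test_disjoint_occupancy(self):
        plants = _mat([range(0, 3)], ["p"], n=10)
        guilds = _mat([range(5, 8)], ["g"], n=10)
        t = cooccurrence_table(plants, guilds).iloc[0]
        assert t["P_c"] == 0.0
        assert t["excess"] == pytest.approx(-t["P_pred"])

    def test_mismatched_points_raise(self):
        plants = _mat([range(3)], ["p"], n=5)
        guilds = _mat([range(3)], ["g"], n=6)
        with pytest.raises(AlignmentError):
            cooccurrence_table(plants, guilds)

    @given(st.integers(2, 10), st.integers(1, 6), st.integers(1, 4),
           st.integers(0, 10 ** 6))
    @settings(max_examples=60)
    def test_matches_set_enumeration(self, n, n_plants, n_guilds, seed):
        rng = np.random.default_rng(seed)
        P = rng.integers(0, 2, size=(n_plants, n))
        G = rng.integers(0, 2, size=(n_guilds, n))
        plants = _mat([np.flatnonzero(r) for r in P], n=n)
        guilds = _mat([np.flatnonzero(r) for r in G],
                      [f"g{i}" for i in range(n_guilds)], n=n)
        table = cooccurrence_table(plants, guilds).set_index(
            ["plant_species", "guild"])
        for i in range(n_plants):
            for j in range(n_guilds):
                exp = brute_force_stats(np.flatnonzero(P[i]),
                                        np.flatnonzero(G[j]), n)
                row = table.loc[(f"e{i}", f"g{j}")]
                got = (row["P_plant"], row["P_ins"], row["P_c"],
                       row["P_pred"])
                assert got == pytest.approx(exp, abs=1e-12)


class TestExclusions:
    def _table(self, plant_rows, n):
        plants = _mat(plant_rows, n=n)
        guilds = _mat([range(0, n, 2)], ["g"], n=n)
        t = cooccurrence_table(plants, guilds)
        return apply_exclusions(t, plants), plants

    def test_single_occurrence_excluded(self):
        t, _ = self._table([[0]], 20)
        assert t.iloc[0]["exclusion_reason"] == "single_occurrence"
        assert t.iloc[0]["excluded"]

    def test_ubiquitous_excluded(self):
        t, _ = self._table([range(20)], 20)
        assert t.iloc[0]["exclusion_reason"] == "ubiquitous"

    def test_two_occurrences_retained(self):
        t, _ = self._table([[0, 7]], 20)
        assert not t.iloc[0]["excluded"]


class TestSelection:
    def _ranked_table(self, n_plants, n=40, seed=0):
        rng = np.random.default_rng(seed)
        rows = [np.flatnonzero(rng.integers(0, 2, n)) for _ in range(n_plants)]
        rows = [r if 1 < len(r) < n else [0, 1] for r in rows]
        plants = _mat(rows, n=n)
        guilds = _mat([range(0, n, 3)], ["g"], n=n)
        t = apply_exclusions(cooccurrence_table(plants, guilds), plants)
        return t

    def test_top_count_rounds_half_up_with_floor_one(self):
        t40 = select_top(self._ranked_table(40), fraction=0.05)
        assert t40["selected_top"].sum() == 2
        t10 = select_top(self._ranked_table(10), fraction=0.05)
        assert t10["selected_top"].sum() == 1

    def test_selected_are_highest_excess(self):
        t = select_top(self._ranked_table(20), fraction=0.05)
        sel = t[t["selected_top"]]["excess"].min()
        rest = t[~t["selected_top"] & ~t["excluded"]]["excess"].max()
        assert sel >= rest

    def test_excluded_never_selected(self):
        plants = _mat([[0], list(range(20)), [1, 5]], n=20)
        guilds = _mat([range(0, 20, 2)], ["g"], n=20)
        t = select_top(apply_exclusions(cooccurrence_table(plants, guilds),
                                        plants))
        assert not (t["excluded"] & t["selected_top"]).any()
        # only the retained plant can be selected
        assert set(t[t["selected_top"]]["plant_species"]) == {"e2"}

    def test_tie_break_is_deterministic(self):
        # two plants with identical excess: higher P_c first, then name
        plants = _mat([[0, 1], [0, 1]], ["b_plant", "a_plant"], n=4)
        guilds = _mat([[0, 1]], ["g"], n=4)
        t = select_top(apply_exclusions(cooccurrence_table(plants, guilds),
                                        plants), fraction=0.05)
        sel = t[t["selected_top"]]
        assert list(sel["plant_species"]) == ["a_plant"]

    def test_shortlist_report_shape(self):
        t = select_top(self._ranked_table(25))
        rep = shortlist(t)
        assert list(rep.columns[:3]) == ["guild", "rank", "plant_species"]
        assert (rep["rank"] >= 1).all()
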