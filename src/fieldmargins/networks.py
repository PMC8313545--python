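"""Bipartite plant/flower-visitor networks and their structural metrics.

Networks are weighted incidence matrices W (plants x visitor guilds, cell =
total observed visits). Metrics:

* **connectance** — realised fraction of possible links, L / (I * J);
* **interaction evenness** — Shannon evenness of interaction weights,
  (-sum q ln q) / ln(I * J) with q = W / sum(W);
* **NODF** — binary nestedness (0-100): mean paired overlap over all row
  pairs and all column pairs with strictly decreasing marginal totals
  (pairs with equal totals contribute 0);
* **robustness** — attack-tolerance area: species of one level are removed
  in uniformly random order; species of the other level lose all links go
  secondarily extinct; the extinction curve (proportion surviving vs.
  proportion removed, endpoints (0, 1) and (1, 0)) is integrated by the
  trapezoid rule and averaged over Monte-Carlo removal orders.

``compare_by_median`` groups sites at the median of a richness covariate
(ties to the "below" group) and tests each metric with a one-way ANOVA.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .anova import oneway
from .errors import ConfigError, EmptyInputError

logger = logging.getLogger("fieldmargins")

METRIC_COLUMNS = ["connectance", "nodf", "interaction_evenness",
                  "robustness_higher", "robustness_lower"]


@dataclasses.dataclass
class BipartiteNetwork:
    """Weighted plant x visitor interaction matrix for one site."""

    site_id: str
    plants: list[str]      # lower level (rows)
    visitors: list[str]    # higher level (columns)
    W: np.ndarray          # non-negative integer visit totals


def build_network(visits: pd.DataFrame, site_id: str) -> BipartiteNetwork:
    """Aggregate a site's visit records into a weighted incidence matrix.

    Duplicate (guild, plant) records are summed; plants or guilds with zero
    total visits are dropped. Raises :class:`EmptyInputError` if the site
    has no visits.
    """
    sub = visits[visits["site_id"] == site_id]
    if len(sub) == 0:
        raise EmptyInputError(f"no visit records for site {site_id!r}")
    W = (sub.pivot_table(index="plant_species", columns="visitor_guild",
                         values="visits", aggfunc="sum", fill_value=0)
         .sort_index(axis=0).sort_index(axis=1))
    W = W.loc[W.sum(axis=1) > 0, W.sum(axis=0) > 0]
    return BipartiteNetwork(site_id=site_id, plants=list(W.index),
                            visitors=list(W.columns),
                            W=W.to_numpy(dtype=np.int64))


def to_edge_list(net: BipartiteNetwork) -> pd.DataFrame:
    """Long-format (plant, guild, weight) export of the positive cells."""
    rows = [(net.site_id, p, g, int(net.W[i, j]))
            for i, p in enumerate(net.plants)
            for j, g in enumerate(net.visitors) if net.W[i, j] > 0]
    return pd.DataFrame(rows, columns=["site_id", "plant_species",
                                       "visitor_guild", "weight"])


def from_edge_list(edges: pd.DataFrame, site_id: str) -> BipartiteNetwork:
    df = edges[edges["site_id"] == site_id].rename(
        columns={"weight": "visits"})
    return build_network(df, site_id)


def connectance(W: np.ndarray) -> float:
    """Fraction of realised links L / (I * J)."""
    W = np.asarray(W)
    if W.size == 0:
        raise EmptyInputError("connectance: empty matrix")
    return float((W > 0).sum() / W.size)


def interaction_evenness(W: np.ndarray) -> float:
    """Shannon evenness of interaction weights; NaN for single-cell webs."""
    W = np.asarray(W, dtype=float)
    if W.size == 0:
        raise EmptyInputError("interaction_evenness: empty matrix")
    if W.size == 1:
        return float("nan")
    q = W / W.sum()
    q = q[q > 0]
    H = -(q * np.log(q)).sum()
    return float(H / np.log(W.size))


def nodf(W: np.ndarray) -> float:
    """Binary NODF nestedness on the incidence derived from W (0-100).

    For every (ordered by fill) pair of rows and of columns with strictly
    decreasing totals, the contribution is the percentage of the sparser
    line's presences that overlap the denser line; equal-fill pairs
    contribute zero. NaN when the matrix has fewer than 2 rows and fewer
    than 2 columns.
    """
    B = (np.asarray(W) > 0).astype(float)
    I, J = B.shape
    if I < 2 and J < 2:
        return float("nan")

    def _axis_sum(M: np.ndarray) -> tuple[float, int]:
        n = M.shape[0]
        if n < 2:
            return 0.0, 0
        fills = M.sum(axis=1)
        overlap = M @ M.T                       # shared presences
        total = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                hi, lo = i, j
                if fills[i] < fills[j]:
                    hi, lo = j, i
                if fills[hi] > fills[lo] > 0:
                    total += 100.0 * overlap[hi, lo] / fills[lo]
        return total, n * (n - 1) // 2

    rows_sum, rows_pairs = _axis_sum(B)
    cols_sum, cols_pairs = _axis_sum(B.T)
    return float((rows_sum + cols_sum) / (rows_pairs + cols_pairs))


def robustness(W: np.ndarray, level: str = "lower", n_reps: int = 2000,
               seed=None) -> float:
    """Monte-Carlo attack-tolerance robustness in [0, 1].

    ``level`` names the level being removed: ``"lower"`` (plants, rows) or
    ``"higher"`` (visitors, columns). After each removal, species of the
    opposite level with no surviving links go secondarily extinct. The area
    under the survival curve is averaged over ``n_reps`` seeded random
    removal orders.
    """
    if n_reps < 1:
        raise ConfigError("robustness: n_reps must be >= 1")
    if level not in ("lower", "higher"):
        raise ConfigError("robustness: level must be 'lower' or 'higher'")
    B = (np.asarray(W) > 0)
    if level == "higher":
        B = B.T
    n_t, n_o = B.shape
    if n_t == 0 or n_o == 0:
        raise EmptyInputError("robustness: empty matrix")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    x = np.arange(n_t + 1) / n_t
    areas = np.empty(n_reps)
    y = np.empty(n_t + 1)
    for r in range(n_reps):
        order = rng.permutation(n_t)
        M = B[order]
        # suffix[k] = column has a link among rows k..n_t-1 (still alive
        # after k removals)
        suffix = np.flip(np.logical_or.accumulate(np.flip(M, 0), 0), 0)
        y[:n_t] = suffix.sum(axis=1) / n_o
        y[n_t] = 0.0
        areas[r] = np.trapezoid(y, x)
    return float(areas.mean())


def network_metrics(net: BipartiteNetwork, n_reps: int = 2000,
                    seed=None) -> dict[str, float]:
    """All five structural metrics for one network."""
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    return {
        "connectance": connectance(net.W),
        "nodf": nodf(net.W),
        "interaction_evenness": interaction_evenness(net.W),
        "robustness_higher": robustness(net.W, "higher", n_reps, rng),
        "robustness_lower": robustness(net.W, "lower", n_reps, rng),
    }


def site_metrics(visits: pd.DataFrame, n_reps: int = 2000,
                 seed=None) -> pd.DataFrame:
    """Per-site metric table over all sites present in the visit records."""
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    rows = []
    for site in sorted(visits["site_id"].unique()):
        net = build_network(visits, site)
        m = network_metrics(net, n_reps=n_reps, seed=rng)
        m["site_id"] = site
        m["n_plants"] = len(net.plants)
        m["n_visitors"] = len(net.visitors)
        rows.append(m)
    if not rows:
        raise EmptyInputError("site_metrics: no visit records")
    return pd.DataFrame(rows)[["site_id", "n_plants", "n_visitors",
                               *METRIC_COLUMNS]]


def compare_by_median(metrics: pd.DataFrame, features: pd.DataFrame,
                      feature: str,
                      metric_cols: list[str] | None = None) -> pd.DataFrame:
    """One-way ANOVA of each metric between sites above vs. at-or-below the
    median of ``feature``.

    Sites exactly at the median join the "below" group (deterministic rule).
    Comparisons with fewer than 2 sites in either group are skipped with a
    warning.
    """
    metric_cols = metric_cols or METRIC_COLUMNS
    merged = metrics.merge(features[["site_id", feature]], on="site_id")
    med = merged[feature].median()
    group = np.where(merged[feature] <= med, "below", "above")
    rows = []
    for col in metric_cols:
        vals = merged[col]
        ok = vals.notna().to_numpy()
        nb, na = int((group[ok] == "below").sum()), int((group[ok] == "above").sum())
        if nb < 2 or na < 2:
            logger.warning("median split on %s: fewer than 2 sites per group "
                           "for metric %s; comparison skipped", feature, col)
            rows.append((feature, col, med, nb, na, np.nan, np.nan,
                         np.nan, np.nan))
            continue
        F, df1, df2, p = oneway(vals[ok], group[ok])
        rows.append((feature, col, med, nb, na, df1, df2, F, p))
    return pd.DataFrame(rows, columns=["feature", "metric", "median",
                                       "n_below", "n_above", "df1", "df2",
                                       "F", "p"])
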