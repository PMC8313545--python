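"""Plant-guild co-occurrence at trap points: observed vs. random expectation.

For every plant species / insect guild pair the contingency statistic is
built from presence frequencies over a shared set of trap points:

    P_plant  observed frequency of the plant being present at a point
    P_ins    observed frequency of the guild being present at a point
    P_c      observed co-occurrence frequency (both present)
    P_pred   expected co-occurrence under random (independent) assortment,
             P_plant * P_ins
    excess   P_c - P_pred   (the default ranking statistic)
    ratio    P_c / P_pred   (missing when P_pred = 0)

Plants found on only one occasion, or present at every point, carry no
information about association and are excluded before ranking. Per guild,
the top 5% most strongly associated of the retained plants (round-half-up,
at least one) form the shortlist.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import AlignmentError, EmptyInputError
from .survey import SurveyBundle, all_points, presence_matrix

RANK_STATS = ("excess", "ratio", "observed")


def cooccurrence_table(plant_presence: pd.DataFrame,
                       guild_presence: pd.DataFrame) -> pd.DataFrame:
    """Full co-occurrence table over all plant x guild pairs.

    Both inputs are binary occurrence matrices (entity x trap point) whose
    columns must be an identical ordered point set; a mismatch raises
    :class:`AlignmentError` naming the offending points.
    """
    if plant_presence.shape[1] == 0 or guild_presence.shape[1] == 0:
        raise EmptyInputError("cooccurrence_table: no trap points")
    if not plant_presence.columns.equals(guild_presence.columns):
        only_p = plant_presence.columns.difference(guild_presence.columns)
        only_g = guild_presence.columns.difference(plant_presence.columns)
        raise AlignmentError(
            "plant and guild matrices use different point sets; "
            f"plant-only: {list(only_p)[:5]}, guild-only: {list(only_g)[:5]}")
    P = plant_presence.to_numpy(dtype=float)
    G = guild_presence.to_numpy(dtype=float)
    n = P.shape[1]
    p_plant = P.mean(axis=1)
    p_ins = G.mean(axis=1)
    p_c = (P @ G.T) / n                      # plants x guilds
    p_pred = np.outer(p_plant, p_ins)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p_pred > 0, p_c / p_pred, np.nan)

    plants = plant_presence.index.to_numpy()
    guilds = guild_presence.index.to_numpy()
    ii, jj = np.meshgrid(np.arange(len(plants)), np.arange(len(guilds)),
                         indexing="ij")
    table = pd.DataFrame({
        "plant_species": plants[ii.ravel()],
        "guild": guilds[jj.ravel()],
        "n_points": n,
        "P_plant": p_plant[ii.ravel()],
        "P_ins": p_ins[jj.ravel()],
        "P_c": p_c.ravel(),
        "P_pred": p_pred.ravel(),
        "excess": p_c.ravel() - p_pred.ravel(),
        "ratio": ratio.ravel(),
    })
    table["excluded"] = False
    table["exclusion_reason"] = "none"
    table["selected_top"] = False
    table["rank"] = pd.NA
    return table


def apply_exclusions(table: pd.DataFrame,
                     plant_presence: pd.DataFrame) -> pd.DataFrame:
    """Flag plants found exactly once (``single_occurrence``) or at every
    point (``ubiquitous``); all their rows are excluded from ranking."""
    counts = plant_presence.sum(axis=1)
    n = plant_presence.shape[1]
    reason = pd.Series("none", index=plant_presence.index)
    reason[counts == 1] = "single_occurrence"
    reason[counts == n] = "ubiquitous"
    out = table.copy()
    out["exclusion_reason"] = (out["plant_species"].map(reason)
                               .fillna("none"))
    out["excluded"] = out["exclusion_reason"] != "none"
    out.loc[out["excluded"], "selected_top"] = False
    return out


def select_top(table: pd.DataFrame, fraction: float = 0.05,
               rank_by: str = "excess") -> pd.DataFrame:
    """Rank retained plants per guild and mark the top ``fraction``.

    k = max(1, round-half-up(fraction * n_retained_plants)). Ties on the
    ranking statistic break on higher P_c, then lexicographic species name.
    ``rank_by`` is one of ``excess`` (default), ``ratio`` or ``observed``
    (raw P_c).
    """
    if rank_by not in RANK_STATS:
        raise ValueError(f"rank_by must be one of {RANK_STATS}")
    stat = {"excess": "excess", "ratio": "ratio", "observed": "P_c"}[rank_by]
    out = table.copy()
    retained = out[~out["excluded"]]
    n_retained = retained["plant_species"].nunique()
    if n_retained == 0:
        return out
    k = max(1, math.floor(fraction * n_retained + 0.5))
    for guild, sub in retained.groupby("guild"):
        sub = sub.sort_values([stat, "P_c", "plant_species"],
                              ascending=[False, False, True],
                              na_position="last")
        idx = sub.index.to_numpy()
        out.loc[idx, "rank"] = np.arange(1, len(idx) + 1)
        out.loc[idx[:k], "selected_top"] = True
    return out


def shortlist(table: pd.DataFrame) -> pd.DataFrame:
    """Report-style shortlist: one row per (guild, rank) selected pair."""
    sel = table[table["selected_top"]].copy()
    sel = sel.sort_values(["guild", "rank"])
    return sel[["guild", "rank", "plant_species", "P_plant", "P_ins", "P_c",
                "P_pred", "excess", "ratio"]].reset_index(drop=True)


def associate(bundle: SurveyBundle, fraction: float = 0.05,
              rank_by: str = "excess", by_stage: bool = False,
              transect: str | None = None) -> pd.DataFrame:
    """Run the full co-occurrence procedure on a survey bundle.

    Presence matrices are built at trap-point resolution (quadrat pairs
    pooled to their point) over the union of points observed in the quadrat
    and trap tables, with cropping stages pooled by default. ``transect``
    restricts the analysis to ``"margin"`` or ``"into_crop"`` points
    (default: both pooled). With ``by_stage=True`` a separate table per
    stage is returned, concatenated with a ``stage`` column.
    """
    quadrats, traps = bundle.quadrats, bundle.traps
    if transect is not None:
        quadrats = quadrats[quadrats["transect"] == transect]
        traps = traps[traps["transect"] == transect]
    if by_stage:
        parts = []
        for stage in sorted(set(quadrats["stage"]) | set(traps["stage"])):
            q = quadrats[quadrats["stage"] == stage]
            t = traps[traps["stage"] == stage]
            if len(q) == 0 or len(t) == 0:
                continue
            part = _associate_once(q, t, fraction, rank_by)
            part.insert(0, "stage", stage)
            parts.append(part)
        if not parts:
            raise EmptyInputError("associate: no stage with both plant and "
                                  "trap records")
        return pd.concat(parts, ignore_index=True)
    return _associate_once(quadrats, traps, fraction, rank_by)


def _associate_once(quadrats: pd.DataFrame, traps: pd.DataFrame,
                    fraction: float, rank_by: str) -> pd.DataFrame:
    points = all_points(quadrats, traps)
    plants = presence_matrix(quadrats, points=points)
    guilds = presence_matrix(traps, points=points)
    table = cooccurrence_table(plants, guilds)
    table = apply_exclusions(table, plants)
    return select_top(table, fraction=fraction, rank_by=rank_by)
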