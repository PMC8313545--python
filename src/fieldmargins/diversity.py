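"""Quadrat- and site-level botanical diversity and the site covariate table.

The Shannon-Weaver index is computed per quadrat survey event (one quadrat
at one cropping stage), weighted by percent cover, in nats. Effective plant
species richness is exp(H) averaged over quadrat events within a site, i.e.
the averaging happens on the effective-number scale (``avg_scale="index"``
switches to exp(mean H)).

``site_features`` assembles the per-site covariates used by the predictor
models: quadrat-level plant and tree richness, native/introduced species
counts and their ratio, off-season flowering richness (species in bloom
during podding, when the bean crop offers no forage), effective plant
richness, the number of plant species receiving visits, plus country and a
representative zone elevation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import UndefinedDiversityError
from .survey import QUADRAT_EVENT_KEY, SurveyBundle

logger = logging.getLogger("fieldmargins")

#: Country and representative elevation (m a.s.l.) per agro-ecological zone.
ZONE_INFO = {
    "malawi_mid": ("malawi", 1100.0),
    "tz_low": ("tanzania", 800.0),
    "tz_mid": ("tanzania", 1250.0),
    "tz_high": ("tanzania", 1700.0),
}


def shannon(cover) -> float:
    """Shannon-Weaver index H = -sum(p_i ln p_i) in nats.

    ``cover`` holds per-species abundances (percent cover) for one quadrat;
    zero entries are filtered before computation (adding a zero-cover species
    changes nothing). All-zero or empty input raises
    :class:`UndefinedDiversityError`; negative values are invalid.
    """
    c = np.asarray(cover, dtype=float)
    if (c < 0).any():
        raise UndefinedDiversityError("negative cover values")
    c = c[c > 0]
    if c.size == 0:
        raise UndefinedDiversityError("no species with positive cover")
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def effective_richness(H: float) -> float:
    """Effective species number exp(H): equally-abundant species equivalent."""
    return float(np.exp(H))


def site_features(bundle: SurveyBundle, exclude_crop: bool = False,
                  presence_weighted: bool = False,
                  avg_scale: str = "effective") -> pd.DataFrame:
    """Per-site covariate table (one row per site).

    Columns: ``H_mean``, ``EffPlRich``, ``PlantQuad``, ``Trees`` (quadrat-
    level mean tree richness), ``TreesTransect`` (mean distinct tree species
    per transect, the scale of the yield-category rule), ``Native``,
    ``Introduced``, ``Ratio`` (NaN when Introduced = 0), ``FloweringOffSeason``,
    ``PlantNet``, ``has_margin``, ``country``, ``elevation``.

    ``exclude_crop`` drops crop species before richness/diversity;
    ``presence_weighted`` replaces cover weights with equal weights in H.
    Sites listed in ``bundle.sites`` but absent from the quadrat records are
    excluded with a logged warning.
    """
    if avg_scale not in ("effective", "index"):
        raise ValueError("avg_scale must be 'effective' or 'index'")
    q = bundle.quadrats
    if exclude_crop:
        q = q[q["growth_form"] != "crop"]
    q = q[q["cover_pct"] > 0].copy()
    if len(q) == 0:
        raise UndefinedDiversityError("no quadrat records with positive cover")

    w = pd.Series(1.0, index=q.index) if presence_weighted else q["cover_pct"]
    q = q.assign(_w=w)
    ev = q.groupby(QUADRAT_EVENT_KEY, sort=False)

    def _h(sub: pd.DataFrame) -> float:
        return shannon(sub["_w"].to_numpy())

    per_event = ev.apply(_h, include_groups=False).rename("H").reset_index()
    per_event["eff"] = np.exp(per_event["H"])
    richness = ev.size().rename("S").reset_index()
    per_event = per_event.merge(richness, on=QUADRAT_EVENT_KEY)
    trees = (q[q["growth_form"] == "tree"].groupby(QUADRAT_EVENT_KEY)
             ["plant_species"].nunique().rename("S_tree").reset_index())
    per_event = per_event.merge(trees, on=QUADRAT_EVENT_KEY, how="left")
    per_event["S_tree"] = per_event["S_tree"].fillna(0)

    agg = per_event.groupby("site_id").agg(
        H_mean=("H", "mean"), EffPlRich=("eff", "mean"),
        PlantQuad=("S", "mean"), Trees=("S_tree", "mean"))
    if avg_scale == "index":
        agg["EffPlRich"] = np.exp(agg["H_mean"])

    by_site = q.groupby("site_id")
    origin_counts = (q.drop_duplicates(["site_id", "plant_species"])
                     .groupby(["site_id", "origin"])["plant_species"]
                     .nunique().unstack(fill_value=0)
                     .reindex(columns=["native", "introduced", "unclassified"],
                              fill_value=0))
    agg["Native"] = origin_counts["native"]
    agg["Introduced"] = origin_counts["introduced"]
    agg["Unclassified"] = origin_counts["unclassified"]
    agg["Ratio"] = np.where(agg["Introduced"] > 0,
                            agg["Native"] / agg["Introduced"], np.nan)
    n_undef = int(agg["Ratio"].isna().sum())
    if n_undef:
        logger.warning("Ratio undefined (Introduced = 0) for %d site(s); "
                       "reported as missing", n_undef)

    off = (q[(q["stage"] == "podding") & q["in_flower"]]
           .groupby("site_id")["plant_species"].nunique())
    agg["FloweringOffSeason"] = off.reindex(agg.index, fill_value=0)

    ttr = (q[q["growth_form"] == "tree"]
           .groupby(["site_id", "transect"])["plant_species"].nunique())
    n_transects = q.groupby("site_id")["transect"].nunique()
    agg["TreesTransect"] = (ttr.groupby("site_id").sum()
                            .reindex(agg.index, fill_value=0) / n_transects)

    if bundle.visits is not None and len(bundle.visits):
        pnet = bundle.visits.groupby("site_id")["plant_species"].nunique()
        agg["PlantNet"] = pnet.reindex(agg.index, fill_value=0)
    else:
        agg["PlantNet"] = 0

    zone = q.groupby("site_id")["zone"].first()
    agg["zone"] = zone
    agg["country"] = zone.map(lambda z: ZONE_INFO[z][0])
    agg["elevation"] = zone.map(lambda z: ZONE_INFO[z][1])

    if bundle.sites is not None:
        meta = bundle.sites.set_index("site_id")
        agg["has_margin"] = meta["has_margin"].reindex(agg.index)
        missing = sorted(set(meta.index) - set(agg.index))
        if missing:
            logger.warning("site(s) with no quadrat records excluded from "
                           "features: %s", ", ".join(missing))
    else:
        agg["has_margin"] = pd.NA

    return agg.reset_index()
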