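"""Survey data model: CSV schemas, validation and presence matrices.

Four record tables make up a survey bundle:

* **quadrats** — one row per plant species observed in a 1x1 m quadrat at one
  cropping stage, with percent cover, flowering status and plant traits
  (origin, growth form).
* **traps** — guild-level pan-trap catches per trap point and stage.
* **visits** — flower-visitation counts per site, stage, visitor guild and
  plant species from standardised transect walks.
* **yields** — per-plant pod and bean counts with field position.

An optional ``sites`` table carries site metadata (zone, margin presence)
and an optional guild vocabulary maps each guild to its functional role
(pollinator, natural enemy or both).

All tables are plain pandas DataFrames with declared column sets; readers
validate enum membership, ranges and key uniqueness on ingest.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, SchemaError, ValidationError

logger = logging.getLogger("fieldmargins")

# Controlled vocabularies ---------------------------------------------------

ZONES = ("malawi_mid", "tz_low", "tz_mid", "tz_high")
TRANSECTS = ("margin", "into_crop")
STAGES = ("pre_plough", "seedling", "flowering", "podding", "post_harvest")
ORIGINS = ("native", "introduced", "unclassified")
GROWTH_FORMS = ("tree", "shrub", "herb", "crop")
POSITIONS = ("edge", "middle")
GUILD_ROLES = ("pollinator", "natural_enemy", "both")

#: Default guild vocabulary (guild -> functional role). Pan-trap and transect
#: identifications are at this functional-group resolution.
DEFAULT_GUILD_ROLES = {
    "honeybee": "pollinator",
    "carpenter_bee": "pollinator",
    "beefly": "pollinator",
    "small_bee": "pollinator",
    "wasp": "natural_enemy",
    "predatory_beetle": "natural_enemy",
    "hoverfly": "both",
    "spider": "natural_enemy",
    "dolichopodidae": "natural_enemy",
}

QUADRAT_COLUMNS = [
    "site_id", "zone", "transect", "point_index", "quadrat_index", "stage",
    "plant_species", "cover_pct", "in_flower", "origin", "growth_form",
]
QUADRAT_KEY = ["site_id", "transect", "point_index", "quadrat_index", "stage",
               "plant_species"]
TRAP_COLUMNS = ["site_id", "transect", "point_index", "stage", "guild", "count"]
TRAP_KEY = ["site_id", "transect", "point_index", "stage", "guild"]
VISIT_COLUMNS = ["site_id", "stage", "visitor_guild", "plant_species", "visits"]
VISIT_KEY = VISIT_COLUMNS[:-1]
YIELD_COLUMNS = ["site_id", "plant_id", "position", "pods_per_plant",
                 "beans_per_pod"]
YIELD_KEY = ["site_id", "plant_id"]
SITE_COLUMNS = ["site_id", "zone", "has_margin"]

#: Key identifying one quadrat survey event (a quadrat at one stage).
QUADRAT_EVENT_KEY = ["site_id", "transect", "point_index", "quadrat_index",
                     "stage"]
#: Key identifying one trap point (the unit of the co-occurrence analysis).
POINT_KEY = ["site_id", "transect", "point_index"]


@dataclasses.dataclass
class SurveyBundle:
    """The four validated record tables, plus optional site metadata."""

    quadrats: pd.DataFrame
    traps: pd.DataFrame
    visits: pd.DataFrame
    yields: pd.DataFrame
    sites: pd.DataFrame | None = None
    guild_roles: pd.DataFrame | None = None


# Validation helpers --------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s): {', '.join(missing)}")


def _check_enum(df: pd.DataFrame, col: str, allowed: Sequence[str],
                table: str) -> None:
    bad = sorted(set(df[col].dropna().unique()) - set(allowed))
    if bad:
        raise ValidationError(
            f"{table}.{col}: unknown value(s) {bad}; allowed: {list(allowed)}")


def _check_unique(df: pd.DataFrame, key: Sequence[str], table: str) -> None:
    dup = df.duplicated(list(key), keep=False)
    if dup.any():
        keys = df.loc[dup, list(key)].drop_duplicates().head(10)
        raise ValidationError(
            f"{table}: duplicate key(s) on ({', '.join(key)}):\n"
            f"{keys.to_string(index=False)}")


def _coerce(df: pd.DataFrame, ints: Sequence[str] = (),
            floats: Sequence[str] = (), bools: Sequence[str] = (),
            table: str = "") -> pd.DataFrame:
    df = df.copy()
    for c in ints:
        try:
            df[c] = pd.to_numeric(df[c]).astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{table}.{c}: not integer-valued: {exc}") from exc
    for c in floats:
        try:
            df[c] = pd.to_numeric(df[c]).astype(float)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{table}.{c}: not numeric: {exc}") from exc
    for c in bools:
        if df[c].dtype != bool:
            mapping = {"true": True, "false": False, "1": True, "0": False}
            vals = df[c].astype(str).str.strip().str.lower().map(mapping)
            if vals.isna().any():
                raise SchemaError(f"{table}.{c}: not boolean-valued")
            df[c] = vals.astype(bool)
    return df


def validate_quadrats(df: pd.DataFrame, layered_cover: bool = False) -> pd.DataFrame:
    """Validate and type a quadrat table; returns the typed copy.

    ``layered_cover=True`` permits total cover above 100% within a quadrat
    (tree canopy layered over herbs); individual species cover must always
    lie in [0, 100].
    """
    _require_columns(df, QUADRAT_COLUMNS, "quadrats")
    df = _coerce(df, ints=["point_index", "quadrat_index"],
                 floats=["cover_pct"], bools=["in_flower"], table="quadrats")
    _check_enum(df, "zone", ZONES, "quadrats")
    _check_enum(df, "transect", TRANSECTS, "quadrats")
    _check_enum(df, "stage", STAGES, "quadrats")
    _check_enum(df, "origin", ORIGINS, "quadrats")
    _check_enum(df, "growth_form", GROWTH_FORMS, "quadrats")
    if (df["cover_pct"] < 0).any() or (df["cover_pct"] > 100).any():
        bad = df.loc[(df["cover_pct"] < 0) | (df["cover_pct"] > 100)]
        raise ValidationError(
            f"quadrats.cover_pct outside [0, 100] in {len(bad)} row(s), "
            f"e.g. {bad['cover_pct'].iloc[0]}")
    if (df["point_index"] < 1).any() or (df["quadrat_index"] < 1).any():
        raise ValidationError("quadrats: point_index and quadrat_index must be >= 1")
    _check_unique(df, QUADRAT_KEY, "quadrats")
    if not layered_cover and len(df):
        totals = df.groupby(QUADRAT_EVENT_KEY, sort=False)["cover_pct"].sum()
        over = totals[totals > 100.0 + 1e-4]   # tolerance ~ CSV round-trip
        if len(over):
            raise ValidationError(
                f"quadrats: total cover exceeds 100% in {len(over)} quadrat(s) "
                "(set layered_cover=True to allow layered canopies)")
    return df


def validate_traps(df: pd.DataFrame,
                   guild_vocabulary: Iterable[str] | None = None) -> pd.DataFrame:
    _require_columns(df, TRAP_COLUMNS, "traps")
    df = _coerce(df, ints=["point_index", "count"], table="traps")
    _check_enum(df, "transect", TRANSECTS, "traps")
    _check_enum(df, "stage", STAGES, "traps")
    if guild_vocabulary is not None:
        _check_enum(df, "guild", tuple(guild_vocabulary), "traps")
    if (df["count"] < 0).any():
        raise ValidationError("traps.count must be >= 0")
    if (df["point_index"] < 1).any():
        raise ValidationError("traps: point_index must be >= 1")
    _check_unique(df, TRAP_KEY, "traps")
    return df


def validate_visits(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, VISIT_COLUMNS, "visits")
    df = _coerce(df, ints=["visits"], table="visits")
    _check_enum(df, "stage", STAGES, "visits")
    if (df["visits"] < 1).any():
        raise ValidationError("visits.visits must be >= 1")
    _check_unique(df, VISIT_KEY, "visits")
    return df


def validate_yields(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, YIELD_COLUMNS, "yields")
    df = _coerce(df, ints=["pods_per_plant"], floats=["beans_per_pod"],
                 table="yields")
    _check_enum(df, "position", POSITIONS, "yields")
    if (df["pods_per_plant"] < 0).any() or (df["beans_per_pod"] < 0).any():
        raise ValidationError("yields: pods_per_plant and beans_per_pod must be >= 0")
    _check_unique(df, YIELD_KEY, "yields")
    return df


def validate_sites(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, SITE_COLUMNS, "sites")
    df = _coerce(df, bools=["has_margin"], table="sites")
    _check_enum(df, "zone", ZONES, "sites")
    _check_unique(df, ["site_id"], "sites")
    return df


def validate_guild_roles(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, ["guild", "role"], "guilds")
    _check_enum(df, "role", GUILD_ROLES, "guilds")
    _check_unique(df, ["guild"], "guilds")
    return df.copy()


def default_guild_roles() -> pd.DataFrame:
    """The built-in guild vocabulary as a (guild, role) table."""
    return pd.DataFrame(sorted(DEFAULT_GUILD_ROLES.items()),
                        columns=["guild", "role"])


# I/O -----------------------------------------------------------------------

_FILENAMES = {"quadrats": "quadrats.csv", "traps": "traps.csv",
              "visits": "visits.csv", "yields": "yields.csv",
              "sites": "sites.csv", "guild_roles": "guilds.csv"}


def read_survey(directory: str | Path | None = None, *,
                quadrats: str | Path | None = None,
                traps: str | Path | None = None,
                visits: str | Path | None = None,
                yields: str | Path | None = None,
                sites: str | Path | None = None,
                guilds: str | Path | None = None,
                layered_cover: bool = False) -> SurveyBundle:
    """Read and validate a survey bundle from CSV files.

    Either pass ``directory`` (standard file names are assumed) or explicit
    per-table paths. ``sites.csv`` and ``guilds.csv`` are optional.
    """
    if directory is not None:
        d = Path(directory)
        quadrats = quadrats or d / _FILENAMES["quadrats"]
        traps = traps or d / _FILENAMES["traps"]
        visits = visits or d / _FILENAMES["visits"]
        yields = yields or d / _FILENAMES["yields"]
        if sites is None and (d / _FILENAMES["sites"]).exists():
            sites = d / _FILENAMES["sites"]
        if guilds is None and (d / _FILENAMES["guild_roles"]).exists():
            guilds = d / _FILENAMES["guild_roles"]
    for name, path in [("quadrats", quadrats), ("traps", traps),
                       ("visits", visits), ("yields", yields)]:
        if path is None:
            raise SchemaError(f"read_survey: no path given for '{name}'")
        if not Path(path).exists():
            raise SchemaError(f"read_survey: file not found: {path}")

    guild_df = (validate_guild_roles(pd.read_csv(guilds))
                if guilds is not None else default_guild_roles())
    bundle = SurveyBundle(
        quadrats=validate_quadrats(pd.read_csv(quadrats), layered_cover),
        traps=validate_traps(pd.read_csv(traps),
                             guild_vocabulary=guild_df["guild"]),
        visits=validate_visits(pd.read_csv(visits)),
        yields=validate_yields(pd.read_csv(yields)),
        sites=(validate_sites(pd.read_csv(sites)) if sites is not None
               and Path(sites).exists() else None),
        guild_roles=guild_df,
    )
    return bundle


def write_survey(bundle: SurveyBundle, directory: str | Path) -> dict[str, Path]:
    """Write a bundle to ``directory`` as UTF-8 comma-separated CSVs."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in ("quadrats", "traps", "visits", "yields", "sites",
                 "guild_roles"):
        df = getattr(bundle, name)
        if df is None:
            continue
        path = d / _FILENAMES[name]
        df.to_csv(path, index=False, float_format="%.10g")
        paths[name] = path
    return paths


# Presence matrices ---------------------------------------------------------

def all_points(*tables: pd.DataFrame) -> pd.MultiIndex:
    """Union of trap-point keys (site, transect, point) across tables."""
    frames = [t[POINT_KEY] for t in tables if t is not None and len(t)]
    if not frames:
        raise EmptyInputError("all_points: no records supplied")
    pts = pd.concat(frames).drop_duplicates().sort_values(POINT_KEY)
    return pd.MultiIndex.from_frame(pts)


def presence_matrix(records: pd.DataFrame,
                    points: pd.MultiIndex | None = None,
                    pool_stages: bool = True) -> pd.DataFrame:
    """Binary occurrence matrix (entity x trap point) from quadrat or trap records.

    Quadrat records are pooled pairwise to their trap point: an entity is
    present at a point if it occurs in either flanking quadrat (with positive
    cover), or was trapped there with a positive count. ``points`` fixes the
    column universe explicitly (absent points become all-zero columns);
    otherwise the points observed in ``records`` are used.

    With ``pool_stages=False`` the stage is appended to the point key, giving
    one column per point x stage survey event.
    """
    if records is None or len(records) == 0:
        raise EmptyInputError("presence_matrix: empty record collection")
    if "plant_species" in records.columns and "cover_pct" in records.columns:
        entity, present = "plant_species", records["cover_pct"] > 0
    elif "guild" in records.columns and "count" in records.columns:
        entity, present = "guild", records["count"] > 0
    else:
        raise SchemaError("presence_matrix: expected quadrat or trap columns")
    key = POINT_KEY if pool_stages else POINT_KEY + ["stage"]
    sub = records.loc[present.to_numpy()]
    if len(sub) == 0:
        raise EmptyInputError("presence_matrix: no positive occurrences")
    mat = pd.crosstab(sub[entity], [sub[k] for k in key])
    mat = (mat > 0).astype(np.int8)
    mat.columns.names = key
    if points is not None:
        mat = mat.reindex(columns=points, fill_value=0).astype(np.int8)
    mat.index.name = entity
    return mat
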