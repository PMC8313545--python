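"""End-to-end orchestration: simulate/ingest -> diversity -> associations ->
networks -> importance -> yield, with a single seed and a run manifest.

The global seed is expanded through a ``numpy.random.SeedSequence`` into one
stream per stage, spawned up front, so toggling a stage off never shifts the
randomness of the others. Every output is a CSV in the run directory; the
manifest records the stages run, the files written, the package version and
a hash of the effective configuration. Re-running with the same config and
seed reproduces all outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cooccurrence import associate, shortlist
from .diversity import site_features
from .errors import (ConfigError, DegenerateModelError, EmptyInputError,
                     ValidationError)
from .networks import compare_by_median, site_metrics
from .predictors import (fit_forest, fit_scatter_models,
                         permutation_importance, site_insect_responses)
from .simulate import (GuildSpec, PlantSpec, SimulationConfig,
                       simulate_bundle)
from .survey import SurveyBundle, read_survey, write_survey
from .yields import categorize_richness, group_means, yield_anova

logger = logging.getLogger("fieldmargins")

STAGE_NAMES = ("simulate", "diversity", "associate", "networks",
               "importance", "yield")

DEFAULT_RESPONSES = ("visits_all", "visits_carpenter", "ne_abundance",
                     "ne_richness", "dolichopodidae")
DEFAULT_PREDICTOR_VARS = ("PlantQuad", "Trees", "Native", "Introduced",
                          "Ratio", "FloweringOffSeason", "EffPlRich",
                          "PlantNet", "elevation", "is_tanzania")
REGRESSION_PREDICTORS = ("Trees", "PlantQuad", "EffPlRich", "PlantNet",
                         "FloweringOffSeason", "Native")


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str | Path = "run"
    seed: int = 0
    input_dir: str | Path | None = None    # read CSVs here instead of simulating
    simulation: SimulationConfig = dataclasses.field(
        default_factory=SimulationConfig)
    stages: dict[str, bool] = dataclasses.field(
        default_factory=lambda: {s: True for s in STAGE_NAMES})
    fraction: float = 0.05
    rank_by: str = "excess"
    by_stage: bool = False
    robustness_reps: int = 2000
    n_trees: int = 500
    n_perm: int = 5
    mtry: int | None = None
    responses: tuple[str, ...] = DEFAULT_RESPONSES
    yield_offset: float = 1.0
    ss_type: str = "I"


def simulation_config_from_dict(d: Mapping[str, Any]) -> SimulationConfig:
    """Build a SimulationConfig from a plain (e.g. YAML-loaded) mapping."""
    d = dict(d)
    if "plant_pool" in d:
        d["plant_pool"] = [PlantSpec(**{**p, "flowering_stages":
                                        tuple(p.get("flowering_stages",
                                                    ("flowering", "podding")))})
                           for p in d["plant_pool"]]
    if "guild_pool" in d:
        d["guild_pool"] = [GuildSpec(**g) for g in d["guild_pool"]]
    for key in ("association", "visitation"):
        if key in d:
            d[key] = {(e["a"], e["b"]) if isinstance(e, Mapping)
                      else tuple(e[:2]): float(e["value"])
                      if isinstance(e, Mapping) else float(e[2])
                      for e in d[key]}
    if "stages" in d:
        d["stages"] = tuple(d["stages"])
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown simulation config key(s): {sorted(unknown)}")
    return SimulationConfig(**d)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = simulation_config_from_dict(raw.pop("simulation", {}))
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown run config key(s): {sorted(unknown)}")
    stages = {s: True for s in STAGE_NAMES}
    stages.update(raw.pop("stages", {}))
    if "responses" in raw:
        raw["responses"] = tuple(raw["responses"])
    return RunConfig(simulation=sim, stages=stages, **raw)


def _config_hash(cfg: RunConfig) -> str:
    """Hash of the scientific configuration (output location excluded)."""
    def stringify(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            o = dataclasses.asdict(o)
        if isinstance(o, Mapping):
            return {str(k): stringify(v) for k, v in sorted(
                o.items(), key=lambda kv: str(kv[0]))}
        if isinstance(o, (list, tuple)):
            return [stringify(v) for v in o]
        if isinstance(o, Path):
            return str(o)
        return o
    d = stringify(cfg)
    d.pop("out_dir", None)
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, index=index, float_format="%.10g")
    return path


def run_all(cfg: RunConfig) -> dict[str, Any]:
    """Run all enabled stages in dependency order; returns the manifest.

    The upstream survey bundle comes either from ``cfg.input_dir`` or from
    the synthetic generator seeded with ``cfg.seed``. Later stages that need
    a disabled upstream stage raise :class:`ConfigError`.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    streams = {name: child for name, child in
               zip(STAGE_NAMES, ss.spawn(len(STAGE_NAMES)))}
    manifest: dict[str, Any] = {
        "package": "fieldmargins", "version": __version__,
        "seed": cfg.seed, "config_hash": _config_hash(cfg),
        "stages": [], "files": {},
    }
    files = manifest["files"]

    # --- stage: simulate or ingest
    bundle: SurveyBundle | None = None
    if cfg.input_dir is not None:
        bundle = read_survey(cfg.input_dir)
        manifest["input_dir"] = str(cfg.input_dir)
    elif cfg.stages.get("simulate", True):
        sim = dataclasses.replace(
            cfg.simulation,
            seed=int(streams["simulate"].generate_state(1)[0] % (2**31)))
        bundle, truth = simulate_bundle(sim)
        paths = write_survey(bundle, out)
        files.update({k: v.name for k, v in paths.items()})
        files["ground_truth"] = _write(
            truth.to_frame(), out / "ground_truth.csv").name
        manifest["stages"].append("simulate")
    if bundle is None:
        raise ConfigError("run_all: no input_dir and simulate stage disabled")

    # --- stage: diversity
    features = None
    if cfg.stages.get("diversity", True):
        features = site_features(bundle)
        files["site_features"] = _write(features, out / "site_features.csv").name
        manifest["stages"].append("diversity")

    # --- stage: associate
    if cfg.stages.get("associate", True):
        table = associate(bundle, fraction=cfg.fraction, rank_by=cfg.rank_by,
                          by_stage=cfg.by_stage)
        files["cooccurrence_full"] = _write(table, out / "cooccurrence_full.csv").name
        files["top_associations"] = _write(shortlist(table), out / "top_associations.csv").name
        manifest["stages"].append("associate")

    # --- stage: networks
    if cfg.stages.get("networks", True):
        rng = np.random.default_rng(streams["networks"])
        try:
            metrics = site_metrics(bundle.visits, n_reps=cfg.robustness_reps,
                                   seed=rng)
        except EmptyInputError:
            logger.warning("networks stage skipped: no visit records")
            metrics = None
        if metrics is not None:
            files["network_metrics"] = _write(metrics, out / "network_metrics.csv").name
            if features is not None:
                comp = pd.concat([
                    compare_by_median(metrics, features, "Trees"),
                    compare_by_median(metrics, features, "EffPlRich"),
                ], ignore_index=True)
                files["network_comparison"] = _write(comp, out / "network_comparison.csv").name
            manifest["stages"].append("networks")

    # --- stage: importance
    if cfg.stages.get("importance", True):
        if features is None:
            raise ConfigError("importance stage requires the diversity stage")
        responses = site_insect_responses(bundle)
        feat = features.merge(responses, on="site_id")
        feat["is_tanzania"] = (feat["country"] == "tanzania").astype(int)
        variables = [v for v in DEFAULT_PREDICTOR_VARS if v in feat.columns]
        seed_imp = int(streams["importance"].generate_state(1)[0] % (2**31))
        imp_rows, reg_rows = [], []
        for i, resp in enumerate(cfg.responses):
            try:
                fit = fit_forest(feat, resp, variables=variables,
                                 mtry=cfg.mtry, n_trees=cfg.n_trees,
                                 seed=seed_imp + i)
            except (DegenerateModelError, ValidationError) as exc:
                logger.warning("importance: response %s skipped (%s)",
                               resp, exc)
                continue
            imp = permutation_importance(fit, n_perm=cfg.n_perm,
                                         seed=seed_imp + 1000 + i)
            imp.insert(0, "response", resp)
            imp["mtry"] = fit.mtry
            imp["pct_var_explained"] = fit.pct_var_explained
            imp_rows.append(imp)
            for pred in REGRESSION_PREDICTORS:
                if pred in feat.columns and feat[pred].nunique() > 1:
                    reg_rows.append(fit_scatter_models(feat, resp, pred))
        if imp_rows:
            files["importance"] = _write(pd.concat(imp_rows, ignore_index=True),
                       out / "importance.csv").name
            files["regressions"] = _write(pd.concat(reg_rows, ignore_index=True),
                       out / "regressions.csv").name
            manifest["stages"].append("importance")
        else:
            logger.warning("importance stage produced no fittable response")

    # --- stage: yield
    if cfg.stages.get("yield", True):
        if features is None:
            raise ConfigError("yield stage requires the diversity stage")
        if len(bundle.yields) == 0:
            logger.warning("yield stage skipped: no yield records")
        else:
            cat = categorize_richness(features)
            table = yield_anova(bundle.yields, cat, offset=cfg.yield_offset,
                                ss_type=cfg.ss_type)
            table = table.reset_index()
            files["yield_anova"] = _write(table, out / "yield_anova.csv").name
            files["yield_group_means"] = _write(group_means(bundle.yields, cat),
                       out / "yield_group_means.csv").name
            manifest["stages"].append("yield")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
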