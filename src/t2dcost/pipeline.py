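"""End-to-end pipeline: registry -> episodes -> windowed costs -> models.

One call reproducibly runs the whole analysis: load (or synthesize) the
registry tables, route diagnosis codes into complication classes, build and
classify episodes, flag pre-index comorbidities, window and deflate costs,
fit the 12 gamma cost models (6 complication classes × incident/recurrent)
and emit the descriptive and model tables as CSV, together with an
attrition log recording the count surviving every filtering step.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import costs as costs_mod
from . import episodes as ep_mod
from .codemaps import (
    COMORBIDITY_CLASSES,
    COMPLICATION_CLASSES,
    default_synthetic_maps,
    load_code_maps,
)
from .model import (
    ModelSpec,
    attach_covariates,
    average_marginal_effects,
    coefficient_table,
    fit_stratum,
    mcfadden_r2,
)
from .registry import Registry, SimulationConfig, generate_registry, read_registry, write_registry

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``registry_dir`` (pre-existing tables) or ``simulation``
    (generate them) must be set.
    """

    registry_dir: str | None = None
    simulation: SimulationConfig | None = None
    code_maps_path: str | None = None        # None -> synthetic mnemonic maps
    inclusion_start: str = "2012-01-01"
    inclusion_end: str = "2016-12-31"
    episode_rule: str = "from_index"
    history_scope: str = "any_class"
    price_index: dict[int, float] = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "t2dcost_run"

    def __post_init__(self) -> None:
        if (self.registry_dir is None) == (self.simulation is None):
            raise ValueError("exactly one of registry_dir or simulation must be set")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "simulation" in raw and isinstance(raw["simulation"], dict):
            sim = dict(raw["simulation"])
            for k in ("birth_year_range", "t2d_onset_year_range"):
                if k in sim:
                    sim[k] = tuple(sim[k])
            raw["simulation"] = SimulationConfig(**sim)
        if "price_index" in raw and raw["price_index"]:
            raw["price_index"] = {int(k): float(v) for k, v in raw["price_index"].items()}
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory handle on everything a run produced."""

    out_dir: Path
    registry: Registry
    episodes: pd.DataFrame          # included episodes with covariates + windowed costs
    all_episodes: pd.DataFrame      # every built episode (pre-inclusion)
    fits: dict                      # model key -> GammaFit (successful fits only)
    failures: dict                  # model key -> error message
    attrition: dict[str, int]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run generate -> episodize -> cost -> model and write all outputs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    attrition: dict[str, int] = {}

    # --- registry ---------------------------------------------------------
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, rng_seed=config.seed)
        registry = generate_registry(sim)
        write_registry(registry, out_dir / "registry")
    else:
        registry = read_registry(config.registry_dir)
    patients, diagnoses, costs = registry.patients, registry.diagnoses, registry.costs
    attrition["patients"] = len(patients)
    attrition["diagnosis_events"] = len(diagnoses)
    attrition["cost_records"] = len(costs)

    if config.code_maps_path:
        code_map, comorbidity_map = load_code_maps(config.code_maps_path)
    else:
        code_map, comorbidity_map = default_synthetic_maps()

    # --- episodes ---------------------------------------------------------
    class_events = ep_mod.extract_class_events(diagnoses, code_map)
    attrition["complication_events"] = len(class_events)
    episodes = ep_mod.build_all_episodes(class_events, rule=config.episode_rule)
    attrition["episodes_built"] = len(episodes)
    episodes = ep_mod.classify_episodes(episodes, patients, history_scope=config.history_scope)
    episodes = ep_mod.flag_comorbidities(diagnoses, episodes, comorbidity_map)
    episodes = attach_covariates(episodes, patients)

    # --- costs ------------------------------------------------------------
    price_index = costs_mod.PriceIndex(deflators=dict(config.price_index)) if config.price_index \
        else costs_mod.PriceIndex.identity()
    windowed = costs_mod.window_costs(costs, episodes, price_index)
    cost_cols = [c for c in windowed.columns if c not in ("patient_id", "index_date")]
    episodes = pd.concat([episodes.reset_index(drop=True), windowed[cost_cols]], axis=1)
    episodes["n_earlier_episodes"] = episodes["n_prior_same_class"].astype(float)
    episodes["high_prior_cost"] = costs_mod.add_high_prior_cost(episodes, episodes).to_numpy(dtype=float)

    included = ep_mod.filter_included(
        episodes, patients, config.inclusion_start, config.inclusion_end
    )
    attrition["episodes_diabetic_included"] = len(included)
    n_inc = int((included["episode_type"] == "incident").sum())
    n_rec = int((included["episode_type"] == "recurrent").sum())
    attrition["episodes_incident"] = n_inc
    attrition["episodes_recurrent"] = n_rec
    assert n_inc + n_rec == len(included)
    per_class = included.groupby("complication_class").size()
    assert int(per_class.sum()) == len(included)  # 6-class partition identity
    logger.info("attrition: %s", attrition)

    # --- descriptive tables ----------------------------------------------
    descriptives = descriptive_table(included)
    comparison = window_comparison_table(included)
    py = ep_mod.person_years(patients, config.inclusion_start, config.inclusion_end)
    incidence = ep_mod.incidence_rate(len(included), py) if py > 0 else float("nan")

    # --- models -----------------------------------------------------------
    fits, failures = {}, {}
    model_rows, ame_rows, stat_rows = [], [], []
    for cls in COMPLICATION_CLASSES:
        for etype in ("incident", "recurrent"):
            spec = ModelSpec(cls, etype)
            data = included[
                (included["complication_class"] == cls) & (included["episode_type"] == etype)
            ].reset_index(drop=True)
            key = spec.key
            try:
                if len(data) < len(spec.covariates) + 2:
                    raise ValueError(f"too few episodes ({len(data)}) to fit {key}")
                fit = fit_stratum(data, spec, robust="hc" if etype == "incident" else "cluster")
            except Exception as exc:  # one stratum failing must not abort the rest
                failures[key] = str(exc)
                logger.warning("model %s not fitted: %s", key, exc)
                continue
            fits[key] = fit
            table = coefficient_table(fit)
            table.insert(0, "model", key)
            model_rows.append(table)
            ame = average_marginal_effects(fit)
            ame.insert(0, "model", key)
            ame_rows.append(ame)
            stat_rows.append(
                {
                    "model": key,
                    "n": fit.n_obs,
                    "n_clusters": fit.n_clusters,
                    "mcfadden_r2": mcfadden_r2(fit),
                    "dispersion": fit.dispersion,
                    "converged": fit.converged,
                    "n_dropped_zero_cost": fit.n_dropped_zero_cost,
                    "dropped_covariates": ";".join(fit.dropped_covariates),
                }
            )

    # --- outputs ----------------------------------------------------------
    _write(included, out_dir / "episodes.csv")
    _write(windowed, out_dir / "episode_costs.csv")
    _write(descriptives, out_dir / "descriptives.csv")
    _write(comparison, out_dir / "window_comparison.csv")
    _write(pd.concat(model_rows, ignore_index=True) if model_rows else
           pd.DataFrame(columns=["model", "term", "exp_coef", "se_log", "p_value", "stars"]),
           out_dir / "models.csv")
    _write(pd.concat(ame_rows, ignore_index=True) if ame_rows else
           pd.DataFrame(columns=["model", "term", "ame_eur", "binary"]),
           out_dir / "ame.csv")
    _write(pd.DataFrame(stat_rows), out_dir / "fit_stats.csv")
    run_log = {
        "seed": config.seed,
        "attrition": attrition,
        "person_years": py,
        "crude_incidence_per_100py": incidence,
        "episodes_per_class": {k: int(v) for k, v in per_class.items()},
        "model_failures": failures,
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, default=str)
    cfg = dataclasses.asdict(config)
    if config.simulation is not None:
        cfg["simulation"] = dataclasses.asdict(config.simulation)
    with open(out_dir / "config_used.yaml", "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(cfg, default=str)), fh, sort_keys=False)
    return PipelineResult(out_dir, registry, included, episodes, fits, failures, attrition)


def _write(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def descriptive_table(included: pd.DataFrame) -> pd.DataFrame:
    """Per (episode type × class) descriptive rows, ordered by mean cost.

    Reports n, mean (SD) age at index, n (%) men, mean (SD) T2D duration,
    mean (SD) outpatient visits and inpatient days in the episode year, and
    mean (SD) one-year cost. Single-episode groups report SD as 0; empty
    strata are omitted.
    """
    rows = []
    for (etype, cls), grp in included.groupby(["episode_type", "complication_class"]):
        n = len(grp)
        age = grp["age_c75_per10"] * 10.0 + 75.0
        dur = grp["t2d_duration_per5"] * 5.0
        men = int(n - grp["woman"].sum())
        sd = (lambda s: float(s.std(ddof=1)) if n > 1 else 0.0)
        rows.append(
            {
                "episode_type": etype,
                "complication_class": cls,
                "n": n,
                "age_mean": float(age.mean()), "age_sd": sd(age),
                "men_n": men, "men_pct": round(100.0 * men / n, 1),
                "t2d_duration_mean": float(dur.mean()), "t2d_duration_sd": sd(dur),
                "outpatient_visits_mean": float(grp["year1_outpatient_visits"].mean()),
                "outpatient_visits_sd": sd(grp["year1_outpatient_visits"]),
                "inpatient_days_mean": float(grp["year1_inpatient_days"].mean()),
                "inpatient_days_sd": sd(grp["year1_inpatient_days"]),
                "year1_cost_mean": float(grp["year1_eur"].mean()),
                "year1_cost_sd": sd(grp["year1_eur"]),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(
            ["episode_type", "year1_cost_mean"], ascending=[True, False], kind="stable"
        ).reset_index(drop=True)
    return out


def men_percent(men_n: int, n: int) -> float:
    """Share of men in a stratum, one decimal — the descriptive-table cell."""
    if n <= 0:
        raise ValueError("group size must be positive")
    return round(100.0 * men_n / n, 1)


def window_comparison_table(included: pd.DataFrame) -> pd.DataFrame:
    """Mean pre-year / first-year / second-year costs per type × class."""
    rows = []
    for (etype, cls), grp in included.groupby(["episode_type", "complication_class"]):
        rows.append(
            {
                "episode_type": etype,
                "complication_class": cls,
                "n": len(grp),
                "pre_year_mean_eur": float(grp["pre_year_eur"].mean()),
                "year1_mean_eur": float(grp["year1_eur"].mean()),
                "year2_mean_eur": float(grp["year2_eur"].mean()),
            }
        )
    return pd.DataFrame(rows)
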