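"""Synthetic hospital registry generator.

Generates patient, diagnosis-event and cost tables with the statistical
structure the downstream analysis assumes: per-class complication episodes
arriving as a renewal process with inter-index gaps wider than the one-year
episode window, repeat same-class diagnoses scattered inside each episode
window (which the episode builder must absorb), Charlson-style comorbidity
codes placed in the two-year pre-index window, death within the episode year
with a configured probability (death truncates all later events), and
positively skewed admission costs whose one-year episode sums are gamma
distributed with mean ``exp(x'beta_true)``.

A ground-truth sidecar table (one row per planned episode, with its type,
covariates, drawn one-year cost and true mean) is emitted alongside the CSVs
so downstream recovery is checkable without re-deriving.

All randomness flows through one ``numpy`` generator seeded from the config;
the same seed reproduces every table byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .codemaps import COMORBIDITY_CLASSES, COMPLICATION_CLASSES

EPISODE_WINDOW_DAYS = 365
COMORBIDITY_WINDOW_DAYS = 730
LOOKBACK_YEARS = 15

RESOURCE_CATEGORIES = (
    "inpatient_ward_days",
    "outpatient_visits",
    "surgical_procedures",
    "emergency_visits",
    "laboratory",
    "medications",
    "other_procedures",
    "other",
)

#: covariates of the incident-episode cost model (design order)
INCIDENT_COVARIATES: tuple[str, ...] = (
    "woman",
    "age_c75_per10",
    "t2d_duration_per5",
    "died_within_1y",
) + tuple(c for c in COMORBIDITY_CLASSES if c != "diabetes_with_chronic_complications")

#: covariates of the recurrent-episode cost model (design order)
RECURRENT_COVARIATES: tuple[str, ...] = (
    "woman",
    "age_c75_per10",
    "t2d_duration_per5",
    "died_within_1y",
    "n_earlier_episodes",
    "high_prior_cost",
) + tuple(COMORBIDITY_CLASSES)


def _default_episode_rates() -> dict[str, float]:
    # per-year per-patient index-event hazards, mirroring the dominance of
    # cardiovascular and eye complications in hospital practice
    return {
        "cardiovascular": 0.080,
        "eye": 0.035,
        "foot_disorder": 0.025,
        "cerebrovascular": 0.025,
        "nephropathy": 0.012,
        "neurological": 0.006,
    }


def _default_comorbidity_prevalence() -> dict[str, float]:
    # per-episode probability that a comorbidity code lands in the 2-year
    # pre-index window; heart failure / malignancy / pulmonary most common
    base = {c: 0.04 for c in COMORBIDITY_CLASSES}
    base.update(
        congestive_heart_failure=0.12,
        any_malignancy=0.10,
        chronic_pulmonary_disease=0.09,
        peripheral_vascular_disease=0.08,
        diabetes_with_chronic_complications=0.15,
        moderate_or_severe_renal_disease=0.07,
    )
    return base


def default_true_coefficients() -> dict[str, dict[str, float]]:
    """Log-scale generating coefficients per ``<class>:<incident|recurrent>``.

    Intercepts are set near the magnitude of observed one-year hospital
    costs (thousands of euros); covariate effects are multiplicative ratios
    of realistic size (age decreasing, death and renal disease increasing).
    """
    out: dict[str, dict[str, float]] = {}
    intercepts = {
        "foot_disorder": (16000.0, 17000.0),
        "nephropathy": (15000.0, 24000.0),
        "cardiovascular": (13000.0, 10000.0),
        "cerebrovascular": (12500.0, 9500.0),
        "neurological": (9500.0, 10000.0),
        "eye": (6000.0, 6300.0),
    }
    common = {
        "woman": np.log(0.90),
        "age_c75_per10": np.log(0.85),
        "t2d_duration_per5": np.log(1.03),
        "died_within_1y": np.log(1.45),
        "congestive_heart_failure": np.log(1.30),
        "moderate_or_severe_renal_disease": np.log(1.80),
        "any_malignancy": np.log(1.25),
    }
    for cls in COMPLICATION_CLASSES:
        inc_mu, rec_mu = intercepts[cls]
        inc = {c: 0.0 for c in INCIDENT_COVARIATES}
        inc.update({k: v for k, v in common.items() if k in inc})
        inc["const"] = float(np.log(inc_mu))
        rec = {c: 0.0 for c in RECURRENT_COVARIATES}
        rec.update({k: v for k, v in common.items() if k in rec})
        rec.update(
            n_earlier_episodes=np.log(1.03),
            high_prior_cost=np.log(2.0),
            diabetes_with_chronic_complications=np.log(1.35),
        )
        rec["const"] = float(np.log(rec_mu))
        out[f"{cls}:incident"] = {k: float(v) for k, v in inc.items()}
        out[f"{cls}:recurrent"] = {k: float(v) for k, v in rec.items()}
    return out


@dataclass
class SimulationConfig:
    """Configuration of the synthetic registry.

    Defaults describe a mid-sized Finnish hospital-district cohort observed
    1996–2017 with the 2012–2016 inclusion window analysed downstream.
    """

    n_patients: int = 2500
    study_start: str = "1996-01-01"
    study_end: str = "2017-12-31"
    rng_seed: int = 0
    male_fraction: float = 0.55
    birth_year_range: tuple[int, int] = (1925, 1970)
    t2d_onset_year_range: tuple[int, int] = (1998, 2014)
    in_catchment_fraction: float = 0.97
    episode_rates_per_year: dict[str, float] = field(default_factory=_default_episode_rates)
    max_repeat_diagnoses: int = 3
    comorbidity_prevalence: dict[str, float] = field(
        default_factory=_default_comorbidity_prevalence
    )
    true_coefficients: dict[str, dict[str, float]] = field(
        default_factory=default_true_coefficients
    )
    gamma_shape: float = 2.0
    p_death_within_year: float = 0.08
    background_cost_rate_per_year: float = 0.2
    background_cost_mean_eur: float = 150.0
    external_provider_fraction: float = 0.10
    high_cost_threshold_eur: float = 50_000.0
    price_index: dict[int, float] = field(default_factory=dict)  # empty -> identity
    adversarial_gaps: bool = False  # gaps straddle the window boundary (stress mode)

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        for name, p in [
            ("male_fraction", self.male_fraction),
            ("in_catchment_fraction", self.in_catchment_fraction),
            ("p_death_within_year", self.p_death_within_year),
            ("external_provider_fraction", self.external_provider_fraction),
            *[(f"comorbidity_prevalence[{k}]", v) for k, v in self.comorbidity_prevalence.items()],
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")


class Registry(NamedTuple):
    """The generated tables plus the echoed configuration."""

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    costs: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def _deflator(config: SimulationConfig, year: int) -> float:
    return float(config.price_index.get(year, 1.0))


def generate_cohort(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the patient table: demographics, T2D onset, catchment flag.

    Death dates are filled in later by the event generator (death is tied to
    episodes); here every patient starts without one.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    n = config.n_patients
    ids = [f"P{i:06d}" for i in range(n)]
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    b_lo, b_hi = config.birth_year_range
    birth = pd.to_datetime(
        {
            "year": rng.integers(b_lo, b_hi + 1, n),
            "month": rng.integers(1, 13, n),
            "day": rng.integers(1, 29, n),
        }
    )
    t_lo, t_hi = config.t2d_onset_year_range
    t2d = pd.to_datetime(
        {
            "year": rng.integers(t_lo, t_hi + 1, n),
            "month": rng.integers(1, 13, n),
            "day": rng.integers(1, 29, n),
        }
    )
    # T2D onset at adult age at the latest of the drawn date / 35th birthday
    t2d = pd.Series(np.maximum(t2d.values, (birth + pd.DateOffset(years=35)).values))
    in_catchment = rng.random(n) < config.in_catchment_fraction
    return pd.DataFrame(
        {
            "patient_id": ids,
            "sex": sex,
            "birth_date": birth,
            "t2d_diagnosis_date": t2d,
            "death_date": pd.NaT,
            "in_catchment": in_catchment,
        }
    )


def _plan_index_dates(
    config: SimulationConfig, rng: np.random.Generator, start: pd.Timestamp, end: pd.Timestamp
) -> dict[str, list[pd.Timestamp]]:
    """Renewal-process index dates per class over [start, end].

    The process starts at *start* — shortly before T2D onset, reflecting
    that complication risk concentrates after diagnosis (episodes drawn
    before the onset date become the prediabetic ones). Default gaps are
    ``window + 1 + Exp(1/rate)`` days, strictly wider than the episode
    window so the planned episodes are unambiguous ground truth.
    Adversarial mode draws gaps uniformly across the window boundary instead.
    """
    horizon_days = (end - start).days
    out: dict[str, list[pd.Timestamp]] = {}
    for cls in COMPLICATION_CLASSES:
        rate = config.episode_rates_per_year.get(cls, 0.0)
        dates: list[pd.Timestamp] = []
        if rate > 0:
            mean_gap_days = 365.25 / rate
            t = float(rng.exponential(mean_gap_days))
            while t <= horizon_days:
                dates.append(start + pd.Timedelta(days=int(t)))
                if config.adversarial_gaps:
                    gap = float(rng.integers(EPISODE_WINDOW_DAYS - 30, EPISODE_WINDOW_DAYS + 31))
                else:
                    gap = EPISODE_WINDOW_DAYS + 1 + float(rng.exponential(mean_gap_days))
                t += gap
        out[cls] = dates
    return out


def generate_event_history(
    config: SimulationConfig,
    patients: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate diagnosis events and the planned-episode skeleton.

    Returns ``(diagnoses, planned, patients)`` where ``planned`` holds one
    row per planned episode (before costs) including post-hoc comorbidity
    flags, and ``patients`` is the input table with death dates filled in.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed + 1)
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    comorb_idx = {c: i for i, c in enumerate(COMORBIDITY_CLASSES)}
    class_code = {
        "cerebrovascular": "CER",
        "cardiovascular": "CAR",
        "nephropathy": "NEP",
        "foot_disorder": "FOO",
        "eye": "EYE",
        "neurological": "NEU",
    }

    events: list[tuple] = []
    planned: list[dict] = []
    patients = patients.copy()
    death_dates: list[pd.Timestamp] = []

    for row in patients.itertuples(index=False):
        pid = row.patient_id
        # complication risk opens three years before T2D onset
        risk_start = max(start, row.t2d_diagnosis_date - pd.DateOffset(years=3))
        per_class = _plan_index_dates(config, rng, risk_start, end)
        episodes = sorted(
            ((d, cls) for cls, ds in per_class.items() for d in ds), key=lambda t: (t[0], t[1])
        )
        death = pd.NaT
        kept: list[tuple[pd.Timestamp, str]] = []
        for d, cls in episodes:
            if not pd.isna(death) and d > death:
                break
            kept.append((d, cls))
            if rng.random() < config.p_death_within_year and pd.isna(death):
                death = d + pd.Timedelta(days=int(rng.integers(30, EPISODE_WINDOW_DAYS)))
        death_dates.append(death)

        seen_any: list[pd.Timestamp] = []
        seen_same: dict[str, list[pd.Timestamp]] = {cls: [] for cls in COMPLICATION_CLASSES}
        comorb_events: list[tuple[pd.Timestamp, str]] = []
        for k, (d, cls) in enumerate(kept):
            mnemonic = class_code[cls]
            provider = (
                "other" if rng.random() < config.external_provider_fraction else "index_hospital"
            )
            # index event, then 0..k repeat diagnoses inside the window
            events.append((pid, d, f"{mnemonic}{rng.integers(0, 1000):03d}", "index_hospital"))
            n_rep = int(rng.integers(0, config.max_repeat_diagnoses + 1))
            rep_offsets = sorted(rng.integers(1, EPISODE_WINDOW_DAYS, n_rep)) if n_rep else []
            for off in rep_offsets:
                rd = d + pd.Timedelta(days=int(off))
                if not pd.isna(death) and rd > death:
                    continue
                events.append((pid, rd, f"{mnemonic}{rng.integers(0, 1000):03d}", provider))
            # comorbidity codes in the 2-year pre-index window
            for cm, prev in config.comorbidity_prevalence.items():
                if rng.random() < prev:
                    cd = d - pd.Timedelta(days=int(rng.integers(1, COMORBIDITY_WINDOW_DAYS)))
                    code = f"CM{comorb_idx[cm]:02d}X"
                    comorb_events.append((cd, code))
                    events.append((pid, cd, code, "other"))
            died_flag = int(not pd.isna(death) and death < d + pd.Timedelta(days=EPISODE_WINDOW_DAYS))
            # episode history is lookback-limited, matching the builder
            cutoff = d - pd.DateOffset(years=LOOKBACK_YEARS)
            n_any = sum(1 for p in seen_any if p >= cutoff)
            n_same = sum(1 for p in seen_same[cls] if p >= cutoff)
            etype = (
                "prediabetic"
                if d < row.t2d_diagnosis_date
                else ("incident" if n_any == 0 else "recurrent")
            )
            planned.append(
                {
                    "patient_id": pid,
                    "complication_class": cls,
                    "index_date": d,
                    "episode_type": etype,
                    "n_prior_any_class": n_any,
                    "n_prior_same_class": n_same,
                    "died_within_1y": died_flag,
                    "_comorb_events": None,  # filled below
                }
            )
            seen_any.append(d)
            seen_same[cls].append(d)
        # post-hoc comorbidity flags: scan every placed comorbidity event
        # against each episode's [index-730, index) window, so the sidecar is
        # exactly what the downstream window scan must find
        n_here = len(kept)
        for j in range(len(planned) - n_here, len(planned)):
            idx_date = planned[j]["index_date"]
            lo = idx_date - pd.Timedelta(days=COMORBIDITY_WINDOW_DAYS)
            flags = {c: 0 for c in COMORBIDITY_CLASSES}
            for cd, code in comorb_events:
                if lo <= cd < idx_date:
                    flags[COMORBIDITY_CLASSES[int(code[2:4])]] = 1
            del planned[j]["_comorb_events"]
            planned[j].update(flags)

    patients["death_date"] = pd.Series(death_dates, index=patients.index)
    diagnoses = pd.DataFrame(events, columns=["patient_id", "event_date", "code", "provider"])
    diagnoses = diagnoses.sort_values(["patient_id", "event_date", "code"], kind="stable")
    diagnoses = diagnoses.reset_index(drop=True)
    planned_cols = [
        "patient_id", "complication_class", "index_date", "episode_type",
        "n_prior_any_class", "n_prior_same_class", "died_within_1y", *COMORBIDITY_CLASSES,
    ]
    planned_df = pd.DataFrame(planned, columns=planned_cols if not planned else None)
    return diagnoses, planned_df, patients


def _covariate_row(ep: dict | pd.Series, patient: pd.Series, covariates: tuple[str, ...]) -> dict:
    idx = ep["index_date"]
    age = (idx - patient["birth_date"]).days / 365.25
    dur = max(0.0, (idx - patient["t2d_diagnosis_date"]).days / 365.25)
    base = {
        "woman": 1.0 if patient["sex"] == "female" else 0.0,
        "age_c75_per10": (age - 75.0) / 10.0,
        "t2d_duration_per5": dur / 5.0,
        "died_within_1y": float(ep["died_within_1y"]),
        "n_earlier_episodes": float(ep.get("n_prior_same_class", 0)),
        "high_prior_cost": float(ep.get("high_prior_cost", 0)),
    }
    for c in COMORBIDITY_CLASSES:
        base[c] = float(ep.get(c, 0))
    return {c: base[c] for c in covariates}


def generate_costs(
    config: SimulationConfig,
    patients: pd.DataFrame,
    planned: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw episode costs and split them into dated admission records.

    Each planned episode's one-year total is gamma with mean
    ``exp(x'beta_true)`` and shape ``gamma_shape``; the split across records
    conserves the drawn total exactly. Amounts are recorded in the nominal
    euros of their accounting year (real value divided by the price-index
    deflator) so downstream deflation is exercised. Returns
    ``(costs, truth)`` with the completed truth sidecar.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed + 2)
    pat = patients.set_index("patient_id")
    records: list[tuple] = []
    truth_rows: list[dict] = []
    prev_cost: dict[tuple[str, str], float] = {}

    planned = planned.sort_values(["patient_id", "index_date", "complication_class"], kind="stable")
    for i, ep in enumerate(planned.to_dict("records")):
        pid = ep["patient_id"]
        patient = pat.loc[pid]
        cls = ep["complication_class"]
        etype = ep["episode_type"]
        key = (pid, cls)
        high_prior = int(prev_cost.get(key, 0.0) > config.high_cost_threshold_eur)
        ep = dict(ep, high_prior_cost=high_prior)
        model_type = "incident" if etype != "recurrent" else "recurrent"
        covariates = INCIDENT_COVARIATES if model_type == "incident" else RECURRENT_COVARIATES
        beta = config.true_coefficients[f"{cls}:{model_type}"]
        x = _covariate_row(ep, patient, covariates)
        eta = beta.get("const", 0.0) + sum(beta.get(c, 0.0) * v for c, v in x.items())
        mean = float(np.exp(eta))
        total = float(rng.gamma(config.gamma_shape, mean / config.gamma_shape))
        prev_cost[key] = total

        idx = ep["index_date"]
        n_rec = 1 + int(rng.poisson(2.0))
        shares = rng.dirichlet(np.ones(n_rec))
        amounts = total * shares
        amounts[-1] = total - amounts[:-1].sum()  # exact conservation
        offsets = np.sort(rng.integers(0, EPISODE_WINDOW_DAYS, n_rec))
        offsets[0] = 0  # index admission is accounted on the index date
        cats = rng.choice(len(RESOURCE_CATEGORIES), n_rec, p=_category_probs())
        for r in range(n_rec):
            date = idx + pd.Timedelta(days=int(offsets[r]))
            cat = RESOURCE_CATEGORIES[cats[r]]
            if r == 0:
                cat = "inpatient_ward_days"
            units = 0
            if cat == "inpatient_ward_days":
                units = max(1, int(round(amounts[r] / 900.0)))
            elif cat == "outpatient_visits":
                units = 1
            year = int(date.year)
            nominal = amounts[r] / _deflator(config, year)
            records.append(
                (pid, f"{pid}-E{i:05d}-{r}", date, cat, nominal, year, units)
            )
        truth_rows.append(
            {
                **{k: ep[k] for k in (
                    "patient_id", "complication_class", "index_date", "episode_type",
                    "n_prior_any_class", "n_prior_same_class", "died_within_1y",
                )},
                **{c: ep[c] for c in COMORBIDITY_CLASSES},
                "high_prior_cost": high_prior,
                "true_mean_eur": mean,
                "drawn_year1_cost_eur": total,
            }
        )

    # low-intensity background (non-episode) costs across each lifespan
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    if config.background_cost_rate_per_year > 0:
        for row in patients.itertuples(index=False):
            exit_date = row.death_date if not pd.isna(row.death_date) else end
            span_years = max(0.0, (exit_date - start).days / 365.25)
            n_bg = int(rng.poisson(config.background_cost_rate_per_year * span_years))
            for b in range(n_bg):
                date = start + pd.Timedelta(days=int(rng.integers(0, max(1, (exit_date - start).days))))
                amt = float(rng.exponential(config.background_cost_mean_eur))
                cat = RESOURCE_CATEGORIES[int(rng.integers(0, len(RESOURCE_CATEGORIES)))]
                year = int(date.year)
                records.append(
                    (row.patient_id, f"{row.patient_id}-BG{b:04d}", date, cat,
                     amt / _deflator(config, year), year, 1 if cat == "outpatient_visits" else 0)
                )

    costs = pd.DataFrame(
        records,
        columns=[
            "patient_id", "admission_id", "accounting_date",
            "resource_category", "amount_eur", "price_year", "units",
        ],
    ).sort_values(["patient_id", "accounting_date", "admission_id"], kind="stable").reset_index(drop=True)
    truth_cols = [
        "patient_id", "complication_class", "index_date", "episode_type",
        "n_prior_any_class", "n_prior_same_class", "died_within_1y",
        *COMORBIDITY_CLASSES, "high_prior_cost", "true_mean_eur", "drawn_year1_cost_eur",
    ]
    truth = pd.DataFrame(truth_rows, columns=truth_cols if not truth_rows else None)
    return costs, truth


def _category_probs() -> np.ndarray:
    # ward days dominate hospital cost; remaining categories share the rest
    p = np.array([0.45, 0.15, 0.10, 0.06, 0.07, 0.05, 0.07, 0.05])
    return p / p.sum()


def generate_registry(config: SimulationConfig) -> Registry:
    """Run the full generator: cohort -> events -> costs, one seed."""
    rng = np.random.default_rng(config.rng_seed)
    patients = generate_cohort(config, rng)
    diagnoses, planned, patients = generate_event_history(config, patients, rng)
    costs, truth = generate_costs(config, patients, planned, rng)
    return Registry(patients, diagnoses, costs, truth, config)


def simulate_model_data(
    beta: dict[str, float],
    covariates: tuple[str, ...],
    n: int,
    gamma_shape: float,
    seed: int,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw a design matrix and gamma one-year costs straight from the model.

    This is the registry generator's statistical core without the calendar
    machinery: covariates from simple mixed distributions, response gamma
    with mean ``exp(x'beta)``. Used for estimator calibration at scale.
    """
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(index=range(n))
    for c in covariates:
        if c == "woman":
            X[c] = (rng.random(n) < 0.45).astype(float)
        elif c == "age_c75_per10":
            X[c] = rng.normal(-0.3, 1.0, n)
        elif c == "t2d_duration_per5":
            X[c] = rng.gamma(2.0, 1.0, n)
        elif c == "n_earlier_episodes":
            X[c] = rng.poisson(1.0, n).astype(float)
        else:  # binary flags: death, high prior cost, comorbidities
            X[c] = (rng.random(n) < 0.10).astype(float)
    eta = beta.get("const", 0.0) + sum(beta.get(c, 0.0) * X[c].to_numpy() for c in covariates)
    mu = np.exp(eta)
    y = rng.gamma(gamma_shape, mu / gamma_shape)
    return X, y


# ---------------------------------------------------------------------------
# registry I/O

_REQUIRED_COLUMNS = {
    "patients.csv": [
        "patient_id", "sex", "birth_date", "t2d_diagnosis_date", "death_date", "in_catchment",
    ],
    "diagnoses.csv": ["patient_id", "event_date", "code", "provider"],
    "costs.csv": [
        "patient_id", "admission_id", "accounting_date",
        "resource_category", "amount_eur", "price_year", "units",
    ],
}

_DATE_COLUMNS = {
    "patients.csv": ["birth_date", "t2d_diagnosis_date", "death_date"],
    "diagnoses.csv": ["event_date"],
    "costs.csv": ["accounting_date"],
    "truth.csv": ["index_date"],
}


def write_registry(registry: Registry, directory: str | Path) -> Path:
    """Write the registry tables as CSV (ISO-8601 dates) plus the echoed config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tables = {
        "patients.csv": registry.patients,
        "diagnoses.csv": registry.diagnoses,
        "costs.csv": registry.costs,
        "truth.csv": registry.truth,
    }
    for name, df in tables.items():
        out = df.copy()
        for col in _DATE_COLUMNS.get(name, []):
            if col in out:
                out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
        out.to_csv(directory / name, index=False)
    cfg = dataclasses.asdict(registry.config)
    cfg["birth_year_range"] = list(cfg["birth_year_range"])
    cfg["t2d_onset_year_range"] = list(cfg["t2d_onset_year_range"])
    with open(directory / "config_used.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return directory


def read_registry(directory: str | Path) -> Registry:
    """Read a registry directory written by :func:`write_registry`.

    Raises a ``ValueError`` naming the file and column if a required column
    is missing; the truth sidecar and config are optional (real registries
    have neither).
    """
    directory = Path(directory)
    frames: dict[str, pd.DataFrame] = {}
    for name, required in _REQUIRED_COLUMNS.items():
        path = directory / name
        if not path.exists():
            raise FileNotFoundError(f"registry file missing: {path}")
        df = pd.read_csv(path)
        for col in required:
            if col not in df.columns:
                raise ValueError(f"{name}: missing required column {col!r}")
        for col in _DATE_COLUMNS.get(name, []):
            if col in df.columns:
                df[col] = pd.to_datetime(df[col])
        frames[name] = df
    truth_path = directory / "truth.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path)
        if len(truth):
            truth["index_date"] = pd.to_datetime(truth["index_date"])
    else:
        truth = pd.DataFrame()
    cfg_path = directory / "config_used.yaml"
    if cfg_path.exists():
        with open(cfg_path) as fh:
            raw = yaml.safe_load(fh)
        raw["birth_year_range"] = tuple(raw["birth_year_range"])
        raw["t2d_onset_year_range"] = tuple(raw["t2d_onset_year_range"])
        raw["price_index"] = {int(k): float(v) for k, v in (raw.get("price_index") or {}).items()}
        config = SimulationConfig(**raw)
    else:
        config = SimulationConfig()
    return Registry(frames["patients.csv"], frames["diagnoses.csv"], frames["costs.csv"], truth, config)
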