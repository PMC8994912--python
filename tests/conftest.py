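import numpy as np
import pandas as pd
import pytest

from t2dcost import (
    COMPLICATION_CLASSES,
    SimulationConfig,
    default_synthetic_maps,
    generate_registry,
)


@pytest.fixture(scope="session")
def maps():
    return default_synthetic_maps()


@pytest.fixture(scope="session")
def small_registry():
    """Multi-class registry, background costs off, for structural checks."""
    cfg = SimulationConfig(n_patients=300, rng_seed=11, background_cost_rate_per_year=0.0)
    return generate_registry(cfg)


@pytest.fixture(scope="session")
def single_class_registry():
    """One active complication class: per-episode window sums are uncontaminated."""
    rates = {c: 0.0 for c in COMPLICATION_CLASSES}
    rates["cardiovascular"] = 0.25
    cfg = SimulationConfig(
        n_patients=400,
        rng_seed=23,
        episode_rates_per_year=rates,
        background_cost_rate_per_year=0.0,
    )
    return generate_registry(cfg)


def make_patients(rows):
    """Small hand-built patient table; rows = dicts with optional fields."""
    defaults = {
        "sex": "male",
        "birth_date": pd.Timestamp("1940-06-01"),
        "t2d_diagnosis_date": pd.Timestamp("2005-01-01"),
        "death_date": pd.NaT,
        "in_catchment": True,
    }
    out = []
    for i, r in enumerate(rows):
        rec = {"patient_id": f"P{i}", **defaults, **r}
        out.append(rec)
    df = pd.DataFrame(out)
    for c in ("birth_date", "t2d_diagnosis_date", "death_date"):
        df[c] = pd.to_datetime(df[c])
    return df


def make_events(rows):
    """Event table from (patient_id, date, code[, provider]) tuples."""
    recs = []
    for r in rows:
        pid, date, code = r[0], r[1], r[2]
        provider = r[3] if len(r) > 3 else "index_hospital"
        recs.append((pid, pd.Timestamp(date), code, provider))
    return pd.DataFrame(recs, columns=["patient_id", "event_date", "code", "provider"])
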