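"""Episode construction, classification, comorbidity windows, person-years."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import t2dcost.episodes as ep
from conftest import make_events, make_patients

D = pd.Timestamp  # shorthand for dates in fixtures


def days(*offsets, origin="2010-01-01"):
    o = pd.Timestamp(origin)
    return [o + pd.Timedelta(days=int(d)) for d in offsets]


# --- independent oracles ---------------------------------------------------

def oracle_from_index(day_numbers, window):
    """Fixed-window rule by exhaustive scan: next index is the first day at
    or beyond the previous index + window."""
    starts = []
    for d in day_numbers:
        if not starts or d - starts[-1] >= window:
            starts.append(d)
    return starts


def oracle_rolling_gap(day_numbers, window):
    """Rolling rule via gap splitting: a new episode starts where the gap
    since the immediately preceding event reaches the window."""
    starts = [day_numbers[0]] if day_numbers else []
    for prev, cur in zip(day_numbers, day_numbers[1:]):
        if cur - prev >= window:
            starts.append(cur)
    return starts


# --- build_episodes --------------------------------------------------------

def test_single_day_single_episode():
    eps = ep.build_episodes(days(0))
    assert len(eps) == 1 and eps[0][1] == days(0)


def test_member_absorbed_within_window():
    eps = ep.build_episodes(days(0, 100, 400), window_days=365)
    assert [e[0] for e in eps] == days(0, 400)
    assert eps[0][1] == days(0, 100)


def test_from_index_vs_rolling_gap_chain():
    """A chain 0/300/600 splits under the fixed-window rule but stays one
    episode under the rolling-gap rule."""
    chain = days(0, 300, 600)
    fixed = ep.build_episodes(chain, rule="from_index")
    rolling = ep.build_episodes(chain, rule="rolling_gap")
    assert [e[0] for e in fixed] == days(0, 600) == [days(*oracle_from_index([0, 300, 600], 365))[i] for i in range(2)]
    assert [e[0] for e in rolling] == days(0)
    assert oracle_rolling_gap([0, 300, 600], 365) == [0]


def test_unsorted_input_rejected():
    with pytest.raises(ValueError):
        ep.build_episodes(days(10, 0))


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    day_numbers=st.lists(st.integers(0, 2000), min_size=1, max_size=15, unique=True),
    window=st.integers(1, 400),
)
def test_both_rules_match_oracles(day_numbers, window):
    day_numbers = sorted(day_numbers)
    dates = days(*day_numbers)
    for rule, oracle in (("from_index", oracle_from_index), ("rolling_gap", oracle_rolling_gap)):
        got = [e[0] for e in ep.build_episodes(dates, window_days=window, rule=rule)]
        assert got == days(*oracle(day_numbers, window))
        # partition: every date in exactly one episode
        members = [d for _, mem in ep.build_episodes(dates, window_days=window, rule=rule) for d in mem]
        assert members == dates


def test_consecutive_indices_spaced_by_window():
    rng = np.random.default_rng(0)
    for _ in range(50):
        nums = sorted(rng.choice(3000, size=rng.integers(1, 20), replace=False))
        eps = ep.build_episodes(days(*nums))
        starts = [e[0] for e in eps]
        assert all((b - a).days >= 365 for a, b in zip(starts, starts[1:]))


# --- extract_class_events --------------------------------------------------

def test_extract_collapses_same_day_duplicates(maps):
    code_map, _ = maps
    ev = make_events([("P0", "2012-01-01", "CER1"), ("P0", "2012-01-01", "CER2")])
    out = ep.extract_class_events(ev, code_map)
    assert len(out) == 1


def test_event_in_two_classes_appears_in_both(maps):
    code_map, _ = maps
    from t2dcost.codemaps import CodeMap
    overlapping = CodeMap(entries={**code_map.entries, "cardiovascular": ("CAR", "CER1")})
    ev = make_events([("P0", "2012-01-01", "CER15")])
    out = ep.extract_class_events(ev, overlapping)
    assert set(out["complication_class"]) == {"cerebrovascular", "cardiovascular"}


def test_episode_count_invariant_to_event_order(maps):
    code_map, _ = maps
    ev = make_events(
        [("P0", d, "CER1") for d in ["2012-05-01", "2010-01-01", "2011-06-01", "2013-01-01"]]
    )
    shuffled = ev.sample(frac=1.0, random_state=3)
    a = ep.build_all_episodes(ep.extract_class_events(ev, code_map))
    b = ep.build_all_episodes(ep.extract_class_events(shuffled, code_map))
    pd.testing.assert_frame_equal(a, b)


# --- classify_episodes -----------------------------------------------------

def _episodes(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "complication_class", "index_date"]
    ).assign(index_date=lambda d: pd.to_datetime(d["index_date"]))


def test_first_diabetic_episode_is_incident():
    pats = make_patients([{"t2d_diagnosis_date": "2005-01-01"}])
    eps = _episodes([("P0", "eye", "2012-05-01")])
    out = ep.classify_episodes(eps, pats)
    assert out.loc[0, "episode_type"] == "incident"
    assert out.loc[0, "n_prior_same_class"] == 0


def test_history_scope_changes_classification():
    """An eye episode preceded only by a cardiovascular one is recurrent
    under any-class history but incident under same-class history."""
    pats = make_patients([{"t2d_diagnosis_date": "2005-01-01"}])
    eps = _episodes([("P0", "cardiovascular", "2010-03-01"), ("P0", "eye", "2013-05-01")])
    any_scope = ep.classify_episodes(eps, pats, history_scope="any_class")
    same_scope = ep.classify_episodes(eps, pats, history_scope="same_class")
    assert any_scope.loc[1, "episode_type"] == "recurrent"
    assert same_scope.loc[1, "episode_type"] == "incident"


def test_pre_onset_episode_is_prediabetic_and_counts_toward_history():
    pats = make_patients([{"t2d_diagnosis_date": "2012-01-01"}])
    eps = _episodes([("P0", "eye", "2010-05-01"), ("P0", "eye", "2013-05-01")])
    out = ep.classify_episodes(eps, pats)
    assert list(out["episode_type"]) == ["prediabetic", "recurrent"]


def test_lookback_horizon_limits_history():
    pats = make_patients([{"t2d_diagnosis_date": "1990-01-01", "birth_date": "1930-01-01"}])
    eps = _episodes([("P0", "eye", "1996-01-01"), ("P0", "eye", "2013-05-01")])
    out = ep.classify_episodes(eps, pats, lookback_years=15)
    assert out.loc[1, "episode_type"] == "incident"  # 1996 episode beyond 15y
    out2 = ep.classify_episodes(eps, pats, lookback_years=20)
    assert out2.loc[1, "episode_type"] == "recurrent"


def test_patient_without_t2d_flagged_non_diabetic():
    pats = make_patients([{"t2d_diagnosis_date": pd.NaT}])
    eps = _episodes([("P0", "eye", "2013-05-01")])
    out = ep.classify_episodes(eps, pats)
    assert out.loc[0, "episode_type"] == "non_diabetic"
    assert len(ep.filter_included(out, pats, "2012-01-01", "2016-12-31")) == 0


# --- flag_comorbidities ----------------------------------------------------

def test_comorbidity_window_boundaries(maps):
    _, comorbidity_map = maps
    pats_idx = pd.Timestamp("2014-01-01")
    eps = _episodes([("P0", "eye", pats_idx)])
    for offset, expected in [(-1, 1), (0, 0), (-730, 1), (-731, 0)]:
        ev = make_events([("P0", pats_idx + pd.Timedelta(days=offset), "CM00X")])
        out = ep.flag_comorbidities(ev, eps, comorbidity_map)
        assert out.loc[0, "myocardial_infarction"] == expected, offset


@settings(max_examples=100, deadline=None, derandomize=True)
@given(offsets=st.lists(st.integers(-1000, 1000), max_size=8))
def test_comorbidity_flags_match_window_scan(offsets, maps):
    _, comorbidity_map = maps
    idx = pd.Timestamp("2014-01-01")
    eps = _episodes([("P0", "eye", idx)])
    ev = make_events([("P0", idx + pd.Timedelta(days=o), "CM03A") for o in offsets])
    out = ep.flag_comorbidities(ev, eps, comorbidity_map)
    expected = int(any(-730 <= o < 0 for o in offsets))
    assert out.loc[0, "cerebrovascular_disease"] == expected


# --- inclusion filter ------------------------------------------------------

def test_inclusion_rules():
    pats = make_patients(
        [{"t2d_diagnosis_date": "2005-01-01"}, {"t2d_diagnosis_date": "2005-01-01", "in_catchment": False}]
    )
    eps = _episodes(
        [
            ("P0", "eye", "2012-01-01"),
            ("P0", "eye", "2016-12-31"),   # last day of the window: included
            ("P0", "eye", "2017-01-01"),   # outside
            ("P1", "eye", "2014-01-01"),   # out of catchment
        ]
    )
    classified = ep.classify_episodes(eps, pats)
    out = ep.filter_included(classified, pats, "2012-01-01", "2016-12-31")
    assert list(out["index_date"]) == days(0, origin="2012-01-01") + days(0, origin="2016-12-31")


def test_prediabetic_in_window_excluded():
    pats = make_patients([{"t2d_diagnosis_date": "2015-06-01"}])
    eps = _episodes([("P0", "eye", "2013-01-01")])
    classified = ep.classify_episodes(eps, pats)
    assert classified.loc[0, "episode_type"] == "prediabetic"
    assert len(ep.filter_included(classified, pats, "2012-01-01", "2016-12-31")) == 0


# --- person-years and incidence --------------------------------------------

def test_person_years_full_and_truncated():
    pats = make_patients(
        [
            {"t2d_diagnosis_date": "2000-01-01"},
            {"t2d_diagnosis_date": "2000-01-01", "death_date": "2012-07-02"},  # ~half of 2012
        ]
    )
    py = ep.person_years(pats.iloc[[0]], "2012-01-01", "2013-01-01")
    assert py == pytest.approx(366 / 365.25)
    py2 = ep.person_years(pats.iloc[[1]], "2012-01-01", "2013-01-01")
    assert py2 == pytest.approx(183 / 365.25)
    # sum equals per-patient hand computation
    assert ep.person_years(pats, "2012-01-01", "2013-01-01") == pytest.approx(py + py2)


def test_entry_delayed_to_t2d_onset():
    pats = make_patients([{"t2d_diagnosis_date": "2012-07-01"}])
    py = ep.person_years(pats, "2012-01-01", "2013-01-01")
    assert py == pytest.approx((pd.Timestamp("2013-01-01") - pd.Timestamp("2012-07-01")).days / 365.25)


def test_incidence_rate_examples():
    assert ep.incidence_rate(16_148, 102_803.0) == 15.7
    assert ep.incidence_rate(0, 100.0) == 0.0
    assert ep.incidence_rate(1, 100.0) == 1.0
    with pytest.raises(ValueError):
        ep.incidence_rate(1, 0.0)


# --- truth-sidecar recovery ------------------------------------------------

def test_exact_recovery_on_synthetic_truth(small_registry, maps):
    """Episode index dates, types, prior counts and comorbidity flags are
    recovered exactly from the generated event stream."""
    code_map, comorbidity_map = maps
    reg = small_registry
    eps = ep.build_all_episodes(ep.extract_class_events(reg.diagnoses, code_map))
    assert len(eps) == len(reg.truth)
    classified = ep.classify_episodes(eps, reg.patients)
    flagged = ep.flag_comorbidities(reg.diagnoses, classified, comorbidity_map)
    merged = flagged.merge(
        reg.truth, on=["patient_id", "complication_class", "index_date"], suffixes=("", "_t")
    )
    assert len(merged) == len(reg.truth)
    assert (merged["episode_type"] == merged["episode_type_t"]).all()
    assert (merged["n_prior_same_class"] == merged["n_prior_same_class_t"]).all()
    for cls in comorbidity_map.classes:
        assert (merged[cls] == merged[f"{cls}_t"]).all(), cls


def test_adversarial_gaps_keep_partition_property(maps):
    """Gaps straddling the window boundary may merge planned episodes, but
    every event still lands in exactly one episode."""
    from t2dcost import SimulationConfig, generate_registry

    code_map, _ = maps
    cfg = SimulationConfig(n_patients=60, rng_seed=13, adversarial_gaps=True)
    reg = generate_registry(cfg)
    class_events = ep.extract_class_events(reg.diagnoses, code_map)
    eps = ep.build_all_episodes(class_events)
    assert eps["n_member_events"].sum() == len(class_events)
    assert len(eps) <= len(reg.truth)
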