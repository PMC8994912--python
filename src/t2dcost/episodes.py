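"""Episode construction from dated, coded hospital diagnosis events.

A complication *episode* is the analysis unit: a one-year period anchored at
an index diagnosis of a complication class. Repeat same-class diagnoses
inside the window belong to the same episode; the next qualifying diagnosis
opens a new one. Episodes are classified as prediabetic (index before the
T2D diagnosis), incident (no prior episode inside a 15-year lookback under
the configured history scope) or recurrent, comorbidities are flagged from
the two-year pre-index window, and crude incidence is episodes per 100
person-years of cohort follow-up.

Two episodification rules are provided:

* ``from_index`` (default): a fixed 365-day window anchored at the index
  event — each event joins the open episode iff it falls strictly within
  365 days of that episode's index.
* ``rolling_gap``: a new episode opens only when the gap since the
  *previous event* (not the index) reaches the window length.

The rules differ on chains of events spaced below the window length; both
are exposed because registry conventions vary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .codemaps import PatternMap

logger = logging.getLogger(__name__)

EPISODE_WINDOW_DAYS = 365
COMORBIDITY_WINDOW_DAYS = 730
LOOKBACK_YEARS = 15
DAYS_PER_YEAR = 365.25


@dataclass
class Episode:
    """One (patient, class, index date) episode with its member events."""

    patient_id: str
    complication_class: str
    index_date: pd.Timestamp
    member_event_dates: list[pd.Timestamp] = field(default_factory=list)
    episode_type: str | None = None
    n_prior_same_class: int = 0
    n_prior_any_class: int = 0


def extract_class_events(events: pd.DataFrame, pattern_map: PatternMap) -> pd.DataFrame:
    """Route diagnosis events into per-class date streams.

    Returns a long frame ``(patient_id, complication_class, event_date)``,
    sorted, with same-day duplicates within a (patient, class) collapsed.
    An event whose code matches several classes appears in each of them.
    """
    rows = []
    if len(events):
        # classify unique codes once; registries repeat codes heavily
        code_classes = {c: pattern_map.classify(c) for c in events["code"].astype(str).unique()}
        for ev in events.itertuples(index=False):
            for cls in code_classes[str(ev.code)]:
                rows.append((ev.patient_id, cls, ev.event_date))
    out = pd.DataFrame(rows, columns=["patient_id", "complication_class", "event_date"])
    out = out.drop_duplicates().sort_values(
        ["patient_id", "complication_class", "event_date"], kind="stable"
    )
    return out.reset_index(drop=True)


def build_episodes(
    dates: list[pd.Timestamp],
    window_days: int = EPISODE_WINDOW_DAYS,
    rule: str = "from_index",
) -> list[tuple[pd.Timestamp, list[pd.Timestamp]]]:
    """Greedy left-to-right episodification of one sorted date stream.

    Returns ``[(index_date, member_dates), ...]`` where member dates include
    the index itself. Under ``from_index`` a date joins the open episode iff
    ``date - index < window_days``; under ``rolling_gap`` iff
    ``date - previous_event < window_days``.
    """
    if rule not in ("from_index", "rolling_gap"):
        raise ValueError(f"unknown episodification rule {rule!r}")
    dates = list(dates)
    for a, b in zip(dates, dates[1:]):
        if b <= a:
            raise ValueError("dates must be sorted ascending and unique")
    episodes: list[tuple[pd.Timestamp, list[pd.Timestamp]]] = []
    for d in dates:
        if episodes:
            anchor = episodes[-1][0] if rule == "from_index" else episodes[-1][1][-1]
            if (d - anchor).days < window_days:
                episodes[-1][1].append(d)
                continue
        episodes.append((d, [d]))
    return episodes


def build_all_episodes(
    class_events: pd.DataFrame,
    window_days: int = EPISODE_WINDOW_DAYS,
    rule: str = "from_index",
) -> pd.DataFrame:
    """Episodify every (patient, class) stream of :func:`extract_class_events`.

    Returns one row per episode with its index date, member count and member
    dates (as an ISO-date list); input row order does not matter.
    """
    rows = []
    if len(class_events):
        grouped = class_events.sort_values("event_date", kind="stable").groupby(
            ["patient_id", "complication_class"], sort=True
        )
        for (pid, cls), grp in grouped:
            for index_date, members in build_episodes(list(grp["event_date"]), window_days, rule):
                rows.append(
                    {
                        "patient_id": pid,
                        "complication_class": cls,
                        "index_date": index_date,
                        "n_member_events": len(members),
                        "member_event_dates": ";".join(d.strftime("%Y-%m-%d") for d in members),
                    }
                )
    out = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "complication_class", "index_date",
            "n_member_events", "member_event_dates",
        ],
    )
    return out.sort_values(
        ["patient_id", "index_date", "complication_class"], kind="stable"
    ).reset_index(drop=True)


def classify_episodes(
    episodes: pd.DataFrame,
    patients: pd.DataFrame,
    lookback_years: int = LOOKBACK_YEARS,
    history_scope: str = "any_class",
) -> pd.DataFrame:
    """Label each episode prediabetic / incident / recurrent and count priors.

    An episode is *prediabetic* when its index date precedes the patient's
    T2D diagnosis (patients without a T2D diagnosis date get every episode
    labelled ``non_diabetic``, excluded downstream). Among diabetic episodes
    the episode is *incident* when no earlier episode of the patient falls
    inside the lookback horizon under ``history_scope`` (``any_class``
    counts every complication class; ``same_class`` only the episode's
    own), else *recurrent*. Prediabetic episodes count toward the history.
    ``n_prior_same_class`` counts earlier same-class episodes inside the
    lookback regardless of scope (the recurrence covariate).
    """
    if history_scope not in ("any_class", "same_class"):
        raise ValueError(f"unknown history_scope {history_scope!r}")
    pat = patients.set_index("patient_id")
    out = episodes.sort_values(["patient_id", "index_date", "complication_class"], kind="stable").copy()
    types, n_same_list, n_any_list = [], [], []
    for pid, grp in out.groupby("patient_id", sort=False):
        t2d = pat.loc[pid, "t2d_diagnosis_date"]
        history: list[tuple[pd.Timestamp, str]] = []
        for ep in grp.itertuples(index=False):
            cutoff = ep.index_date - pd.DateOffset(years=lookback_years)
            in_look = [(d, c) for d, c in history if d >= cutoff]
            n_same = sum(1 for d, c in in_look if c == ep.complication_class)
            n_any = len(in_look)
            n_scope = n_any if history_scope == "any_class" else n_same
            if pd.isna(t2d):
                etype = "non_diabetic"
            elif ep.index_date < t2d:
                etype = "prediabetic"
            else:
                etype = "incident" if n_scope == 0 else "recurrent"
            types.append(etype)
            n_same_list.append(n_same)
            n_any_list.append(n_any)
            history.append((ep.index_date, ep.complication_class))
    out["episode_type"] = types
    out["n_prior_same_class"] = n_same_list
    out["n_prior_any_class"] = n_any_list
    return out.reset_index(drop=True)


def flag_comorbidities(
    events: pd.DataFrame,
    episodes: pd.DataFrame,
    comorbidity_map: PatternMap,
    window_days: int = COMORBIDITY_WINDOW_DAYS,
) -> pd.DataFrame:
    """Set one 0/1 column per comorbidity class on each episode.

    A flag is 1 iff some event with a matching code falls in
    ``[index - window_days, index)`` — strictly before the index date.
    """
    cm_events = extract_class_events(events, comorbidity_map).rename(
        columns={"complication_class": "comorbidity_class"}
    )
    out = episodes.copy()
    for cls in comorbidity_map.classes:
        out[cls] = 0
    if not len(out) or not len(cm_events):
        return out
    by_patient: dict = {
        pid: grp for pid, grp in cm_events.groupby("patient_id", sort=False)
    }
    for i, ep in enumerate(out.itertuples(index=False)):
        grp = by_patient.get(ep.patient_id)
        if grp is None:
            continue
        lo = ep.index_date - pd.Timedelta(days=window_days)
        hit = grp[(grp["event_date"] >= lo) & (grp["event_date"] < ep.index_date)]
        for cls in hit["comorbidity_class"].unique():
            out.iloc[i, out.columns.get_loc(cls)] = 1
    return out


def filter_included(
    episodes: pd.DataFrame,
    patients: pd.DataFrame,
    inclusion_start: str | pd.Timestamp,
    inclusion_end: str | pd.Timestamp,
) -> pd.DataFrame:
    """Apply the main-analysis inclusion rule.

    Keeps diabetic (incident or recurrent) episodes whose index date lies in
    the closed inclusion window and whose patient lives in the catchment
    area; prediabetic and non-diabetic episodes are dropped.
    """
    lo, hi = pd.Timestamp(inclusion_start), pd.Timestamp(inclusion_end)
    in_catch = patients.set_index("patient_id")["in_catchment"]
    keep = (
        episodes["episode_type"].isin(["incident", "recurrent"])
        & (episodes["index_date"] >= lo)
        & (episodes["index_date"] <= hi)
        & episodes["patient_id"].map(in_catch).fillna(False).astype(bool)
    )
    return episodes[keep].reset_index(drop=True)


def person_years(
    patients: pd.DataFrame,
    window_start: str | pd.Timestamp,
    window_end: str | pd.Timestamp,
) -> float:
    """Cohort follow-up in years over the window.

    Each patient contributes from max(window start, T2D diagnosis) to
    min(window end, death); negative spans contribute zero. Years are
    365.25 days.
    """
    lo, hi = pd.Timestamp(window_start), pd.Timestamp(window_end)
    total = 0.0
    for row in patients.itertuples(index=False):
        entry = max(lo, row.t2d_diagnosis_date) if not pd.isna(row.t2d_diagnosis_date) else lo
        exit_ = min(hi, row.death_date) if not pd.isna(row.death_date) else hi
        total += max(0.0, (exit_ - entry).days / DAYS_PER_YEAR)
    return total


def incidence_rate(n_episodes: int, person_years_: float) -> float:
    """Crude incidence per 100 person-years, to one decimal."""
    if person_years_ <= 0:
        raise ValueError("person_years must be positive")
    return round(100.0 * n_episodes / person_years_, 1)
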