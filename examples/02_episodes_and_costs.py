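"""From raw diagnoses to classified, costed complication episodes.

Each complication class is episodified separately: a diagnosis starts a
one-year episode, and further diagnoses of the same class within that year
belong to it. Episodes are then classified as prediabetic, incident (no
same- or other-class episode in the 15-year lookback) or recurrent, flagged
for comorbidities in the two years before the index date, and costed over
three one-year windows around the index date.
"""

from t2dcost import (
    SimulationConfig,
    build_all_episodes,
    classify_episodes,
    default_synthetic_maps,
    extract_class_events,
    filter_included,
    flag_comorbidities,
    generate_registry,
    incidence_rate,
    person_years,
    window_costs,
)

registry = generate_registry(SimulationConfig(n_patients=500, rng_seed=7))
code_map, comorbidity_map = default_synthetic_maps()

events = extract_class_events(registry.diagnoses, code_map)
episodes = build_all_episodes(events)
episodes = classify_episodes(episodes, registry.patients)
episodes = flag_comorbidities(registry.diagnoses, episodes, comorbidity_map)

print("episodes by type:")
print(episodes["episode_type"].value_counts().to_string())

included = filter_included(episodes, registry.patients, "2012-01-01", "2016-12-31")
print(f"\nincluded 2012-2016 (diabetic, in catchment): {len(included)}")
print(included.groupby(["episode_type", "complication_class"]).size().to_string())

costs = window_costs(registry.costs, included)
print("\nmean first-year cost by class (EUR):")
merged = included.assign(year1_eur=costs["year1_eur"].to_numpy())
print(merged.groupby("complication_class")["year1_eur"].mean().round(0).to_string())

py = person_years(registry.patients, "2012-01-01", "2016-12-31")
print(f"\nperson-years at risk: {py:.0f}")
print(f"crude episode rate per 100 person-years: {incidence_rate(len(included), py)}")
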