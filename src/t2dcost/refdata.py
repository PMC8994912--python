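"""Published reference values from the Finnish university-hospital registry
analysis of T2D complication costs.

These are the self-contained printed numbers of that analysis — the
cerebrovascular cost-model coefficient tables (intercept in 2019 euros,
exponentiated covariate ratios), the included-episode counts per
complication class, the cohort person-years, and the (men, n) pairs of the
descriptive tables. They serve as worked-example inputs: the package's
arithmetic (table-based prediction, crude incidence, descriptive
percentages) must reproduce the printed derived values from them. The
underlying patient-level registry is not public, so model *fits* are never
checked against these tables — only the printed arithmetic is.
"""

from __future__ import annotations

#: Incident cerebrovascular cost model: intercept (euros, reference profile =
#: 75-year-old newly diagnosed man, no comorbidities, alive at one year) and
#: exponentiated covariate ratios.
INCIDENT_CEREBROVASCULAR = {
    "intercept_eur": 9663.62,
    "ratios": {
        "woman": 0.85,
        "age_c75_per10": 0.81,
        "t2d_duration_per5": 1.05,
        "died_within_1y": 1.53,
        "rheumatological_disease": 1.28,
        "dementia": 0.49,
        "cerebrovascular_disease": 1.07,
        "congestive_heart_failure": 1.36,
        "moderate_or_severe_renal_disease": 1.33,
        "chronic_pulmonary_disease": 1.00,
        "myocardial_infarction": 1.39,
        "any_malignancy": 1.11,
        "peripheral_vascular_disease": 1.36,
        "peptic_ulcer_disease": 1.45,
        "any_chronic_liver_disease": 1.27,
    },
}

#: Recurrent cerebrovascular cost model (adds the recurrence covariates).
RECURRENT_CEREBROVASCULAR = {
    "intercept_eur": 8980.94,
    "ratios": {
        "woman": 0.91,
        "age_c75_per10": 0.86,
        "t2d_duration_per5": 1.00,
        "died_within_1y": 1.05,
        "n_earlier_episodes": 0.97,
        "high_prior_cost": 1.62,
        "rheumatological_disease": 1.77,
        "dementia": 0.84,
        "cerebrovascular_disease": 0.80,
        "congestive_heart_failure": 0.98,
        "diabetes_with_chronic_complications": 1.50,
        "moderate_or_severe_renal_disease": 1.66,
        "chronic_pulmonary_disease": 1.29,
        "myocardial_infarction": 1.00,
        "any_malignancy": 1.03,
        "peripheral_vascular_disease": 1.29,
        "peptic_ulcer_disease": 1.36,
        "any_chronic_liver_disease": 2.03,
    },
}

#: Included complication episodes per class, 2012–2016 inclusion window.
INCLUDED_EPISODES_BY_CLASS = {
    "cardiovascular": 7225,
    "eye": 3083,
    "foot_disorder": 2266,
    "cerebrovascular": 2222,
    "nephropathy": 996,
    "neurological": 356,
}

#: Total included episodes and cohort follow-up behind the crude incidence.
TOTAL_INCLUDED_EPISODES = 16_148
COHORT_PERSON_YEARS = 102_803.0

#: (men, n) pairs of the incident-episode descriptive table.
INCIDENT_MEN_COUNTS = {
    "foot_disorder": (636, 1094),
    "nephropathy": (236, 371),
    "cardiovascular": (1056, 1870),
    "cerebrovascular": (699, 1367),
    "neurological": (129, 220),
    "eye": (404, 855),
}

#: (men, n) pairs of the recurrent-episode descriptive table.
RECURRENT_MEN_COUNTS = {
    "nephropathy": (427, 625),
    "foot_disorder": (806, 1172),
    "cardiovascular": (3070, 5355),
    "neurological": (75, 136),
    "cerebrovascular": (490, 855),
    "eye": (1163, 2228),
}

#: Published percentages paired with the counts above (one decimal).
INCIDENT_MEN_PERCENT = {
    "foot_disorder": 58.1,
    "nephropathy": 63.6,
    "cardiovascular": 56.5,
    "cerebrovascular": 51.1,
    "neurological": 58.6,
    "eye": 47.3,
}
RECURRENT_MEN_PERCENT = {
    "nephropathy": 68.3,
    "foot_disorder": 68.8,
    "cardiovascular": 57.3,
    "neurological": 55.1,
    "cerebrovascular": 57.3,
    "eye": 52.2,
}

#: Crude complication incidence per 100 person-years, as published.
PUBLISHED_CRUDE_INCIDENCE = 15.7

#: Worked footnote predictions: female reference profile, cerebrovascular.
PUBLISHED_FEMALE_REFERENCE_PREDICTION = {
    "incident": 8214.077,   # 0.85 x 9663.62
    "recurrent": 8172.655,  # 0.91 x 8980.94
}
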