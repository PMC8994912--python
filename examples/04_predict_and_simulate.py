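"""Predict expected costs for covariate profiles, with uncertainty.

Two prediction routes:

1. `predict_from_table` works from a *printed* coefficient table — an
   intercept in euros and multiplicative cost ratios — exactly as a reader
   of a published table would, e.g. for a woman aged 75 without recorded
   comorbidities (the female reference profile).
2. `simulate_cost_distribution` works from a fitted model object and
   propagates coefficient uncertainty by drawing coefficient vectors from
   a multivariate normal (Cholesky factor of the robust covariance),
   yielding a distribution of expected costs for the profile.
"""

from t2dcost import (
    PredictionRequest,
    RunConfig,
    SimulationConfig,
    predict_from_table,
    predict_mean,
    run_pipeline,
    simulate_cost_distribution,
)
from t2dcost.refdata import INCIDENT_CEREBROVASCULAR, RECURRENT_CEREBROVASCULAR

# Route 1: the published worked examples, from printed tables alone.
for label, table in (("incident", INCIDENT_CEREBROVASCULAR),
                     ("recurrent", RECURRENT_CEREBROVASCULAR)):
    pred = predict_from_table(table["intercept_eur"], table["ratios"], {"woman": 1.0})
    print(f"published {label} cerebrovascular model, female reference profile: "
          f"{pred:.3f} EUR")

# Route 2: a model fitted on synthetic data, with uncertainty.
result = run_pipeline(RunConfig(
    simulation=SimulationConfig(n_patients=2500, rng_seed=3),
    seed=3,
    out_dir="scratch/example_run",
))
fit = result.fits["cardiovascular:recurrent"]

profile = {"woman": 1.0, "age_c75_per10": -1.0}  # woman aged 65
point = predict_mean(fit, profile)
request = PredictionRequest("cardiovascular:recurrent", profile=profile,
                            n_draws=20_000, rng_seed=12)
dist = simulate_cost_distribution(request, fit)

print(f"\nsynthetic recurrent cardiovascular model, woman aged 65:")
print(f"  point prediction:      {point:,.0f} EUR")
print(f"  mean over draws:       {dist.mean:,.0f} EUR")
print(f"  95% interval:          {dist.q2_5:,.0f} - {dist.q97_5:,.0f} EUR")
print(f"  interquartile range:   {dist.q25:,.0f} - {dist.q75:,.0f} EUR")
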