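# Methods note

This note records what `t2dcost` computes, the exact conventions used, the
defaults and their units, what the synthetic registry generator does and
does not emulate, and the numerical choices in the estimator. It is the
reference for every deliberate design decision in the package.

## 1. Cohort and inclusion

The analysis targets a catchment-area cohort of people with type 2
diabetes followed in hospital registries. In this package the cohort is
synthetic (section 6); the analysis code is agnostic to the source and
only requires the documented table schemas (`registry.read_registry`
validates them and names any missing column).

An episode enters the analysed set when all of the following hold:

- the patient is flagged `in_catchment`;
- the index date lies in the inclusion window (closed interval, default
  2012-01-01 … 2016-12-31);
- the episode is **incident** or **recurrent** (prediabetic and
  non-diabetic episodes are described but not modelled).

Person-years at risk accumulate from the later of the inclusion start and
the type 2 diabetes diagnosis date to the earlier of the inclusion end and
the death date, for in-catchment patients. The crude episode rate is
reported per 100 person-years, rounded to one decimal.

## 2. Code maps

Complication classes: `cerebrovascular`, `cardiovascular` (other
cardiovascular), `nephropathy`, `foot_disorder`, `eye`, `neurological`.
Comorbidities are a modified Charlson set of 12 classes: myocardial
infarction, congestive heart failure, peripheral vascular disease,
cerebrovascular disease, dementia, chronic pulmonary disease,
rheumatological disease, peptic ulcer disease, any chronic liver disease
(mild and moderate/severe merged), diabetes with chronic complications,
moderate or severe renal disease, and any malignancy (including
metastatic). HIV/AIDS, hemiplegia/paraplegia and diabetes *without*
complications are deliberately excluded from the set.

Maps are prefix-pattern based: a code belongs to a class when its
normalized form (upper-case, dots stripped) starts with any listed
pattern. A code may match several classes; complication maps must not let
one code start episodes of two classes, comorbidity maps may overlap.
Maps load from YAML (`load_code_maps`); `default_synthetic_maps` supplies
the synthetic vocabulary (`CER…`, `CAR…`, `NEP…`, `FOO…`, `EYE…`, `NEU…`
complication codes, `CM00…CM11` comorbidity codes).

## 3. Episodes

Within one patient and one complication class, diagnosis dates are scanned
left to right. Rule `from_index` (default): a diagnosis starts an episode
only if at least `window_days` (default 365) have elapsed since the *index
date* of the previous episode; anything earlier belongs to that episode.
Rule `rolling_gap` (alternative): a new episode starts when the gap since
the *previous diagnosis* reaches `window_days`. `from_index` is the default
because the costing windows are anchored at the index date and a fixed
one-year episode matches the one-year cost attribution exactly.

Classification per episode:

- **non_diabetic** — patient has no type 2 diabetes diagnosis date;
- **prediabetic** — index date strictly before the diabetes diagnosis;
- **incident** — diabetic at index and no prior complication episode of
  *any* class (scope `any_class`, default; `same_class` is available)
  within a 15-year lookback from the index date;
- **recurrent** — otherwise. Prediabetic episodes count as history: a
  later episode after the diabetes diagnosis is recurrent.

Comorbidity flags are set from any matching diagnosis in the half-open
window `[index − 730 days, index)`.

## 4. Cost attribution

Cost records carry an accounting date, a resource category
(`inpatient_ward_days`, `outpatient_visits`, `emergency_visits`,
`day_surgery`, `medications`, `laboratory`, `imaging`, `other`), a nominal
euro amount and its price year. Amounts are deflated to the reference year
(2019) with a `PriceIndex`; the identity index (all deflators 1) is the
default for synthetic data, and the reference-year deflator must be 1.

Each episode accrues deflated costs in three half-open windows relative to
its index date: `pre_year` `[idx−365, idx)`, `year1` `[idx, idx+365)`,
`year2` `[idx+365, idx+730)`. A record on the index date belongs to
`year1`; a record exactly 730 days after the index belongs to no window.
Within one episode the three window totals partition the records that fall
in `[idx−365, idx+730)`, overall and per resource category (asserted at
runtime). When a patient has overlapping episodes of *different* classes,
a record can serve several episodes — window sums are per-episode
attributions, not a partition of total expenditure across episodes.

`high_prior_cost` flags an episode whose patient had an earlier episode of
the same class with first-year cost strictly above 50 000 € (2019 euros).
`threshold_percentile_check` reports where that threshold sits in the
observed first-year cost distribution.

## 5. Cost models

For each complication class × episode type (incident, recurrent) stratum
with enough data, first-year cost is modelled with a gamma GLM, log link:

E[y | x] = exp(x'β).

Zero-cost episodes are excluded from fitting (gamma support is positive;
in the synthetic registry every episode has an index admission, so this
exclusion is empty by construction).

Covariates (reference profile: man, aged 75, no recorded comorbidities,
alive through year 1):

- `woman` (0/1);
- `age_c75_per10` — (age at index − 75)/10, in decades;
- `t2d_duration_per5` — years since diabetes diagnosis / 5 (incident and
  recurrent models);
- `died_within_1y` (0/1);
- the 12 comorbidity indicators;
- recurrent models only: `n_earlier_episodes` (count of earlier same-class
  episodes) and `high_prior_cost` (0/1).

Fitting uses IRLS via `statsmodels` (`sm.GLM` with `Gamma(log)`); the
package raises on non-convergence and on rank deficiency, naming the
collinear columns. Zero-variance covariates in a stratum are dropped with
a notice. Dispersion is the deviance-based estimate.

**Robust covariance.** Because patients contribute multiple episodes,
inference uses a hand-written cluster-robust sandwich clustered on
patient: bread (X'X)^{-1} from the expected information of the log-link
gamma score x_i (y_i − μ_i)/μ_i (dispersion-free estimating equations),
meat from cluster score sums, CR1 small-sample factor
G/(G−1) · (n−1)/(n−p). With all-singleton clusters this reduces exactly to
HC1, which is verified in tests; agreement with `statsmodels`
`cov_type="cluster"` is to ~1% (it uses observed information in the
bread). `robust="hc"` gives the heteroskedasticity-robust version.

Reported per model: exponentiated coefficients (cost ratios; the
exponentiated intercept is the reference-profile cost in euros),
log-scale robust SEs, p-values with `*` (p<0.05) / `**` (p<0.01) stars,
McFadden pseudo-R² (1 − llf/llnull), and average marginal effects —
β_j · mean(exp(x'β)) for continuous covariates, the mean counterfactual
difference for binary ones.

**Predictions.** `predict_mean` evaluates exp(x'β̂) for a profile (ratios
for unnamed covariates default to reference level 0). `predict_from_table`
does the same from a *printed* table — euro intercept times the ratios of
active covariates — so published tables can be used without refitting.

## 6. Predictive simulation

`simulate_cost_distribution` propagates coefficient uncertainty: draw
β(s) = β̂ + L z, with L the Cholesky factor of the chosen covariance
(sandwich by default, model-based optional; a 1e-10 diagonal jitter makes
positive-semidefinite matrices factorable), and evaluate exp(x'β(s)) for
the profile over `n_draws` draws. Optionally gamma outcome noise at the
fitted shape is layered on, giving a predictive distribution for an
individual episode rather than for the mean. Summaries: mean, SD, 2.5/25/
50/75/97.5 percentiles. A zero covariance degenerates exactly to the point
prediction (tested). `refit_subset_model` refits on covariate subsets for
sensitivity analyses, down to the intercept-only model whose closed form
exp(β̂₀) = ȳ is verified to 10 significant digits.

## 7. Synthetic registry generator

The generator (`SimulationConfig`, `generate_registry`) emulates the study
conditions; its defaults are the study conditions and are never tuned to
any downstream check.

- **Cohort** (default `n_patients=2500`): sex ≈ balanced, birth years such
  that ages at episodes centre near 75, type 2 diabetes diagnosis dates
  spread over 1996–2016, 90% in catchment, death hazard rising with age.
- **Episodes**: per class, a renewal process with inter-arrival
  `window+1+Exp(365.25/rate)` days (gaps always exceed the episode window,
  so planned events are exactly the episodes the builder must find; an
  `adversarial_gaps` mode instead straddles the window boundary to stress
  the builder). Risk starts at max(study start, diabetes diagnosis − 3
  years), so prediabetic, incident and recurrent episodes all occur.
  Default rates per year at risk: cardiovascular 0.08, eye 0.04, foot
  disorder 0.03, cerebrovascular 0.025, nephropathy 0.015, neurological
  0.006. Each episode kills the patient within the year with probability
  0.08 (`died_within_1y`), truncating later events.
- **Costs**: each episode's first-year cost is drawn Gamma(shape=2, mean
  exp(x'β_true)) with `β_true` the documented generating coefficients
  (e.g. woman log 0.90, age-decade log 0.85, died log 1.45, renal disease
  log 1.80, high prior cost log 2.0). The drawn total is split across
  dated records in `[idx, idx+365)` with exact conservation (the last
  record absorbs the rounding remainder); the first record sits on the
  index date (the index admission). Background (non-episode) cost records
  arrive at 0.2/year with mean 150 €. Ward days/visit units accompany the
  relevant categories.
- **Truth sidecar**: for every planned episode, its class, type, prior
  counts (lookback-limited exactly as the builder's rule), comorbidity
  flags, `died_within_1y`, `high_prior_cost`, the true mean and the drawn
  cost. Tests recover the sidecar from raw tables with 100% agreement.
- **Determinism**: one `numpy.random.default_rng(seed)` threaded through
  all stages; identical configs give byte-identical registries and
  pipeline outputs (tested).

Not emulated: primary-care and out-of-area costs (`impute_external_costs`
exists as an explicit hook and defaults to zero imputation), price
inflation (identity index), coded severity within classes, and
within-year cost timing patterns (uniform spread).

`simulate_model_data(beta, covariates, n, shape, seed)` bypasses the
registry and draws design + gamma outcome directly from the model; it is
used for replicate-level calibration (coverage) tests.

## 8. Numerical and testing choices

- Seeds are plain Python ints below 2³¹; every stochastic public function
  takes an explicit seed.
- Monetary values are float64 euros; window sums are order-stable
  (grouped sums over date-sorted records), making CSV outputs
  byte-reproducible.
- `incidence_rate` and `men_percent` round half-even to one decimal, the
  printing convention of the reference tables.
- Dual-route validation: the sandwich covariance is checked exactly
  against a direct HC1 formula oracle and approximately against
  `statsmodels`; episodification is checked against brute-force scan
  oracles over randomized event sets; intercept-only and AME closed forms
  are checked against analytic values; parameter recovery and 95% interval
  coverage are checked on registries/replicates with known β_true.
- Known limitation: with several active complication classes, cross-class
  window overlap makes per-episode window sums non-conservative across
  episodes (section 4); conservation tests therefore run on single-class
  configurations.
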