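"""Gamma cost model: design, fitting, sandwich covariance, AME, predictions."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from t2dcost.model import (
    GammaFit,
    ModelSpec,
    average_marginal_effects,
    build_design,
    cluster_sandwich,
    coefficient_table,
    fit_gamma_glm,
    fit_stratum,
    mcfadden_r2,
    predict_from_table,
    predict_mean,
)
from t2dcost.registry import INCIDENT_COVARIATES, simulate_model_data


def _fit(beta, covs, n=800, shape=2.0, seed=1, clusters=None):
    X, y = simulate_model_data(beta, covs, n, shape, seed)
    Xd = pd.concat([pd.Series(1.0, index=X.index, name="const"), X], axis=1)
    return fit_gamma_glm(Xd, y, clusters), Xd, y


# --- design ----------------------------------------------------------------

def test_reference_profile_design_row():
    spec = ModelSpec("cerebrovascular", "incident")
    data = pd.DataFrame(
        {
            "patient_id": ["P0", "P1"],
            "year1_eur": [5000.0, 6000.0],
            **{c: [0.0, 1.0] for c in spec.covariates},
        }
    )
    X, y, clusters, _ = build_design(data, spec)
    assert list(X.columns)[0] == "const"
    assert X.iloc[0].drop("const").eq(0).all()  # reference row: all zeros


def test_covariate_scalings():
    """Age 85 -> 1.0 on the decade scale; T2D duration 10y -> 2.0 on 5y scale."""
    from t2dcost.model import attach_covariates
    pats = pd.DataFrame(
        {
            "patient_id": ["P0"],
            "sex": ["male"],
            "birth_date": pd.to_datetime(["1930-01-01"]),
            "t2d_diagnosis_date": pd.to_datetime(["2005-01-01"]),
            "death_date": [pd.NaT],
            "in_catchment": [True],
        }
    )
    eps = pd.DataFrame({"patient_id": ["P0"], "index_date": pd.to_datetime(["2015-01-01"])})
    out = attach_covariates(eps, pats)
    assert out.loc[0, "age_c75_per10"] == pytest.approx(1.0, abs=0.01)
    assert out.loc[0, "t2d_duration_per5"] == pytest.approx(2.0, abs=0.01)
    assert out.loc[0, "woman"] == 0.0
    assert out.loc[0, "died_within_1y"] == 0.0


def test_zero_cost_rows_dropped_and_zero_variance_columns_named(caplog):
    spec = ModelSpec("eye", "incident")
    n = 30
    rng = np.random.default_rng(0)
    data = pd.DataFrame({"patient_id": [f"P{i}" for i in range(n)], "year1_eur": rng.gamma(2, 500, n)})
    for c in spec.covariates:
        data[c] = 0.0
    data["woman"] = rng.integers(0, 2, n).astype(float)
    data.loc[0, "year1_eur"] = 0.0
    with caplog.at_level("WARNING"):
        X, y, _, info = build_design(data, spec)
    assert info["n_dropped_zero_cost"] == 1
    assert "died_within_1y" in info["dropped_covariates"]
    assert len(y) == n - 1 and (y > 0).all()
    assert list(X.columns) == ["const", "woman"]


def test_incident_spec_rejects_recurrence_covariates():
    with pytest.raises(ValueError):
        ModelSpec("eye", "incident", covariates=("woman", "n_earlier_episodes"))


# --- fitting ---------------------------------------------------------------

def test_intercept_only_closed_form():
    """Gamma log-link MLE with only an intercept fits the sample mean exactly."""
    rng = np.random.default_rng(8)
    y = rng.gamma(2.0, 4000.0, 500)
    fit = fit_gamma_glm(pd.DataFrame({"const": np.ones(len(y))}), y)
    assert np.exp(fit.params["const"]) == pytest.approx(y.mean(), rel=1e-10)


def test_parameter_recovery_within_3_se():
    beta = {
        "const": float(np.log(9000.0)),
        "woman": float(np.log(0.85)),
        "age_c75_per10": float(np.log(0.8)),
        "died_within_1y": float(np.log(1.5)),
    }
    covs = ("woman", "age_c75_per10", "died_within_1y")
    fit, _, _ = _fit(beta, covs, n=5000, seed=10)
    se = np.sqrt(np.diag(fit.cov_sandwich))
    for j, term in enumerate(fit.terms):
        assert abs(fit.params[term] - beta[term]) < 3 * se[j], term


def test_duplicating_rows_leaves_estimates_unchanged():
    beta = {"const": float(np.log(5000.0)), "woman": float(np.log(0.9))}
    fit, X, y = _fit(beta, ("woman",), n=300, seed=2)
    X2 = pd.concat([X, X], ignore_index=True)
    y2 = np.concatenate([y, y])
    fit2 = fit_gamma_glm(X2, y2)
    assert np.allclose(fit.params, fit2.params, rtol=1e-8)


def test_rank_deficient_design_names_columns():
    rng = np.random.default_rng(4)
    X = pd.DataFrame({"const": 1.0, "a": rng.random(50)})
    X["b"] = 2.0 * X["a"]
    y = rng.gamma(2.0, 100.0, 50)
    with pytest.raises(ValueError, match="b"):
        fit_gamma_glm(X, y)


def test_scale_equivariance_of_predictions():
    beta = {"const": float(np.log(5000.0)), "woman": float(np.log(0.9))}
    fit, X, y = _fit(beta, ("woman",), n=400, seed=6)
    fit_scaled = fit_gamma_glm(X, 10.0 * y)
    assert np.exp(fit_scaled.params["const"]) == pytest.approx(10.0 * np.exp(fit.params["const"]), rel=1e-6)
    assert np.exp(fit_scaled.params["woman"]) == pytest.approx(np.exp(fit.params["woman"]), rel=1e-6)


# --- sandwich covariance ---------------------------------------------------

def test_singleton_clusters_equal_direct_hc1_formula():
    """With singleton clusters the estimator equals HC1 computed from the
    direct formula with expected-information bread."""
    beta = {"const": float(np.log(7000.0)), "woman": float(np.log(0.9))}
    fit, X, y = _fit(beta, ("woman",), n=250, seed=3)
    Xv = X.to_numpy()
    mu = np.exp(Xv @ fit.params.to_numpy())
    r = (y - mu) / mu
    bread = np.linalg.inv(Xv.T @ Xv)
    meat = (Xv * (r**2)[:, None]).T @ Xv
    n, p = Xv.shape
    hc1 = n / (n - p) * bread @ meat @ bread
    assert np.allclose(fit.cov_sandwich.to_numpy(), hc1, rtol=1e-10)


def test_sandwich_close_to_statsmodels_cluster():
    beta = {"const": float(np.log(7000.0)), "woman": float(np.log(0.9)), "died_within_1y": 0.3}
    covs = ("woman", "died_within_1y")
    clusters = np.repeat(np.arange(300), 2)
    fit, X, y = _fit(beta, covs, n=600, seed=12, clusters=clusters)
    fam = sm.families.Gamma(link=sm.families.links.Log())
    res = sm.GLM(y, X.to_numpy(), family=fam).fit(
        cov_type="cluster", cov_kwds={"groups": clusters}
    )
    ours = np.sqrt(np.diag(fit.cov_sandwich))
    theirs = res.bse
    assert np.allclose(ours, theirs, rtol=0.05)


def test_duplicated_clusters_shrink_se_by_sqrt2():
    beta = {"const": float(np.log(7000.0)), "woman": float(np.log(0.9))}
    fit, X, y = _fit(beta, ("woman",), n=400, seed=9)
    X2 = pd.concat([X, X], ignore_index=True)
    y2 = np.concatenate([y, y])
    fit2 = fit_gamma_glm(X2, y2, clusters=np.arange(len(y2)))
    ratio = np.sqrt(np.diag(fit2.cov_sandwich)) / np.sqrt(np.diag(fit.cov_sandwich))
    assert np.allclose(ratio, 1.0 / np.sqrt(2.0), atol=0.02)


def test_sandwich_symmetric_psd():
    beta = {"const": float(np.log(7000.0)), "woman": 0.0}
    fit, _, _ = _fit(beta, ("woman",), n=200, seed=14)
    S = fit.cov_sandwich.to_numpy()
    assert np.allclose(S, S.T)
    assert (np.linalg.eigvalsh(S) >= -1e-12).all()
    assert (np.diag(S) >= 0).all()


# --- pseudo-R², tables, predictions ----------------------------------------

def test_mcfadden_matches_stored_loglikelihoods():
    beta = {"const": float(np.log(6000.0)), "woman": float(np.log(0.7))}
    fit, _, _ = _fit(beta, ("woman",), n=500, seed=21)
    r2 = mcfadden_r2(fit)
    assert r2 == pytest.approx(1.0 - fit.llf / fit.ll_null, rel=1e-12)
    assert 0.0 < r2 < 1.0


def test_null_model_pseudo_r2_is_zero():
    rng = np.random.default_rng(3)
    y = rng.gamma(2.0, 100.0, 200)
    fit = fit_gamma_glm(pd.DataFrame({"const": np.ones(len(y))}), y)
    assert mcfadden_r2(fit) == pytest.approx(0.0, abs=1e-10)


def test_coefficient_table_stars_match_normal_tail():
    from scipy import stats

    beta = {"const": float(np.log(6000.0)), "woman": float(np.log(0.6)), "died_within_1y": 0.0}
    fit, _, _ = _fit(beta, ("woman", "died_within_1y"), n=2000, seed=30)
    table = coefficient_table(fit).set_index("term")
    for term in ("woman", "died_within_1y"):
        z = fit.params[term] / np.sqrt(fit.cov_sandwich.loc[term, term])
        p = 2 * stats.norm.sf(abs(z))
        assert table.loc[term, "p_value"] == pytest.approx(p, rel=1e-9)
        expected_star = "**" if p < 0.01 else ("*" if p < 0.05 else "")
        assert table.loc[term, "stars"] == expected_star
    assert table.loc["const", "exp_coef"] == pytest.approx(np.exp(fit.params["const"]))


def test_predict_mean_reference_and_profiles():
    beta = {"const": float(np.log(5000.0)), "woman": float(np.log(0.9))}
    fit, _, _ = _fit(beta, ("woman",), n=300, seed=17)
    assert predict_mean(fit, {}) == pytest.approx(np.exp(fit.params["const"]))
    assert predict_mean(fit, {"woman": 1.0}) == pytest.approx(
        np.exp(fit.params["const"] + fit.params["woman"])
    )
    with pytest.raises(KeyError):
        predict_mean(fit, {"nonexistent": 1.0})


def test_predict_from_published_tables():
    """The printed cerebrovascular tables reproduce the published female
    reference-profile predictions."""
    from t2dcost.refdata import (
        INCIDENT_CEREBROVASCULAR,
        PUBLISHED_FEMALE_REFERENCE_PREDICTION,
        RECURRENT_CEREBROVASCULAR,
    )

    inc = predict_from_table(
        INCIDENT_CEREBROVASCULAR["intercept_eur"],
        INCIDENT_CEREBROVASCULAR["ratios"],
        {"woman": 1.0},
    )
    rec = predict_from_table(
        RECURRENT_CEREBROVASCULAR["intercept_eur"],
        RECURRENT_CEREBROVASCULAR["ratios"],
        {"woman": 1.0},
    )
    assert round(inc, 3) == PUBLISHED_FEMALE_REFERENCE_PREDICTION["incident"]
    assert round(rec, 3) == PUBLISHED_FEMALE_REFERENCE_PREDICTION["recurrent"]
    # all-reference profile returns the intercept itself
    assert predict_from_table(100.0, {"woman": 0.85}, {}) == 100.0


# --- average marginal effects ----------------------------------------------

def test_ame_loglink_identity_and_counterfactual():
    beta = {
        "const": float(np.log(6000.0)),
        "age_c75_per10": float(np.log(0.85)),
        "woman": float(np.log(0.8)),
    }
    fit, X, _ = _fit(beta, ("age_c75_per10", "woman"), n=800, seed=19)
    ame = average_marginal_effects(fit).set_index("term")
    mu = np.exp(X.to_numpy() @ fit.params.to_numpy())
    # continuous: AME = beta_j * mean(mu), an exact log-link identity
    assert ame.loc["age_c75_per10", "ame_eur"] == pytest.approx(
        fit.params["age_c75_per10"] * mu.mean(), rel=1e-8
    )
    # binary: brute-force counterfactual means
    X1, X0 = X.copy(), X.copy()
    X1["woman"], X0["woman"] = 1.0, 0.0
    expect = np.mean(
        np.exp(X1.to_numpy() @ fit.params.to_numpy()) - np.exp(X0.to_numpy() @ fit.params.to_numpy())
    )
    assert ame.loc["woman", "ame_eur"] == pytest.approx(expect, rel=1e-10)


def test_ame_zero_for_null_coefficient():
    fit = GammaFit(
        spec=ModelSpec("eye", "incident", covariates=("woman",)),
        params=pd.Series({"const": np.log(1000.0), "woman": 0.0}),
        cov_model=pd.DataFrame(np.eye(2) * 1e-4, index=["const", "woman"], columns=["const", "woman"]),
        cov_sandwich=pd.DataFrame(np.eye(2) * 1e-4, index=["const", "woman"], columns=["const", "woman"]),
        dispersion=0.5, shape=2.0, llf=-10.0, ll_null=-11.0, n_obs=10, n_clusters=10, converged=True,
        X=pd.DataFrame({"const": np.ones(10), "woman": np.r_[np.zeros(5), np.ones(5)]}),
    )
    ame = average_marginal_effects(fit).set_index("term")
    assert ame.loc["woman", "ame_eur"] == 0.0
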