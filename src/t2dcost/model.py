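"""Gamma log-link regression of one-year episode costs.

One model is fitted per complication class × incident/recurrent stratum
(12 in all). The response is the episode's first-year hospital cost in
reference-year euros; the gamma family with log link handles the strong
positive skew of cost data and gives multiplicative covariate effects:
``E[y | x] = exp(x'beta)``, so ``exp(beta_j)`` is a cost ratio against the
reference profile (75-year-old newly diagnosed man, no comorbidities,
alive through the episode year).

Inference uses a cluster-robust sandwich covariance with patients as
clusters — repeated episodes of the same type on one patient are
correlated — computed here from the gamma-log estimating equations
(bread = inverse expected information, meat = within-cluster score outer
products, CR1 small-sample factor). With singleton clusters it reduces to
the HC1 heteroskedasticity-robust estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .registry import INCIDENT_COVARIATES, RECURRENT_COVARIATES

logger = logging.getLogger(__name__)

RESPONSE = "year1_eur"


@dataclass(frozen=True)
class ModelSpec:
    """One stratum's model: covariate list and clustering variable."""

    complication_class: str
    episode_type: str  # "incident" | "recurrent"
    covariates: tuple[str, ...] = ()
    cluster: str = "patient_id"

    def __post_init__(self) -> None:
        if self.episode_type not in ("incident", "recurrent"):
            raise ValueError(f"episode_type must be incident|recurrent, got {self.episode_type!r}")
        if not self.covariates:
            default = INCIDENT_COVARIATES if self.episode_type == "incident" else RECURRENT_COVARIATES
            object.__setattr__(self, "covariates", tuple(default))
        if self.episode_type == "incident":
            banned = {"n_earlier_episodes", "high_prior_cost"} & set(self.covariates)
            if banned:
                raise ValueError(f"incident spec cannot include recurrence covariates {sorted(banned)}")

    @property
    def key(self) -> str:
        return f"{self.complication_class}:{self.episode_type}"


@dataclass
class GammaFit:
    """A fitted gamma log-link cost model with both covariances."""

    spec: ModelSpec
    params: pd.Series               # log-scale coefficients, "const" first
    cov_model: pd.DataFrame         # model-based covariance
    cov_sandwich: pd.DataFrame      # cluster-robust covariance
    dispersion: float               # deviance-based dispersion estimate
    shape: float                    # gamma shape = 1 / dispersion
    llf: float
    ll_null: float
    n_obs: int
    n_clusters: int
    converged: bool
    n_dropped_zero_cost: int = 0
    dropped_covariates: tuple[str, ...] = ()
    X: pd.DataFrame | None = None   # design used for the fit (for AME/simulation)

    @property
    def terms(self) -> list[str]:
        return list(self.params.index)


def attach_covariates(episodes: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """Add the demographic/outcome covariate columns to an episode table.

    ``woman`` (0/1), ``age_c75_per10`` ((age at index − 75)/10),
    ``t2d_duration_per5`` (years since T2D diagnosis / 5, floored at 0) and
    ``died_within_1y`` (death strictly inside the episode year).
    """
    pat = patients.set_index("patient_id")
    out = episodes.copy()
    sex = out["patient_id"].map(pat["sex"])
    birth = pd.to_datetime(out["patient_id"].map(pat["birth_date"]))
    t2d = pd.to_datetime(out["patient_id"].map(pat["t2d_diagnosis_date"]))
    death = pd.to_datetime(out["patient_id"].map(pat["death_date"]))
    idx = pd.to_datetime(out["index_date"])
    age = (idx - birth).dt.days / 365.25
    dur = ((idx - t2d).dt.days / 365.25).clip(lower=0.0)
    out["woman"] = (sex == "female").astype(float)
    out["age_c75_per10"] = (age - 75.0) / 10.0
    out["t2d_duration_per5"] = dur / 5.0
    out["died_within_1y"] = (
        death.notna() & (death < idx + pd.Timedelta(days=365))
    ).astype(float)
    return out


def build_design(
    data: pd.DataFrame, spec: ModelSpec, response: str = RESPONSE
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, dict]:
    """Assemble (X, y, clusters) for one model stratum.

    The intercept column comes first; zero-cost rows are excluded (the gamma
    support is positive) with a logged count, and zero-variance covariates
    are dropped with a warning naming them (a covariate never observed in a
    stratum is not estimable — reported as NA downstream).
    """
    missing = [c for c in spec.covariates if c not in data.columns]
    if missing:
        raise KeyError(f"covariate column(s) missing from episode data: {missing}")
    y_all = data[response].to_numpy(dtype=float)
    keep = y_all > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d zero-cost episode(s) before fitting", spec.key, n_dropped)
    sub = data.loc[keep]
    X = pd.DataFrame({"const": np.ones(len(sub))}, index=sub.index)
    dropped = []
    for c in spec.covariates:
        col = sub[c].to_numpy(dtype=float)
        if len(col) and np.ptp(col) == 0.0:
            dropped.append(c)
            continue
        X[c] = col
    if dropped:
        logger.warning("%s: dropped zero-variance covariate(s): %s", spec.key, dropped)
    y = sub[response].to_numpy(dtype=float)
    clusters = sub[spec.cluster].to_numpy() if spec.cluster in sub.columns else np.arange(len(sub))
    info = {"n_dropped_zero_cost": n_dropped, "dropped_covariates": tuple(dropped)}
    return X, y, clusters, info


def cluster_sandwich(
    X: np.ndarray, y: np.ndarray, mu: np.ndarray, clusters: np.ndarray
) -> np.ndarray:
    """Cluster-robust covariance of a gamma log-link fit.

    Built from the dispersion-free estimating equations
    ``sum_i x_i (y_i - mu_i)/mu_i = 0``: bread is the inverse expected
    information ``(X'X)^{-1}``, meat the sum of within-cluster score outer
    products, scaled by the CR1 factor ``G/(G-1) * (n-1)/(n-p)``. With every
    cluster a singleton this is exactly the HC1 estimator.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    resid = (np.asarray(y, dtype=float) - mu) / mu
    scores = X * resid[:, None]
    groups = pd.factorize(np.asarray(clusters))[0]
    n_groups = groups.max() + 1 if n else 0
    if n_groups < p:
        logger.warning(
            "fewer clusters (%d) than coefficients (%d); sandwich covariance may be deficient",
            n_groups, p,
        )
    meat = np.zeros((p, p))
    for g in range(n_groups):
        u = scores[groups == g].sum(axis=0)
        meat += np.outer(u, u)
    bread = np.linalg.inv(X.T @ X)
    if n_groups > 1 and n > p:
        c = (n_groups / (n_groups - 1.0)) * ((n - 1.0) / (n - p))
    else:
        c = 1.0
    return c * bread @ meat @ bread


def fit_gamma_glm(
    X: pd.DataFrame,
    y: np.ndarray,
    clusters: np.ndarray | None = None,
    spec: ModelSpec | None = None,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> GammaFit:
    """Fit one gamma log-link model and both covariance estimates.

    Raises on non-convergence or a rank-deficient design (naming the
    collinear columns). The null (intercept-only) model is fitted on the
    same observations for the McFadden pseudo-R².
    """
    Xv = np.asarray(X, dtype=float)
    if np.any(y <= 0):
        raise ValueError("response must be strictly positive for the gamma family")
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # identify offending columns by greedy scan
        bad = []
        cols: list[int] = []
        for j in range(Xv.shape[1]):
            trial = cols + [j]
            if np.linalg.matrix_rank(Xv[:, trial]) < len(trial):
                bad.append(X.columns[j])
            else:
                cols.append(j)
        raise ValueError(f"design is rank deficient; collinear column(s): {bad}")
    family = sm.families.Gamma(link=sm.families.links.Log())
    res = sm.GLM(y, Xv, family=family).fit(maxiter=maxiter, tol=tol)
    if not res.converged:
        raise RuntimeError(
            f"gamma GLM did not converge in {maxiter} iterations "
            f"(deviance trace: {getattr(res, 'fit_history', {}).get('deviance', 'n/a')})"
        )
    null = sm.GLM(y, np.ones((len(y), 1)), family=family).fit()
    params = pd.Series(res.params, index=list(X.columns))
    mu = np.exp(Xv @ params.to_numpy())
    if clusters is None:
        clusters = np.arange(len(y))
    dispersion = float(res.deviance / res.df_resid) if res.df_resid > 0 else float("nan")
    cov_sand = cluster_sandwich(Xv, y, mu, np.asarray(clusters))
    cols = list(X.columns)
    return GammaFit(
        spec=spec or ModelSpec("unspecified", "incident", covariates=tuple(c for c in cols if c != "const")),
        params=params,
        cov_model=pd.DataFrame(res.cov_params(), index=cols, columns=cols),
        cov_sandwich=pd.DataFrame(cov_sand, index=cols, columns=cols),
        dispersion=dispersion,
        shape=1.0 / dispersion if dispersion and dispersion > 0 else float("nan"),
        llf=float(res.llf),
        ll_null=float(null.llf),
        n_obs=int(len(y)),
        n_clusters=int(pd.unique(np.asarray(clusters)).size),
        converged=bool(res.converged),
        X=X.copy(),
    )


def fit_stratum(data: pd.DataFrame, spec: ModelSpec, robust: str = "cluster") -> GammaFit:
    """Build the design for *spec* and fit it.

    ``robust="cluster"`` clusters on patients (used for recurrent models);
    ``robust="hc"`` treats every episode as its own cluster, i.e. plain
    heteroskedasticity-robust SEs (incident models, where each patient
    contributes one first episode per scope).
    """
    X, y, clusters, info = build_design(data, spec)
    if robust == "hc":
        clusters = np.arange(len(y))
    fit = fit_gamma_glm(X, y, clusters, spec=spec)
    fit.n_dropped_zero_cost = info["n_dropped_zero_cost"]
    fit.dropped_covariates = info["dropped_covariates"]
    return fit


def mcfadden_r2(fit: GammaFit) -> float:
    """McFadden pseudo-R²: 1 − llf/ll_null."""
    if fit.ll_null == 0:
        raise ZeroDivisionError("null log-likelihood is zero")
    return 1.0 - fit.llf / fit.ll_null


def _stars(p: float) -> str:
    return "**" if p < 0.01 else ("*" if p < 0.05 else "")


def coefficient_table(fit: GammaFit, covariance: str = "sandwich") -> pd.DataFrame:
    """Exponentiated coefficient table with significance stars.

    The intercept row is ``exp(beta_0)`` in euros — the predicted cost of
    the reference profile; other rows are cost ratios ``exp(beta_j)``.
    P-values are two-sided normal-tail tests on the log scale using the
    requested covariance's SEs (** p<0.01, * p<0.05).
    """
    cov = fit.cov_sandwich if covariance == "sandwich" else fit.cov_model
    se = np.sqrt(np.diag(cov.to_numpy()))
    rows = []
    for j, term in enumerate(fit.terms):
        b = fit.params.iloc[j]
        z = b / se[j] if se[j] > 0 else np.inf * np.sign(b) if b else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "term": term,
                "exp_coef": float(np.exp(b)),
                "se_log": float(se[j]),
                "p_value": float(p),
                "stars": _stars(p),
            }
        )
    return pd.DataFrame(rows)


def predict_mean(fit: GammaFit, profile: dict[str, float]) -> float:
    """Predicted mean one-year cost ``exp(x'beta)`` for a covariate profile.

    Covariates absent from *profile* sit at their reference value 0; a key
    that is not a model term raises.
    """
    unknown = set(profile) - set(fit.terms)
    if unknown:
        raise KeyError(f"unknown covariate(s) in profile: {sorted(unknown)}")
    eta = fit.params["const"] + sum(
        fit.params[k] * v for k, v in profile.items() if k != "const"
    )
    return float(np.exp(eta))


def predict_from_table(intercept_eur: float, ratios: dict[str, float], profile: dict[str, float]) -> float:
    """Predicted cost from a published exponentiated coefficient table.

    ``intercept_eur × prod_j ratio_j ** x_j`` — the arithmetic a reader does
    with a printed table (e.g. the female reference profile multiplies the
    intercept by the sex ratio alone).
    """
    unknown = set(profile) - set(ratios)
    if unknown:
        raise KeyError(f"profile covariate(s) not in table: {sorted(unknown)}")
    value = float(intercept_eur)
    for k, x in profile.items():
        value *= float(ratios[k]) ** x
    return value


def average_marginal_effects(
    fit: GammaFit, X: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Average marginal effects on the euro scale.

    For a continuous covariate the AME is the sample mean of
    ``beta_j * exp(x_i'beta)`` (the derivative of the log-link mean); for a
    binary covariate it is the mean counterfactual difference
    ``exp(x'beta | x_j=1) − exp(x'beta | x_j=0)``. Binary covariates are
    detected as columns whose observed values all lie in {0, 1}.
    """
    X = X if X is not None else fit.X
    if X is None:
        raise ValueError("a design matrix is required for AMEs")
    Xv = X[fit.terms].to_numpy(dtype=float)
    beta = fit.params.to_numpy()
    mu = np.exp(Xv @ beta)
    rows = []
    for j, term in enumerate(fit.terms):
        if term == "const":
            continue
        col = Xv[:, j]
        binary = np.all(np.isin(col, (0.0, 1.0)))
        if binary:
            X1, X0 = Xv.copy(), Xv.copy()
            X1[:, j], X0[:, j] = 1.0, 0.0
            ame = float(np.mean(np.exp(X1 @ beta) - np.exp(X0 @ beta)))
        else:
            ame = float(beta[j] * mu.mean())
        rows.append({"term": term, "ame_eur": ame, "binary": binary})
    return pd.DataFrame(rows)
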