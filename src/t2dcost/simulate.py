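"""Predictive simulation of one-year cost distributions.

Given a fitted gamma cost model, coefficient vectors are drawn from a
multivariate normal centered at the estimates via a Cholesky factor of the
chosen covariance (model-based or cluster-robust sandwich); each draw yields
a predicted mean cost ``exp(x'beta_draw)`` for the requested covariate
profile, and optionally a gamma outcome draw at the fitted shape on top of
it. The resulting distribution summarises parameter (and, if requested,
outcome) uncertainty for a population with the chosen characteristics —
the computational core behind interactive what-if costing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import GammaFit, ModelSpec, fit_gamma_glm, predict_mean

logger = logging.getLogger(__name__)

DEFAULT_DRAWS = 10_000
CHOLESKY_JITTER = 1e-10


@dataclass(frozen=True)
class PredictionRequest:
    """What to simulate: model stratum, profile, draws, covariance choice."""

    model_key: str                      # "<class>:<incident|recurrent>"
    profile: dict[str, float] = field(default_factory=dict)
    n_draws: int = DEFAULT_DRAWS
    rng_seed: int = 0
    include_outcome_noise: bool = False
    covariance: str = "sandwich"        # "model" | "sandwich"

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.covariance not in ("model", "sandwich"):
            raise ValueError(f"covariance must be model|sandwich, got {self.covariance!r}")


@dataclass(frozen=True)
class CostDistributionSummary:
    """Summary of the simulated predicted-cost distribution (euros)."""

    mean: float
    sd: float
    q2_5: float
    q25: float
    median: float
    q75: float
    q97_5: float
    n_draws: int
    seed: int

    def as_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean, "sd": self.sd, "q2.5": self.q2_5, "q25": self.q25,
            "median": self.median, "q75": self.q75, "q97.5": self.q97_5,
            "n_draws": self.n_draws, "seed": self.seed,
        }


def draw_coefficients(
    beta: np.ndarray, cov: np.ndarray, n_draws: int, seed: int
) -> np.ndarray:
    """Draw coefficient vectors ``beta + L z`` with ``L L' = cov``.

    A numerically semi-definite covariance gets a tiny diagonal jitter
    (logged); if the Cholesky factorization still fails the covariance is
    not usable and an error is raised.
    """
    beta = np.asarray(beta, dtype=float)
    cov = np.asarray(cov, dtype=float)
    p = beta.size
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    if np.allclose(cov, 0.0):
        return np.tile(beta, (n_draws, 1))
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        logger.info("covariance not positive definite; applying diagonal jitter %g", CHOLESKY_JITTER)
        try:
            L = np.linalg.cholesky(cov + CHOLESKY_JITTER * np.eye(p))
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance is not positive semi-definite (jitter failed)") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, p))
    return beta[None, :] + z @ L.T


def simulate_cost_distribution(request: PredictionRequest, fit: GammaFit) -> CostDistributionSummary:
    """Simulate the predicted one-year cost distribution for a profile.

    With a zero covariance and no outcome noise the distribution is
    degenerate at ``predict_mean(fit, profile)``.
    """
    unknown = set(request.profile) - set(fit.terms)
    if unknown:
        raise KeyError(f"profile covariate(s) not in model: {sorted(unknown)}")
    x = np.array(
        [1.0 if t == "const" else float(request.profile.get(t, 0.0)) for t in fit.terms]
    )
    cov = (fit.cov_sandwich if request.covariance == "sandwich" else fit.cov_model).to_numpy()
    draws = draw_coefficients(fit.params.to_numpy(), cov, request.n_draws, request.rng_seed)
    pred = np.exp(draws @ x)
    if request.include_outcome_noise:
        rng = np.random.default_rng(request.rng_seed + 1)
        shape = fit.shape
        if not np.isfinite(shape) or shape <= 0:
            raise ValueError("fitted gamma shape unavailable for outcome noise")
        pred = rng.gamma(shape, pred / shape)
    q = np.quantile(pred, [0.025, 0.25, 0.5, 0.75, 0.975])
    return CostDistributionSummary(
        mean=float(pred.mean()),
        sd=float(pred.std(ddof=1)) if request.n_draws > 1 else 0.0,
        q2_5=float(q[0]), q25=float(q[1]), median=float(q[2]), q75=float(q[3]), q97_5=float(q[4]),
        n_draws=request.n_draws,
        seed=request.rng_seed,
    )


def refit_subset_model(
    data: pd.DataFrame, spec: ModelSpec, covariate_subset: tuple[str, ...] | list[str]
) -> GammaFit:
    """Refit one stratum on a user-selected covariate subset.

    An empty subset yields the intercept-only model (whose fitted mean is
    the stratum's average one-year cost). The returned fit plugs straight
    into :func:`simulate_cost_distribution`.
    """
    unknown = set(covariate_subset) - set(spec.covariates)
    if unknown:
        raise KeyError(f"subset covariate(s) not in spec: {sorted(unknown)}")
    # ModelSpec treats an empty covariate tuple as "use the defaults", so an
    # explicit intercept-only design is built for the empty subset
    from .model import build_design

    if covariate_subset:
        sub_spec = ModelSpec(
            spec.complication_class,
            spec.episode_type,
            covariates=tuple(covariate_subset),
            cluster=spec.cluster,
        )
        X, y, clusters, info = build_design(data, sub_spec)
    else:
        y_all = data["year1_eur"].to_numpy(dtype=float)
        keep = y_all > 0
        X = pd.DataFrame({"const": np.ones(int(keep.sum()))})
        y = y_all[keep]
        clusters = data.loc[keep, spec.cluster].to_numpy()
        info = {"n_dropped_zero_cost": int((~keep).sum()), "dropped_covariates": ()}
    fit = fit_gamma_glm(X, y, clusters, spec=spec)
    fit.n_dropped_zero_cost = info["n_dropped_zero_cost"]
    fit.dropped_covariates = info["dropped_covariates"]
    return fit
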