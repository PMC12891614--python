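"""Binomial response-curve models of bleaching/mortality against heat stress.

The central statistical object is a logistic dose-response model for a
binary survey outcome (moderate/severe bleaching or mortality) as a
function of accumulated heat stress (DHW, degC-weeks), with ocean basin
and bleaching year entering as categorical fixed effects and their
interactions, plus an optional Regional Virtual Station random intercept
absorbing spatial autocorrelation:

    logit P(y_i = 1) = x_i' beta + u_{g(i)},   u_g ~ N(0, sigma_u^2)

Fixed-effects fits use iteratively reweighted least squares; the random
intercept is integrated out with a Laplace approximation (optionally
adaptive Gauss-Hermite quadrature).  Candidate interaction structures are
enumerated and compared by AIC, including the constrained variants that
share one baseline at DHW = 0 (DHW-by-basin/year interactions without the
corresponding main effects).  Model performance is summarized as the
proportion of outcomes correctly predicted at the 0.5 probability cut,
both conditional on the station effects and marginal (fixed effects only).
Spatial autocorrelation of residuals is diagnosed with semivariograms over
geodesic distances.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, logsumexp

from .geodesy import geodesic_km, pairwise_geodesic_km

__all__ = [
    "ModelSpec",
    "DesignInfo",
    "FittedResponseModel",
    "ResponseCurve",
    "VariogramResult",
    "SeparationError",
    "OPTIONAL_TERMS",
    "analysis_table",
    "build_design",
    "design_matrix_for",
    "fit_logistic",
    "fit_logistic_mixed",
    "fit_model",
    "candidate_models",
    "select_by_aic",
    "prediction_accuracy",
    "response_curve",
    "residuals",
    "residual_variogram",
    "geodesic_km",
]

#: Optional fixed-effect terms beyond the always-present intercept and DHW slope.
OPTIONAL_TERMS = (
    "basin",
    "year",
    "basin:year",
    "dhw:basin",
    "dhw:year",
    "dhw:basin:year",
)

_BLEACHING_OUTCOMES = {"moderate_bleach", "severe_bleach"}
_MORTALITY_OUTCOMES = {"moderate_mortality", "severe_mortality"}


class SeparationError(RuntimeError):
    """Raised when a logistic fit diverges (complete/quasi separation)."""

    def __init__(self, message: str, deviance_trace: list[float]):
        super().__init__(message)
        self.deviance_trace = deviance_trace


@dataclass(frozen=True)
class ModelSpec:
    """A candidate fixed-effect structure.

    ``terms`` always contains ``'dhw'``; optional terms obey the hierarchy
    used in the candidate set: ``basin:year`` requires both main effects,
    and the three-way ``dhw:basin:year`` requires ``dhw:basin`` and
    ``dhw:year`` (but *not* the basin/year main effects — the constrained
    variants share a single baseline at DHW = 0).
    """

    outcome: str
    terms: frozenset = frozenset({"dhw"})
    random_intercept: bool = True
    depth_covariate: bool = False

    def __post_init__(self) -> None:
        terms = frozenset(self.terms) | {"dhw"}
        object.__setattr__(self, "terms", terms)
        unknown = terms - {"dhw", *OPTIONAL_TERMS}
        if unknown:
            raise ValueError(f"unknown model terms: {sorted(unknown)}")
        if "basin:year" in terms and not {"basin", "year"} <= terms:
            raise ValueError("basin:year interaction requires both main effects")
        if "dhw:basin:year" in terms and not {"dhw:basin", "dhw:year"} <= terms:
            raise ValueError("dhw:basin:year requires dhw:basin and dhw:year")

    def describe(self) -> str:
        order = ["dhw", *OPTIONAL_TERMS]
        parts = [t for t in order if t in self.terms]
        if self.depth_covariate:
            parts.append("depth")
        return " + ".join(parts)


@dataclass(frozen=True)
class DesignInfo:
    """Coding metadata fixing column order and factor levels of a design."""

    spec: ModelSpec
    basins: tuple[str, ...]  # first level is the reference
    years: tuple[str, ...]
    names: tuple[str, ...]


def analysis_table(matched: pd.DataFrame, outcome: str, depth_required: bool = False) -> pd.DataFrame:
    """Modelling table for one outcome from the matched-observation frame.

    Picks the exposure column the matching rules dictate (contemporary/max
    DHW for bleaching, yearly max for mortality), drops unmatched rows and
    rows missing the outcome, and for mortality drops surveys recorded
    before the heat-stress peak.
    """
    df = matched[matched["matched"]].copy() if "matched" in matched else matched.copy()
    if outcome in _MORTALITY_OUTCOMES:
        df = df[df["mortality_excluded"] == False]  # noqa: E712  (pd.NA-safe)
        df["dhw"] = df["mortality_dhw"]
    else:
        df["dhw"] = df["dhw_used"]
    df = df[df[outcome].notna() & df["dhw"].notna()]
    if depth_required:
        df = df[df["depth_m"].notna()]
    df["y"] = df[outcome].astype(bool).astype(int)
    return df.reset_index(drop=True)


def _columns(
    dhw: np.ndarray,
    basin: np.ndarray,
    year: np.ndarray,
    info: DesignInfo,
    depth: np.ndarray | None = None,
) -> np.ndarray:
    spec = info.spec
    for b in np.unique(basin):
        if b not in info.basins:
            raise ValueError(f"unknown basin level {b!r}")
    for yv in np.unique(year):
        if yv not in info.years:
            raise ValueError(f"unknown bleaching-year level {yv!r}")
    n = len(dhw)
    cols = [np.ones(n), np.asarray(dhw, dtype=float)]
    b_dum = {b: (basin == b).astype(float) for b in info.basins[1:]}
    y_dum = {y: (year == y).astype(float) for y in info.years[1:]}
    if "basin" in spec.terms:
        cols.extend(b_dum.values())
    if "year" in spec.terms:
        cols.extend(y_dum.values())
    if "basin:year" in spec.terms:
        for b in info.basins[1:]:
            for y in info.years[1:]:
                cols.append(b_dum[b] * y_dum[y])
    if "dhw:basin" in spec.terms:
        cols.extend(dhw * d for d in b_dum.values())
    if "dhw:year" in spec.terms:
        cols.extend(dhw * d for d in y_dum.values())
    if "dhw:basin:year" in spec.terms:
        for b in info.basins[1:]:
            for y in info.years[1:]:
                cols.append(dhw * b_dum[b] * y_dum[y])
    if spec.depth_covariate:
        if depth is None:
            raise ValueError("spec includes depth but no depth values supplied")
        cols.append(np.asarray(depth, dtype=float))
    return np.column_stack(cols)


def _column_names(info_basins, info_years, spec: ModelSpec) -> tuple[str, ...]:
    names = ["(Intercept)", "dhw"]
    if "basin" in spec.terms:
        names += [f"basin[{b}]" for b in info_basins[1:]]
    if "year" in spec.terms:
        names += [f"year[{y}]" for y in info_years[1:]]
    if "basin:year" in spec.terms:
        names += [
            f"basin[{b}]:year[{y}]" for b in info_basins[1:] for y in info_years[1:]
        ]
    if "dhw:basin" in spec.terms:
        names += [f"dhw:basin[{b}]" for b in info_basins[1:]]
    if "dhw:year" in spec.terms:
        names += [f"dhw:year[{y}]" for y in info_years[1:]]
    if "dhw:basin:year" in spec.terms:
        names += [
            f"dhw:basin[{b}]:year[{y}]" for b in info_basins[1:] for y in info_years[1:]
        ]
    if spec.depth_covariate:
        names.append("depth_m")
    return tuple(names)


def build_design(
    observations: pd.DataFrame,
    spec: ModelSpec,
    basin_levels: Sequence[str] | None = None,
    year_levels: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, DesignInfo]:
    """Design matrix, response vector and group index for a model spec.

    Basin and year use treatment (reference-level) coding with reference
    levels AP and the earliest bleaching year.  Returns
    ``(X, y, groups, info)`` where ``groups`` is the station id per row.
    """
    df = observations
    if df["y"].isna().any() or df["dhw"].isna().any():
        raise ValueError("observations contain missing outcome or DHW")
    basins = tuple(basin_levels) if basin_levels else _levels(df["basin"], prefer_first="AP")
    years = tuple(year_levels) if year_levels else tuple(sorted(df["bleaching_year"].unique()))
    info = DesignInfo(
        spec=spec, basins=basins, years=years, names=_column_names(basins, years, spec)
    )
    X = _columns(
        df["dhw"].to_numpy(float),
        df["basin"].to_numpy(),
        df["bleaching_year"].to_numpy(),
        info,
        depth=df["depth_m"].to_numpy(float) if spec.depth_covariate else None,
    )
    y = df["y"].to_numpy(int)
    groups = df["station_id"].to_numpy() if "station_id" in df else np.zeros(len(df))
    return X, y, groups, info


def _levels(series: pd.Series, prefer_first: str) -> tuple[str, ...]:
    levels = sorted(series.unique())
    if prefer_first in levels:
        levels.remove(prefer_first)
        levels.insert(0, prefer_first)
    return tuple(levels)


def design_matrix_for(
    info: DesignInfo,
    dhw,
    basin,
    year,
    depth=None,
) -> np.ndarray:
    """Design rows for new data under an existing coding (for prediction)."""
    dhw = np.atleast_1d(np.asarray(dhw, dtype=float))
    basin = np.broadcast_to(np.atleast_1d(np.asarray(basin, dtype=object)), dhw.shape)
    year = np.broadcast_to(np.atleast_1d(np.asarray(year, dtype=object)), dhw.shape)
    if depth is not None:
        depth = np.broadcast_to(np.atleast_1d(np.asarray(depth, dtype=float)), dhw.shape)
    return _columns(dhw, basin, year, info, depth=depth)


@dataclass
class FittedResponseModel:
    """A fitted (possibly mixed) binomial logit response model."""

    spec: ModelSpec
    info: DesignInfo
    beta: np.ndarray
    vcov: np.ndarray
    sigma_u: float
    loglik: float
    aic: float
    n_obs: int
    converged: bool
    deviance_trace: list[float] = field(default_factory=list)
    group_levels: tuple = ()
    group_effects: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dhw_domain: dict = field(default_factory=dict)
    accuracy_conditional: float | None = None
    accuracy_marginal: float | None = None

    @property
    def names(self) -> tuple[str, ...]:
        return self.info.names

    @property
    def k_parameters(self) -> int:
        return len(self.beta) + (1 if self.spec.random_intercept else 0)

    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.vcov))
        return pd.DataFrame(
            {"coef": self.beta, "se": se}, index=list(self.names)
        )

    def station_effect(self, station_id) -> float:
        """Empirical-Bayes intercept for a station; 0 for unseen stations."""
        try:
            idx = self.group_levels.index(station_id)
        except ValueError:
            return 0.0
        return float(self.group_effects[idx])

    def predict(self, dhw, basin, year, depth=None, station_id=None) -> np.ndarray:
        X = design_matrix_for(self.info, dhw, basin, year, depth=depth)
        eta = X @ self.beta
        if station_id is not None:
            u = np.array(
                [self.station_effect(s) for s in np.atleast_1d(np.asarray(station_id, dtype=object))]
            )
            eta = eta + u
        return expit(eta)

    def to_dict(self) -> dict:
        return {
            "outcome": self.spec.outcome,
            "terms": sorted(self.spec.terms),
            "random_intercept": self.spec.random_intercept,
            "depth_covariate": self.spec.depth_covariate,
            "basins": list(self.info.basins),
            "years": list(self.info.years),
            "names": list(self.info.names),
            "beta": self.beta.tolist(),
            "vcov": self.vcov.tolist(),
            "sigma_u": self.sigma_u,
            "loglik": self.loglik,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "group_levels": list(self.group_levels),
            "group_effects": self.group_effects.tolist(),
            "dhw_domain": {f"{b}|{y}": list(v) for (b, y), v in self.dhw_domain.items()},
            "accuracy_conditional": self.accuracy_conditional,
            "accuracy_marginal": self.accuracy_marginal,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedResponseModel":
        spec = ModelSpec(
            outcome=d["outcome"],
            terms=frozenset(d["terms"]),
            random_intercept=d["random_intercept"],
            depth_covariate=d["depth_covariate"],
        )
        info = DesignInfo(
            spec=spec,
            basins=tuple(d["basins"]),
            years=tuple(d["years"]),
            names=tuple(d["names"]),
        )
        return cls(
            spec=spec,
            info=info,
            beta=np.asarray(d["beta"]),
            vcov=np.asarray(d["vcov"]),
            sigma_u=d["sigma_u"],
            loglik=d["loglik"],
            aic=d["aic"],
            n_obs=d["n_obs"],
            converged=d["converged"],
            group_levels=tuple(d["group_levels"]),
            group_effects=np.asarray(d["group_effects"]),
            dhw_domain={
                tuple(k.split("|")): tuple(v) for k, v in d["dhw_domain"].items()
            },
            accuracy_conditional=d["accuracy_conditional"],
            accuracy_marginal=d["accuracy_marginal"],
        )


def _bernoulli_deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    info: DesignInfo,
    max_iter: int = 100,
    tol: float = 1e-10,
    ridge: float = 0.0,
) -> FittedResponseModel:
    """Maximum-likelihood logit fit by IRLS (fixed effects only).

    The deviance decreases monotonically (step-halving guards the rare
    non-monotone IRLS step).  Diverging coefficients (separation) raise
    :class:`SeparationError` carrying the deviance trace; passing
    ``ridge > 0`` instead returns a ridge-stabilized, non-ML fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    dev = _bernoulli_deviance(y, np.full(n, y.mean() if 0 < y.mean() < 1 else 0.5))
    trace = [dev]
    penalty = ridge * np.eye(p)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        prob = expit(eta)
        w = np.clip(prob * (1 - prob), 1e-10, None)
        z = eta + (y - prob) / w
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X + penalty, XtW @ z)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular design: {exc}", trace) from exc
        # step-halving to keep the deviance monotone
        step = beta_new - beta
        for _half in range(30):
            cand = beta + step
            dev_new = _bernoulli_deviance(y, expit(X @ cand)) + ridge * cand @ cand
            if dev_new <= trace[-1] + 1e-12:
                break
            step /= 2.0
        beta = beta + step
        trace.append(_bernoulli_deviance(y, expit(X @ beta)) + ridge * beta @ beta)
        if np.max(np.abs(beta)) > 50 and ridge == 0.0:
            raise SeparationError(
                "coefficients diverging; data may be separated", trace
            )
        if abs(trace[-2] - trace[-1]) < tol * (abs(trace[-2]) + 1):
            converged = True
            break
    if ridge == 0.0 and trace[-1] < 1e-4:
        # deviance at (numerically) zero: every outcome fitted exactly,
        # the ML estimate lies at infinity
        raise SeparationError("perfect separation: deviance converged to 0", trace)
    if not converged and ridge == 0.0:
        raise SeparationError("IRLS failed to converge", trace)
    prob = expit(X @ beta)
    w = np.clip(prob * (1 - prob), 1e-10, None)
    vcov = np.linalg.inv((X.T * w) @ X + penalty)
    loglik = -_bernoulli_deviance(y, prob) / 2.0
    return FittedResponseModel(
        spec=info.spec,
        info=info,
        beta=beta,
        vcov=vcov,
        sigma_u=0.0,
        loglik=loglik,
        aic=-2 * loglik + 2 * p,
        n_obs=n,
        converged=converged,
        deviance_trace=trace,
    )


def _inner_modes(
    eta0: np.ndarray,
    y: np.ndarray,
    codes: np.ndarray,
    n_groups: int,
    sigma: float,
    u0: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior modes of the group intercepts given (beta, sigma).

    Vectorized Newton iterations across all groups at once; returns the
    modes and the per-group negative Hessians h_j = sum w_i + 1/sigma^2.
    """
    u = np.where(np.isfinite(u0) & (np.abs(u0) < 50), u0, 0.0)
    inv_var = 1.0 / sigma**2

    def group_objective(uu: np.ndarray) -> np.ndarray:
        eta = eta0 + uu[codes]
        ll = y * eta - np.logaddexp(0.0, eta)
        return np.bincount(codes, weights=ll, minlength=n_groups) - uu**2 * inv_var / 2

    obj = group_objective(u)
    for _ in range(max_iter):
        eta = eta0 + u[codes]
        prob = expit(eta)
        grad = np.bincount(codes, weights=y - prob, minlength=n_groups) - u * inv_var
        if np.max(np.abs(grad)) < tol:
            break
        hess = (
            np.bincount(codes, weights=prob * (1 - prob), minlength=n_groups) + inv_var
        )
        step = grad / hess
        # per-group step halving: Newton can overshoot for the logistic
        for _half in range(30):
            obj_new = group_objective(u + step)
            worse = obj_new < obj - 1e-13
            if not worse.any():
                break
            step = np.where(worse, step / 2.0, step)
        u = u + step
        obj = group_objective(u)
    prob = expit(eta0 + u[codes])
    hess = np.bincount(codes, weights=prob * (1 - prob), minlength=n_groups) + inv_var
    return u, hess


def _marginal_loglik(
    beta: np.ndarray,
    log_sigma: float,
    X: np.ndarray,
    y: np.ndarray,
    codes: np.ndarray,
    n_groups: int,
    u_cache: np.ndarray,
    agq_points: int = 1,
) -> tuple[float, np.ndarray]:
    sigma = float(np.exp(log_sigma))
    eta0 = X @ beta
    u, hess = _inner_modes(eta0, y, codes, n_groups, sigma, u_cache)
    eta = eta0 + u[codes]
    # log f(y | u*) per group
    ll_obs = y * eta - np.logaddexp(0.0, eta)
    ll_group = np.bincount(codes, weights=ll_obs, minlength=n_groups)
    if agq_points <= 1:
        ll = ll_group - u**2 / (2 * sigma**2) - np.log(sigma) - 0.5 * np.log(hess)
        return float(ll.sum()), u
    # adaptive Gauss-Hermite around the mode with scale 1/sqrt(h_j)
    nodes, weights = hermgauss(agq_points)
    scale = np.sqrt(2.0 / hess)  # (G,)
    log_terms = np.empty((agq_points, n_groups))
    for k, (t, wq) in enumerate(zip(nodes, weights)):
        u_k = u + scale * t
        eta_k = eta0 + u_k[codes]
        ll_obs_k = y * eta_k - np.logaddexp(0.0, eta_k)
        ll_g = np.bincount(codes, weights=ll_obs_k, minlength=n_groups)
        log_phi = -(u_k**2) / (2 * sigma**2) - 0.5 * np.log(2 * np.pi * sigma**2)
        log_terms[k] = np.log(wq) + t**2 + ll_g + log_phi + np.log(scale)
    ll = logsumexp(log_terms, axis=0)
    return float(ll.sum()), u


def fit_logistic_mixed(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    info: DesignInfo,
    agq_points: int = 1,
    start_beta: np.ndarray | None = None,
    sigma_bounds: tuple[float, float] = (1e-4, 25.0),
) -> FittedResponseModel:
    """Random-intercept logistic fit by Laplace (``agq_points=1``) or AGQ.

    The marginal likelihood integrates the station intercepts out of the
    joint binomial likelihood; optimization is over (beta, log sigma_u).
    A sigma_u estimate at the lower boundary is reported as 0 (not an
    error), in which case the fit coincides with the fixed-effects model.
    Returns empirical-Bayes station effects alongside the fixed effects.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    levels, codes = np.unique(np.asarray(groups), return_inverse=True)
    n_groups = len(levels)
    if n_groups < 2:
        raise ValueError("mixed model requires at least 2 groups")
    n, p = X.shape

    if start_beta is None:
        try:
            start_beta = fit_logistic(X, y.astype(int), info).beta
        except SeparationError:
            start_beta = np.zeros(p)
    u_cache = np.zeros(n_groups)

    def nll(theta: np.ndarray) -> float:
        ll, u = _marginal_loglik(
            theta[:p], theta[p], X, y, codes, n_groups, u_cache, agq_points
        )
        u_cache[:] = u  # warm start the inner Newton
        return -ll

    x0 = np.concatenate([start_beta, [np.log(0.5)]])
    bounds = [(None, None)] * p + [(np.log(sigma_bounds[0]), np.log(sigma_bounds[1]))]
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-8},
    )
    beta = res.x[:p]
    sigma = float(np.exp(res.x[p]))
    loglik, u = _marginal_loglik(beta, res.x[p], X, y, codes, n_groups, u_cache, agq_points)

    at_boundary = sigma <= sigma_bounds[0] * 1.01
    vcov = _beta_vcov(res.x, nll, p, at_boundary)
    if at_boundary:
        sigma = 0.0
        u = np.zeros(n_groups)
    k = p + 1
    return FittedResponseModel(
        spec=info.spec,
        info=info,
        beta=beta,
        vcov=vcov,
        sigma_u=sigma,
        loglik=loglik,
        aic=-2 * loglik + 2 * k,
        n_obs=n,
        converged=bool(res.success),
        group_levels=tuple(levels.tolist()),
        group_effects=u,
    )


def _beta_vcov(theta: np.ndarray, nll, p: int, sigma_fixed: bool) -> np.ndarray:
    """Observed-information covariance of beta by central finite differences."""
    m = p if sigma_fixed else p + 1
    h = 1e-4 * np.maximum(np.abs(theta[:m]), 1.0)
    H = np.zeros((m, m))
    f0 = nll(theta)
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros_like(theta)
            ej = np.zeros_like(theta)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                H[i, i] = (nll(theta + ei) - 2 * f0 + nll(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    nll(theta + ei + ej)
                    - nll(theta + ei - ej)
                    - nll(theta - ei + ej)
                    + nll(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return cov[:p, :p]


def fit_model(
    observations: pd.DataFrame,
    spec: ModelSpec,
    agq_points: int = 1,
    basin_levels: Sequence[str] | None = None,
    year_levels: Sequence[str] | None = None,
) -> FittedResponseModel:
    """Fit one spec on an analysis table (see :func:`analysis_table`)."""
    X, y, groups, info = build_design(observations, spec, basin_levels, year_levels)
    if spec.random_intercept:
        model = fit_logistic_mixed(X, y, groups, info, agq_points=agq_points)
    else:
        model = fit_logistic(X, y, info)
    model.dhw_domain = {
        (b, yv): (float(g["dhw"].min()), float(g["dhw"].max()))
        for (b, yv), g in observations.groupby(["basin", "bleaching_year"])
    }
    model.accuracy_marginal = prediction_accuracy(model, observations, use_random_effects=False)
    if spec.random_intercept:
        model.accuracy_conditional = prediction_accuracy(
            model, observations, use_random_effects=True
        )
    else:
        model.accuracy_conditional = model.accuracy_marginal
    return model


def candidate_models(
    outcome: str, random_intercept: bool = True, depth_covariate: bool = False
) -> list[ModelSpec]:
    """The candidate interaction structures compared by AIC.

    Starting from the full three-way model (DHW x basin x year), all
    combinations of the basin/year main effects and interactions are
    removed, keeping the hierarchy rules of :class:`ModelSpec` and always
    retaining DHW.  This includes the constrained variants that share one
    baseline at DHW = 0 but differ in heat-stress sensitivity (DHW
    interactions without the matching main effects).  25 specs in total:
    5 main-effect structures x 5 DHW-interaction structures.
    """
    main_options = [
        frozenset(),
        frozenset({"basin"}),
        frozenset({"year"}),
        frozenset({"basin", "year"}),
        frozenset({"basin", "year", "basin:year"}),
    ]
    slope_options = [
        frozenset(),
        frozenset({"dhw:basin"}),
        frozenset({"dhw:year"}),
        frozenset({"dhw:basin", "dhw:year"}),
        frozenset({"dhw:basin", "dhw:year", "dhw:basin:year"}),
    ]
    specs = []
    for mains, slopes in itertools.product(main_options, slope_options):
        specs.append(
            ModelSpec(
                outcome=outcome,
                terms=frozenset({"dhw"}) | mains | slopes,
                random_intercept=random_intercept,
                depth_covariate=depth_covariate,
            )
        )
    # deterministic order: by parameter-richness then description
    specs.sort(key=lambda s: (len(s.terms), s.describe()))
    return specs


def select_by_aic(
    candidates: Sequence[ModelSpec],
    observations: pd.DataFrame,
    agq_points: int = 1,
) -> tuple[FittedResponseModel, pd.DataFrame]:
    """Fit all candidates on identical observations and pick the lowest AIC.

    Non-converged candidates are excluded with a warning.  Ties break to
    the model with fewer parameters.  Returns the winning fit and the full
    AIC table.
    """
    rows = []
    fits: list[FittedResponseModel] = []
    for spec in candidates:
        try:
            fit = fit_model(observations, spec, agq_points=agq_points)
        except SeparationError as exc:
            warnings.warn(f"candidate {spec.describe()!r} failed: {exc}")
            continue
        if not fit.converged:
            warnings.warn(f"candidate {spec.describe()!r} did not converge; excluded")
            continue
        fits.append(fit)
        rows.append(
            {
                "terms": spec.describe(),
                "k": fit.k_parameters,
                "loglik": fit.loglik,
                "aic": fit.aic,
            }
        )
    if not fits:
        raise RuntimeError("no candidate model converged")
    table = pd.DataFrame(rows).sort_values(["aic", "k"], kind="mergesort").reset_index(drop=True)
    best_idx = min(range(len(fits)), key=lambda i: (fits[i].aic, fits[i].k_parameters))
    return fits[best_idx], table


def _predicted_probs(
    model: FittedResponseModel, observations: pd.DataFrame, use_random_effects: bool
) -> np.ndarray:
    station = observations["station_id"] if (use_random_effects and "station_id" in observations) else None
    return model.predict(
        observations["dhw"].to_numpy(float),
        observations["basin"].to_numpy(),
        observations["bleaching_year"].to_numpy(),
        depth=observations["depth_m"].to_numpy(float) if model.spec.depth_covariate else None,
        station_id=station,
    )


def prediction_accuracy(
    model: FittedResponseModel,
    observations: pd.DataFrame,
    use_random_effects: bool = True,
) -> float:
    """Proportion of outcomes correctly predicted at the strict p > 0.5 cut.

    ``use_random_effects=True`` gives the conditional accuracy (station
    effects included; unseen stations get 0), ``False`` the marginal
    (fixed-effects-only) accuracy.
    """
    p = _predicted_probs(model, observations, use_random_effects)
    predicted = p > 0.5
    y = observations["y"].to_numpy(int).astype(bool)
    return float(np.mean(predicted == y))


@dataclass
class ResponseCurve:
    """Fitted probability vs DHW for one basin x year cell with 95% CI."""

    basin: str
    bleaching_year: str
    dhw: np.ndarray
    p_mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray


def response_curve(
    model: FittedResponseModel,
    basin: str,
    year: str,
    dhw_grid: np.ndarray,
    trim_to_domain: bool = True,
    z: float = 1.959963984540054,
) -> ResponseCurve:
    """Mean response and 95% CI over a DHW grid for one basin/year.

    The CI is a normal (Wald) interval on the linear predictor,
    x' V x, transformed through the inverse logit, so the endpoints always
    lie inside (0, 1).  Grid points outside the DHW domain observed for
    that basin/year are trimmed (with a warning) unless disabled.
    """
    grid = np.asarray(dhw_grid, dtype=float)
    if trim_to_domain and (basin, year) in model.dhw_domain:
        lo, hi = model.dhw_domain[(basin, year)]
        keep = (grid >= lo) & (grid <= hi)
        if not keep.all():
            warnings.warn(
                f"trimmed {np.sum(~keep)} grid points outside the observed "
                f"DHW domain [{lo:.3g}, {hi:.3g}] for {basin}/{year}"
            )
        grid = grid[keep]
    X = design_matrix_for(model.info, grid, basin, year,
                          depth=np.zeros_like(grid) if model.spec.depth_covariate else None)
    eta = X @ model.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, model.vcov, X), 0.0))
    return ResponseCurve(
        basin=basin,
        bleaching_year=year,
        dhw=grid,
        p_mean=expit(eta),
        ci_lo=expit(eta - z * se),
        ci_hi=expit(eta + z * se),
    )


def residuals(
    model: FittedResponseModel,
    observations: pd.DataFrame,
    kind: str = "response",
    use_random_effects: bool = True,
) -> np.ndarray:
    """Response (y - p) or Pearson ((y - p)/sqrt(p(1-p))) residuals."""
    p = _predicted_probs(model, observations, use_random_effects)
    r = observations["y"].to_numpy(float) - p
    if kind == "pearson":
        r = r / np.sqrt(np.clip(p * (1 - p), 1e-12, None))
    elif kind != "response":
        raise ValueError(f"unknown residual kind {kind!r}")
    return r


@dataclass
class VariogramResult:
    """Binned semivariance of residuals over geodesic distance."""

    bin_edges_km: np.ndarray
    bin_centers_km: np.ndarray
    semivariance: np.ndarray  # NaN for empty bins
    pair_counts: np.ndarray


def residual_variogram(
    resid: np.ndarray,
    lats: np.ndarray,
    lons: np.ndarray,
    bin_edges_km: np.ndarray | None = None,
) -> VariogramResult:
    """Empirical semivariogram: gamma(h) = mean of (r_i - r_j)^2 / 2 per bin.

    Distances are WGS-84 geodesic.  Default bins: 100 km widths out to
    5000 km.  Empty bins yield NaN semivariance, not zero.
    """
    resid = np.asarray(resid, dtype=float)
    if bin_edges_km is None:
        bin_edges_km = np.arange(0.0, 5001.0, 100.0)
    bin_edges_km = np.asarray(bin_edges_km, dtype=float)
    d = pairwise_geodesic_km(lats, lons)
    i, j = np.triu_indices(len(resid), k=1)
    sqdiff = 0.5 * (resid[i] - resid[j]) ** 2
    which = np.digitize(d, bin_edges_km) - 1
    nbin = len(bin_edges_km) - 1
    ok = (which >= 0) & (which < nbin)
    counts = np.bincount(which[ok], minlength=nbin)
    sums = np.bincount(which[ok], weights=sqdiff[ok], minlength=nbin)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return VariogramResult(
        bin_edges_km=bin_edges_km,
        bin_centers_km=0.5 * (bin_edges_km[:-1] + bin_edges_km[1:]),
        semivariance=gamma,
        pair_counts=counts,
    )
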