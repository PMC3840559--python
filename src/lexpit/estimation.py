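"""Constrained maximum pseudo-likelihood estimation of the lexpit model.

Estimates solve

    theta_hat = argmax  l(theta)   subject to  theta in F,

where l is the expansion-weighted Bernoulli log-likelihood

    l(beta, gamma0, gamma) = sum_j sum_i w_ij [ y_ij log R(x_ij, z_ij)
                                              + (1 - y_ij) log(1 - R(x_ij, z_ij)) ]

and the feasible region F requires 0 <= beta'x + expit(gamma0 + gamma'z) <= 1
at every *unique observed* covariate pattern.  With all weights equal to 1
this is the exact cohort likelihood; with expansion weights it is a
pseudo-likelihood whose maximizer estimates the population parameters.

The optimizer is sequential quadratic programming (SLSQP) over the full
parameter vector with one constraint pair per observed pattern, started
from a weighted logistic fit of the multiplicative block (beta = 0, a
point always interior to F).  When no constraint is active at the SLSQP
solution, a damped Newton polish with feasibility backtracking refines
the interior optimum to near machine precision, so that special cases
(pure logistic, pure linear-binomial) agree with their closed-form or
IRLS solutions to tight tolerance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .design import CaseControlDesign, compute_sampling_weights, _validate_binary
from .model import LexpitSpec, ParameterVector, expit

logger = logging.getLogger(__name__)

__all__ = [
    "FeasibleRegion",
    "FitOptions",
    "FitResult",
    "pseudo_log_likelihood",
    "build_feasible_region",
    "fit_lexpit",
]

_RISK_EPS = 1e-12  # clip for logs inside the smooth surrogate objective


@dataclass(frozen=True)
class FeasibleRegion:
    """Deduplicated observed covariate patterns and their risk bounds.

    Each unique observed (x, z) pattern contributes the constraint pair
    ``0 <= R(x, z) <= 1``.
    """

    x_patterns: np.ndarray  # (k, p)
    z_patterns: np.ndarray  # (k, q)
    counts: np.ndarray  # multiplicity of each pattern in the data

    @property
    def n_patterns(self) -> int:
        return self.x_patterns.shape[0]

    def risks(self, theta: np.ndarray) -> np.ndarray:
        p = self.x_patterns.shape[1]
        beta, gamma0, gamma = theta[:p], theta[p], theta[p + 1 :]
        return self.x_patterns @ beta + expit(gamma0 + self.z_patterns @ gamma)


@dataclass(frozen=True)
class FitOptions:
    """Optimizer controls (defaults are standard and rarely need touching)."""

    max_iter: int = 500
    gtol: float = 1e-6  # max |gradient| per unit weight on the inactive set
    constraint_tol: float = 1e-8
    polish: bool = True
    polish_iter: int = 50


@dataclass
class FitResult:
    """A fitted lexpit model."""

    params: ParameterVector
    loglik: float
    converged: bool
    n_iterations: int
    active_constraints: list[int]
    fitted_risks: np.ndarray
    spec: LexpitSpec
    design: CaseControlDesign | None
    feasible_region: FeasibleRegion
    message: str = ""
    covariance: np.ndarray | None = None
    covariance_method: str | None = None
    # observation-level arrays retained for inference and diagnostics
    y: np.ndarray = field(default=None, repr=False)
    X: np.ndarray = field(default=None, repr=False)
    Z: np.ndarray = field(default=None, repr=False)
    weights: np.ndarray = field(default=None, repr=False)
    stratum_labels: np.ndarray = field(default=None, repr=False)

    @property
    def theta(self) -> np.ndarray:
        return self.params.theta

    @property
    def param_names(self) -> list[str]:
        return self.spec.param_names

    def clipped_risks(self) -> np.ndarray:
        """Fitted risks clipped to [0, 1] for reporting."""
        return np.clip(self.fitted_risks, 0.0, 1.0)


# ---------------------------------------------------------------------------
# likelihood machinery


def _unpack(theta: np.ndarray, p: int):
    return theta[:p], theta[p], theta[p + 1 :]


def _risk_parts(theta, X, Z):
    beta, gamma0, gamma = _unpack(theta, X.shape[1])
    eta = gamma0 + Z @ gamma
    pz = expit(eta)
    R = X @ beta + pz
    return R, pz


def _loglik_raw(theta, y, X, Z, w) -> float:
    """Pseudo-log-likelihood with the -inf convention for infeasible risks."""
    R, _ = _risk_parts(theta, X, Z)
    if np.any(R <= 0.0) or np.any(R >= 1.0):
        return -np.inf
    return float(np.sum(w * (y * np.log(R) + (1.0 - y) * np.log1p(-R))))


def _loglik_grad(theta, y, X, Z, w, clip: bool = True):
    """Smooth surrogate (clipped) log-likelihood and its gradient."""
    R, pz = _risk_parts(theta, X, Z)
    if clip:
        R = np.clip(R, _RISK_EPS, 1.0 - _RISK_EPS)
    ll = float(np.sum(w * (y * np.log(R) + (1.0 - y) * np.log1p(-R))))
    u = w * (y / R - (1.0 - y) / (1.0 - R))
    pq = pz * (1.0 - pz)
    upq = u * pq
    grad = np.concatenate([X.T @ u, [upq.sum()], Z.T @ upq])
    return ll, grad


def _neg_hessian(theta, y, X, Z, w) -> np.ndarray:
    """Weighted observed information, -d2 l / d theta d theta'."""
    R, pz = _risk_parts(theta, X, Z)
    R = np.clip(R, _RISK_EPS, 1.0 - _RISK_EPS)
    u = y / R - (1.0 - y) / (1.0 - R)
    a = y / R**2 + (1.0 - y) / (1.0 - R) ** 2
    pq = pz * (1.0 - pz)
    # M = dR/dtheta rows; G = d eta/d(gamma0, gamma) rows
    M = np.hstack([X, pq[:, None], pq[:, None] * Z])
    H = M.T @ (M * (w * a)[:, None])
    # curvature of expit: d2R/deta2 = pq (1 - 2 pz)
    c = w * u * pq * (1.0 - 2.0 * pz)
    G = np.hstack([np.ones((len(y), 1)), Z])
    Hzz = G.T @ (G * c[:, None])
    p = X.shape[1]
    H[p:, p:] -= Hzz
    return H


def _scores(theta, y, X, Z) -> np.ndarray:
    """Per-observation (unweighted) score vectors of the likelihood summand."""
    R, pz = _risk_parts(theta, X, Z)
    R = np.clip(R, _RISK_EPS, 1.0 - _RISK_EPS)
    u = y / R - (1.0 - y) / (1.0 - R)
    pq = pz * (1.0 - pz)
    M = np.hstack([X, pq[:, None], pq[:, None] * Z])
    return M * u[:, None]


def pseudo_log_likelihood(
    params: ParameterVector,
    spec: LexpitSpec,
    data: pd.DataFrame,
    outcome: str = "outcome",
    weight_col: str = "weight",
) -> float:
    """Evaluate the weighted pseudo-log-likelihood at ``params``.

    Returns ``-inf`` when any fitted risk falls outside the open
    interval (0, 1), signalling an infeasible point.
    """
    y = _validate_binary(data[outcome], outcome)
    w = (
        data[weight_col].to_numpy(dtype=float)
        if weight_col in data.columns
        else np.ones(len(data))
    )
    X, Z = spec.design_matrices(data)
    return _loglik_raw(params.theta, y, X, Z, w)


def build_feasible_region(X: np.ndarray, Z: np.ndarray) -> FeasibleRegion:
    """Deduplicate observed (x, z) patterns into a feasible region."""
    if len(X) == 0:
        raise ValueError("cannot build a feasible region from empty data")
    XZ = np.hstack([X, Z])
    patterns, counts = np.unique(XZ, axis=0, return_counts=True)
    p = X.shape[1]
    return FeasibleRegion(
        x_patterns=patterns[:, :p], z_patterns=patterns[:, p:], counts=counts
    )


# ---------------------------------------------------------------------------
# optimization


def _weighted_logistic_start(y, Z, w) -> np.ndarray:
    """Starting values: gamma from a weighted logistic fit, beta = 0."""
    import statsmodels.api as sm

    wbar = float(np.average(y, weights=w))
    wbar = min(max(wbar, 1e-10), 1 - 1e-10)
    g0 = float(np.log(wbar / (1 - wbar)))
    if Z.shape[1] == 0:
        return np.array([g0])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(
                y, np.hstack([np.ones((len(y), 1)), Z]),
                family=sm.families.Binomial(), freq_weights=w,
            ).fit(maxiter=200)
        coef = np.asarray(res.params, dtype=float)
        if np.all(np.isfinite(coef)):
            return coef
    except Exception:  # separation or rank deficiency: fall back to intercept
        pass
    logger.warning("weighted logistic start failed; starting from the intercept")
    return np.concatenate([[g0], np.zeros(Z.shape[1])])


def _check_degenerate(X, Z, spec) -> None:
    for k, name in enumerate(spec.additive):
        if np.ptp(X[:, k]) == 0.0:
            raise ValueError(f"covariate {name!r} is constant across the sample")
    for k, name in enumerate(spec.multiplicative):
        if np.ptp(Z[:, k]) == 0.0:
            raise ValueError(f"covariate {name!r} is constant across the sample")


def _newton_polish(theta, y, X, Z, w, region, options, w_total):
    """Damped Newton refinement of an interior optimum.

    Backtracks until both the observation risks and the pattern risks
    stay strictly inside (0, 1) and the likelihood does not decrease.
    Returns (theta, n_iter, gmax).
    """
    ll, g = _loglik_grad(theta, y, X, Z, w)
    it = 0
    for it in range(1, options.polish_iter + 1):
        gmax = np.max(np.abs(g)) / w_total
        if gmax < 1e-12:
            break
        H = _neg_hessian(theta, y, X, Z, w)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        improved = False
        for _ in range(40):
            cand = theta + t * step
            r_obs, _ = _risk_parts(cand, X, Z)
            r_pat = region.risks(cand)
            if (
                np.all(r_obs > 0.0)
                and np.all(r_obs < 1.0)
                and np.all(r_pat > -options.constraint_tol)
                and np.all(r_pat < 1.0 + options.constraint_tol)
            ):
                ll_new, g_new = _loglik_grad(cand, y, X, Z, w)
                if ll_new >= ll - 1e-12 * max(1.0, abs(ll)):
                    theta, ll, g = cand, ll_new, g_new
                    improved = True
                    break
            t *= 0.5
        if not improved:
            break
    gmax = np.max(np.abs(g)) / w_total
    return theta, it, gmax


def fit_lexpit(
    data: pd.DataFrame,
    spec: LexpitSpec,
    design: CaseControlDesign | None = None,
    outcome: str = "outcome",
    stratum: str = "stratum",
    weight_col: str | None = None,
    options: FitOptions | None = None,
    start: np.ndarray | None = None,
) -> FitResult:
    """Fit the lexpit model by constrained maximum pseudo-likelihood.

    Parameters
    ----------
    data :
        Subject table with the outcome, stratum and covariate columns.
    spec :
        Additive/multiplicative covariate assignment and tau.
    design :
        Sampling design used to derive expansion weights.  May be
        ``None`` for cohort-style data (all weights 1) or when
        ``weight_col`` supplies the weights directly.
    weight_col :
        Explicit weight column; overrides design-derived weights.
    start :
        Optional full starting vector [beta, gamma0, gamma] (used e.g.
        by bootstrap refits); must be feasible.

    Returns
    -------
    FitResult
        Estimates, optimum pseudo-log-likelihood, convergence flag,
        active-constraint list and per-observation fitted risks.  The
        fit is deterministic given data, spec and options.
    """
    options = options or FitOptions()

    if weight_col is not None or design is not None:
        data_w = compute_sampling_weights(
            design, data, outcome=outcome, stratum=stratum, weight_col=weight_col
        )
        w = data_w["weight"].to_numpy(dtype=float)
    else:
        w = np.ones(len(data), dtype=float)

    y = _validate_binary(data[outcome], outcome).astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("the data must contain at least one case and one control")
    X, Z = spec.design_matrices(data)
    _check_degenerate(X, Z, spec)
    region = build_feasible_region(X, Z)
    strata = (
        data[stratum].astype(str).to_numpy() if stratum in data.columns else None
    )
    w_total = float(w.sum())
    p = X.shape[1]

    theta0 = np.asarray(start, dtype=float) if start is not None else np.concatenate(
        [np.zeros(p), _weighted_logistic_start(y, Z, w)]
    )
    if theta0.size != spec.n_params:
        raise ValueError("starting vector length does not match the parameter count")

    ll0 = _loglik_raw(theta0, y, X, Z, w)
    if not np.isfinite(ll0):
        raise ValueError("the starting point is infeasible (a fitted risk outside (0,1))")

    # SLSQP on the normalized objective with one constraint pair per pattern
    def objective(theta):
        ll, g = _loglik_grad(theta, y, X, Z, w)
        return -ll / w_total, -g / w_total

    def cons_fun(theta):
        r = region.risks(theta)
        return np.concatenate([r, 1.0 - r])

    def cons_jac(theta):
        pz = expit(theta[p] + region.z_patterns @ theta[p + 1 :])
        pq = pz * (1.0 - pz)
        J = np.hstack([region.x_patterns, pq[:, None], pq[:, None] * region.z_patterns])
        return np.vstack([J, -J])

    res = minimize(
        objective,
        theta0,
        jac=True,
        method="SLSQP",
        constraints=[{"type": "ineq", "fun": cons_fun, "jac": cons_jac}],
        options={"maxiter": options.max_iter, "ftol": 1e-12},
    )
    theta = res.x
    n_iter = int(res.get("nit", options.max_iter))
    message = str(res.message)

    # a solver step may end marginally infeasible; fall back if it got worse
    if _loglik_raw(theta, y, X, Z, w) == -np.inf and not np.all(
        (region.risks(theta) > -options.constraint_tol)
        & (region.risks(theta) < 1 + options.constraint_tol)
    ):
        logger.warning("SLSQP returned an infeasible point; reverting to the start")
        theta, message = theta0, "optimizer returned infeasible point"

    r_pat = region.risks(theta)
    active = np.flatnonzero(
        (r_pat <= options.constraint_tol) | (r_pat >= 1.0 - options.constraint_tol)
    )

    polished_g = None
    if options.polish and active.size == 0:
        theta, extra, polished_g = _newton_polish(
            theta, y, X, Z, w, region, options, w_total
        )
        n_iter += extra
        r_pat = region.risks(theta)
        active = np.flatnonzero(
            (r_pat <= options.constraint_tol) | (r_pat >= 1.0 - options.constraint_tol)
        )

    feasible = bool(
        np.all(r_pat >= -options.constraint_tol)
        and np.all(r_pat <= 1.0 + options.constraint_tol)
    )
    if polished_g is None:
        _, g = _loglik_grad(theta, y, X, Z, w)
        polished_g = np.max(np.abs(g)) / w_total

    # first-order check: at interior optima demand a small gradient; at the
    # boundary defer to the SQP solver's own KKT-based success flag
    if active.size == 0:
        converged = feasible and polished_g < options.gtol
    else:
        converged = feasible and bool(res.success)
        message += f" [{active.size} active feasibility constraint(s)]"
        logger.warning(
            "%d feasibility constraint(s) active at the optimum; "
            "Wald inference near the boundary is unreliable", active.size,
        )
    if not converged and not message:
        message = "did not satisfy first-order conditions"

    ll_hat = _loglik_raw(theta, y, X, Z, w)
    if not np.isfinite(ll_hat):  # boundary optimum: report the clipped value
        ll_hat, _ = _loglik_grad(theta, y, X, Z, w)
    if ll_hat < ll0 - 1e-8 * max(1.0, abs(ll0)):
        # never return a point worse than the start
        theta, ll_hat = theta0, ll0
        converged = False
        message += " [no improvement over the start]"

    fitted, _ = _risk_parts(theta, X, Z)
    params = ParameterVector.from_theta(theta, p)
    return FitResult(
        params=params,
        loglik=float(ll_hat),
        converged=converged,
        n_iterations=n_iter,
        active_constraints=active.tolist(),
        fitted_risks=fitted,
        spec=spec,
        design=design,
        feasible_region=region,
        message=message.strip(),
        y=y,
        X=X,
        Z=Z,
        weights=w,
        stratum_labels=strata,
    )
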