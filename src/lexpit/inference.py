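"""Design-based variance estimation for fitted lexpit models.

Because the estimating function is a *pseudo*-likelihood, the inverse
information matrix is not a valid variance.  Standard errors instead
come from influence-function linearization, the usual device for
survey-weighted estimators: each observation's influence on theta_hat is

    d_ij = w_ij * H^{-1} s_ij,

with ``s_ij`` the per-observation score of the likelihood summand at the
optimum and ``H`` the weighted observed information.  The covariance of
theta_hat is then the variance of the influence total under the study's
two sources of randomness:

* controls are a within-stratum simple random sample, estimated by the
  with-replacement stratified form
  ``n_j/(n_j-1) * sum_i (d_ij - dbar_j)(d_ij - dbar_j)'``;
* cases are a census of a random (Poisson-like) disease process, so the
  case stratum contributes the uncentered total ``sum_i d_i d_i'``.
  (Centering the case stratum would only capture case-mix variation and
  demonstrably understates the variance of absolute-risk estimates; see
  the methods note.)

A stratified bootstrap with the matching resampling scheme is provided
as an independent cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .estimation import FitResult, _neg_hessian, _scores, fit_lexpit, FitOptions
from .model import ParameterVector

logger = logging.getLogger(__name__)

__all__ = [
    "InfluenceSet",
    "CovarianceEstimate",
    "influence_vectors",
    "linearized_covariance",
    "bootstrap_covariance",
    "wald_intervals",
]


@dataclass(frozen=True)
class InfluenceSet:
    """Per-observation influence vectors for the fitted parameters."""

    vectors: np.ndarray  # (n, d)
    is_case: np.ndarray  # (n,) bool
    stratum_labels: np.ndarray | None
    weights: np.ndarray

    @property
    def n_params(self) -> int:
        return self.vectors.shape[1]


@dataclass(frozen=True)
class CovarianceEstimate:
    """Symmetric PSD parameter covariance with provenance."""

    matrix: np.ndarray
    method: str  # "linearized" | "bootstrap"
    df_note: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance must be a square matrix")
        object.__setattr__(self, "matrix", 0.5 * (m + m.T))

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.matrix), 0.0, None))


def influence_vectors(fit: FitResult, data: pd.DataFrame | None = None) -> InfluenceSet:
    """Influence of each observation on theta_hat.

    ``d_ij = w_ij H^{-1} s_ij``; at an interior optimum the weighted
    score condition makes the influences sum to (numerically) zero.
    """
    if not fit.converged:
        logger.warning("computing influences for a non-converged fit")
    if fit.active_constraints:
        logger.warning(
            "active feasibility constraints at the optimum; the covariance is "
            "reported for the unconstrained parameterization and Wald inference "
            "for boundary parameters is unreliable"
        )
    theta = fit.theta
    H = _neg_hessian(theta, fit.y, fit.X, fit.Z, fit.weights)
    S = _scores(theta, fit.y, fit.X, fit.Z)
    try:
        Hinv_S = np.linalg.solve(H, S.T).T
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "the observed information is singular; consider removing collinear "
            "covariates or simplifying the model"
        ) from err
    D = fit.weights[:, None] * Hinv_S
    return InfluenceSet(
        vectors=D,
        is_case=fit.y.astype(bool),
        stratum_labels=fit.stratum_labels,
        weights=fit.weights,
    )


def _stratum_contribution(D: np.ndarray, center: bool, fpc: float = 1.0) -> np.ndarray:
    n = D.shape[0]
    if center:
        if n < 2:
            raise ValueError("centered contribution needs >= 2 units")
        Dc = D - D.mean(axis=0)
        return fpc * (n / (n - 1)) * (Dc.T @ Dc)
    return fpc * (D.T @ D)


def linearized_covariance(
    influences: InfluenceSet,
    design_based: bool | None = None,
    case_strategy: str = "poisson",
    fpc: bool = False,
    design=None,
) -> CovarianceEstimate:
    """Stratified linearized covariance of the parameter estimates.

    Parameters
    ----------
    influences :
        Output of :func:`influence_vectors`.
    design_based :
        If True, controls are grouped by sampling stratum and the cases
        form their own variance stratum.  If False, all observations
        form a single variance stratum (cohort-style simple random
        sample).  Default: design-based when stratum labels are present
        and any weight differs from 1.
    case_strategy :
        ``"poisson"`` (default) treats the case total as a realization
        of an independent disease process and uses the uncentered sum
        ``sum d d'``; ``"centered"`` treats the cases as a
        fixed-size with-replacement sample (captures case-mix variation
        only, and is also what a fixed-n case bootstrap estimates).
    fpc :
        Apply the finite-population correction ``1 - n_j/N_j`` per
        control stratum (requires ``design``).  Off by default: with
        census-scale strata the sampling fractions are tiny.
    """
    if case_strategy not in ("poisson", "centered"):
        raise ValueError("case_strategy must be 'poisson' or 'centered'")
    D = influences.vectors
    d = D.shape[1]
    if design_based is None:
        design_based = influences.stratum_labels is not None and bool(
            np.any(influences.weights != 1.0)
        )

    V = np.zeros((d, d))
    if not design_based:
        V = _stratum_contribution(D, center=True)
        note = "single variance stratum (simple random sample)"
        return CovarianceEstimate(matrix=V, method="linearized", df_note=note)

    if influences.stratum_labels is None:
        raise ValueError("design-based variance requires stratum labels")

    is_case = influences.is_case
    n_cases = int(is_case.sum())
    if n_cases:
        V += _stratum_contribution(D[is_case], center=(case_strategy == "centered"))

    labels = influences.stratum_labels
    ctrl = ~is_case
    groups: list[tuple[str, np.ndarray]] = []
    for lab in np.unique(labels[ctrl]):
        idx = np.flatnonzero(ctrl & (labels == lab))
        groups.append((str(lab), idx))
    # collapse single-unit control strata with the neighbour by label order
    merged: list[tuple[str, np.ndarray]] = []
    pending: np.ndarray | None = None
    pending_lab = ""
    for lab, idx in groups:
        if pending is not None:
            idx = np.concatenate([pending, idx])
            lab = f"{pending_lab}+{lab}"
            pending = None
        if len(idx) < 2:
            logger.warning("control stratum %r has a single unit; collapsing with neighbour", lab)
            pending, pending_lab = idx, lab
        else:
            merged.append((lab, idx))
    if pending is not None:
        if merged:
            lab, idx = merged[-1]
            merged[-1] = (f"{lab}+{pending_lab}", np.concatenate([idx, pending]))
        else:
            logger.warning("only one control unit in total; its stratum adds no variance")

    fractions = {}
    if fpc:
        if design is None:
            raise ValueError("fpc=True requires the design")
        fractions = {s.label: s.sampling_fraction for s in design.strata}

    for lab, idx in merged:
        f = 1.0
        if fpc:
            f = 1.0 - fractions.get(lab, 0.0)
        V += _stratum_contribution(D[idx], center=True, fpc=f)

    note = (
        f"cases as a self-representing stratum ({case_strategy}); "
        f"{len(merged)} control variance stratum(s)"
        + ("; with finite-population correction" if fpc else "")
    )
    return CovarianceEstimate(matrix=V, method="linearized", df_note=note)


def bootstrap_covariance(
    fit: FitResult,
    n_reps: int = 500,
    seed: int | None = None,
    case_strategy: str = "poisson",
) -> CovarianceEstimate:
    """Stratified bootstrap covariance, mirroring the sampling design.

    Controls are resampled with replacement within each sampling
    stratum (fixed ``n_j``); cases are resampled as a stratum, either
    with Poisson(1) multiplicities (``"poisson"``, matching the default
    linearization) or with a fixed-size multinomial (``"centered"``).
    Each replicate refits the model with multiplicity-scaled weights,
    warm-started at theta_hat.
    """
    if case_strategy not in ("poisson", "centered"):
        raise ValueError("case_strategy must be 'poisson' or 'centered'")
    rng = np.random.default_rng(seed)
    y, X, Z, w = fit.y, fit.X, fit.Z, fit.weights
    labels = fit.stratum_labels
    is_case = y.astype(bool)
    idx_case = np.flatnonzero(is_case)
    ctrl_groups = []
    if labels is None:
        ctrl_groups.append(np.flatnonzero(~is_case))
    else:
        for lab in np.unique(labels[~is_case]):
            ctrl_groups.append(np.flatnonzero(~is_case & (labels == lab)))

    df = pd.DataFrame({"outcome": y.astype(int)})
    thetas = []
    n_fail = 0
    options = FitOptions(polish=True, polish_iter=25)
    for _ in range(n_reps):
        counts = np.zeros(len(y))
        if idx_case.size:
            if case_strategy == "poisson":
                counts[idx_case] = rng.poisson(1.0, idx_case.size)
            else:
                pick = rng.integers(0, idx_case.size, idx_case.size)
                np.add.at(counts, idx_case[pick], 1.0)
        for idx in ctrl_groups:
            pick = rng.integers(0, idx.size, idx.size)
            np.add.at(counts, idx[pick], 1.0)
        wb = w * counts
        keep = wb > 0
        if not (np.any(y[keep] == 1) and np.any(y[keep] == 0)):
            n_fail += 1
            continue
        try:
            res = _refit(fit, keep, wb[keep], options)
        except Exception:
            n_fail += 1
            continue
        if res is None:
            n_fail += 1
            continue
        thetas.append(res)
    if n_fail:
        logger.warning("%d of %d bootstrap replicates failed and were dropped", n_fail, n_reps)
    if len(thetas) < 2:
        raise RuntimeError("too few successful bootstrap replicates")
    T = np.asarray(thetas)
    V = np.cov(T, rowvar=False, ddof=1)
    V = np.atleast_2d(V)
    return CovarianceEstimate(
        matrix=V,
        method="bootstrap",
        df_note=f"{len(thetas)} replicates, case strategy {case_strategy!r}",
    )


def _refit(fit: FitResult, keep: np.ndarray, wb: np.ndarray, options: FitOptions):
    """Refit on a bootstrap replicate via the low-level arrays."""
    data = pd.DataFrame({"outcome": fit.y[keep].astype(int)})
    for k, name in enumerate(fit.spec.additive):
        data[name] = fit.X[keep, k]
    for k, name in enumerate(fit.spec.multiplicative):
        data[name] = fit.Z[keep, k]
    data["weight"] = wb
    if fit.stratum_labels is not None:
        data["stratum"] = fit.stratum_labels[keep]
    # centers/scales were already applied to the stored arrays
    spec = type(fit.spec)(
        additive=fit.spec.additive,
        multiplicative=fit.spec.multiplicative,
        tau=fit.spec.tau,
        allow_dual=fit.spec.allow_dual,
    )
    try:
        res = fit_lexpit(
            data, spec, design=None, weight_col="weight",
            options=options, start=fit.theta,
        )
    except ValueError:
        return None
    return res.theta if res.converged or res.active_constraints else None


def wald_intervals(
    fit: FitResult,
    covariance: CovarianceEstimate | np.ndarray,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-parameter Wald confidence intervals.

    Returns the raw-scale intervals for every parameter plus the
    residual-odds-ratio transform (``exp``) of the multiplicative rows.
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    V = covariance.matrix if isinstance(covariance, CovarianceEstimate) else np.asarray(covariance)
    theta = fit.theta
    if V.shape != (theta.size, theta.size):
        raise ValueError("covariance shape does not match the parameter count")
    se = np.sqrt(np.clip(np.diag(V), 0.0, None))
    zq = norm.ppf(0.5 + level / 2.0)
    p = len(fit.spec.additive)
    scale = ["additive"] * p + ["baseline"] + ["multiplicative"] * len(fit.spec.multiplicative)
    out = pd.DataFrame(
        {
            "term": fit.param_names,
            "scale": scale,
            "estimate": theta,
            "se": se,
            "lower": theta - zq * se,
            "upper": theta + zq * se,
        }
    )
    mult = out["scale"] == "multiplicative"
    out["residual_or"] = np.where(mult, np.exp(out["estimate"]), np.nan)
    out["residual_or_lower"] = np.where(mult, np.exp(out["lower"]), np.nan)
    out["residual_or_upper"] = np.where(mult, np.exp(out["upper"]), np.nan)
    return out
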