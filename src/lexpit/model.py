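"""The lexpit (linear-expit) risk function and coefficient transforms.

The model for the absolute (cumulative) risk of disease within a fixed
period ``tau`` given additive covariates ``x`` and multiplicative
covariates ``z`` is

    R(x, z) = beta' x + expit(gamma0 + gamma' z)

a sum of a linear risk-difference part and a logistic part.  Each
``beta`` coefficient is an adjusted risk difference per unit of the
corresponding ``x`` variable (probability units).  Each ``exp(gamma)``
is a *residual odds ratio*: the odds-ratio effect of a ``z`` variable on
the risk that remains after subtracting the additive component
``beta'x``.  The baseline risk is ``R0 = expit(gamma0)``; placing the
intercept inside the expit keeps the baseline in (0, 1) without a
constraint.

Setting all additive terms to zero recovers ordinary logistic
regression; an empty multiplicative block recovers the binomial linear
(pure additive risk) model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit as _expit
from scipy.stats import norm

__all__ = [
    "LexpitSpec",
    "ParameterVector",
    "expit",
    "predict_risk",
    "incidence_rate",
    "residual_odds_ratio",
    "risk_difference_report",
]


def expit(u):
    """Numerically stable inverse logit, e^u / (1 + e^u)."""
    return _expit(u)


@dataclass(frozen=True)
class LexpitSpec:
    """Which covariates act additively vs multiplicatively, plus tau.

    Parameters
    ----------
    additive : tuple of str
        Covariate names entering the linear (risk-difference) block.
    multiplicative : tuple of str
        Covariate names entering the logistic block; an intercept
        ``gamma0`` is always implicit and never listed.
    tau : float
        Risk-period length (case-ascertainment duration), user units.
    centers, scales : dict
        Optional per-covariate offsets and divisors applied before the
        model sees the values: ``(v - center) / scale``.  Centering a
        continuous multiplicative covariate (e.g. age at 60) makes
        ``expit(gamma0)`` the baseline risk at the reference value;
        scaling an additive covariate (e.g. pack-years by 10) makes
        ``beta`` the risk difference per 10 units.
    allow_dual : bool
        Permit a covariate in both blocks (used by the dual-scale
        diagnostic; generally weakly identified, hence off by default).
    """

    additive: tuple[str, ...] = ()
    multiplicative: tuple[str, ...] = ()
    tau: float = 1.0
    centers: dict = field(default_factory=dict)
    scales: dict = field(default_factory=dict)
    allow_dual: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "additive", tuple(self.additive))
        object.__setattr__(self, "multiplicative", tuple(self.multiplicative))
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if len(set(self.additive)) != len(self.additive):
            raise ValueError("duplicate names in the additive block")
        if len(set(self.multiplicative)) != len(self.multiplicative):
            raise ValueError("duplicate names in the multiplicative block")
        overlap = set(self.additive) & set(self.multiplicative)
        if overlap and not self.allow_dual:
            raise ValueError(
                f"covariate(s) {sorted(overlap)} appear in both blocks; set "
                "allow_dual=True (used by the dual-scale diagnostic) if intended"
            )

    @property
    def n_params(self) -> int:
        return len(self.additive) + 1 + len(self.multiplicative)

    @property
    def param_names(self) -> list[str]:
        return list(self.additive) + ["(baseline)"] + list(self.multiplicative)

    def transform_column(self, name: str, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        c = float(self.centers.get(name, 0.0))
        s = float(self.scales.get(name, 1.0))
        if s == 0:
            raise ValueError(f"scale for covariate {name!r} must be nonzero")
        return (v - c) / s

    def design_matrices(self, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Extract (X, Z) from a subject table, applying centers/scales."""
        missing = [c for c in (*self.additive, *self.multiplicative) if c not in data.columns]
        if missing:
            raise ValueError(f"covariate(s) not in the data: {missing}")
        n = len(data)
        X = np.empty((n, len(self.additive)))
        for k, name in enumerate(self.additive):
            X[:, k] = self.transform_column(name, data[name].to_numpy())
        Z = np.empty((n, len(self.multiplicative)))
        for k, name in enumerate(self.multiplicative):
            Z[:, k] = self.transform_column(name, data[name].to_numpy())
        if np.any(~np.isfinite(X)) or np.any(~np.isfinite(Z)):
            raise ValueError("covariates contain non-finite values; drop or impute first")
        return X, Z


@dataclass(frozen=True)
class ParameterVector:
    """Full lexpit coefficient set (beta, gamma0, gamma)."""

    beta: np.ndarray
    gamma0: float
    gamma: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, dtype=float)))
        object.__setattr__(self, "gamma", np.atleast_1d(np.asarray(self.gamma, dtype=float)))
        if not np.all(np.isfinite(self.beta)) or not np.all(np.isfinite(self.gamma)):
            raise ValueError("coefficients must be finite")
        if not np.isfinite(self.gamma0):
            raise ValueError("gamma0 must be finite")

    @property
    def theta(self) -> np.ndarray:
        """Flat parameter vector [beta, gamma0, gamma]."""
        return np.concatenate([self.beta, [self.gamma0], self.gamma])

    @classmethod
    def from_theta(cls, theta: np.ndarray, n_additive: int) -> "ParameterVector":
        theta = np.asarray(theta, dtype=float)
        return cls(
            beta=theta[:n_additive],
            gamma0=float(theta[n_additive]),
            gamma=theta[n_additive + 1 :],
        )

    @property
    def baseline_risk(self) -> float:
        """R0 = expit(gamma0), risk at x = 0, z = 0."""
        return float(expit(self.gamma0))


def predict_risk(params: ParameterVector, x, z) -> np.ndarray | float:
    """Absolute risk R(x, z) = beta'x + expit(gamma0 + gamma'z).

    ``x`` and ``z`` may be single covariate vectors or (n, p) arrays.
    Values are returned unclipped; for a converged constrained fit every
    observed pattern lies in [0, 1].
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if x.shape[1] != params.beta.size:
        raise ValueError(f"x has {x.shape[1]} columns but beta has {params.beta.size}")
    if z.shape[1] != params.gamma.size:
        raise ValueError(f"z has {z.shape[1]} columns but gamma has {params.gamma.size}")
    r = x @ params.beta + expit(params.gamma0 + z @ params.gamma)
    return float(r[0]) if r.size == 1 and np.ndim(r) == 1 and x.shape[0] == 1 else r


def incidence_rate(params: ParameterVector, x, z, tau: float):
    """Average incidence rate R(x, z) / tau, assuming constant risk
    over the risk period (per person-time-unit of ``tau``)."""
    if not tau > 0:
        raise ValueError(f"tau must be positive, got {tau}")
    return predict_risk(params, x, z) / tau


def residual_odds_ratio(gamma_k: float, delta: float = 1.0) -> float:
    """Residual odds ratio exp(gamma_k * delta) for a delta-unit
    increase of a multiplicative covariate."""
    return float(np.exp(gamma_k * delta))


def risk_difference_report(
    params: ParameterVector,
    spec: LexpitSpec,
    covariance: np.ndarray | None = None,
    scale_factor: float = 100_000.0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Tabulate coefficients on reporting scales.

    Additive coefficients are reported as risk differences per
    ``scale_factor`` persons per risk period, with Wald intervals on the
    same scale.  Multiplicative coefficients are reported as residual
    odds ratios ``exp(gamma)`` with intervals from exponentiating the
    Wald endpoints of ``gamma``.  When no covariance is available the
    interval columns are NaN and the table is flagged via the
    ``"se"`` column being NaN.
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    zq = norm.ppf(0.5 + level / 2.0)
    theta = params.theta
    names = spec.param_names
    p = len(spec.additive)
    if covariance is not None:
        covariance = np.asarray(covariance, dtype=float)
        if covariance.shape != (theta.size, theta.size):
            raise ValueError("covariance shape does not match the parameter count")
        se = np.sqrt(np.clip(np.diag(covariance), 0.0, None))
    else:
        se = np.full(theta.size, np.nan)

    rows = []
    for k, name in enumerate(names):
        est, s = theta[k], se[k]
        if k < p:  # additive: scaled risk difference
            rows.append(
                {
                    "term": name,
                    "scale": "additive",
                    "estimate": est * scale_factor,
                    "se": s * scale_factor,
                    "lower": (est - zq * s) * scale_factor,
                    "upper": (est + zq * s) * scale_factor,
                }
            )
        elif k == p:  # baseline risk
            rows.append(
                {
                    "term": name,
                    "scale": "baseline",
                    "estimate": float(expit(est)) * scale_factor,
                    "se": np.nan,
                    "lower": float(expit(est - zq * s)) * scale_factor,
                    "upper": float(expit(est + zq * s)) * scale_factor,
                }
            )
        else:  # multiplicative: residual odds ratio
            rows.append(
                {
                    "term": name,
                    "scale": "multiplicative",
                    "estimate": float(np.exp(est)),
                    "se": s,
                    "lower": float(np.exp(est - zq * s)),
                    "upper": float(np.exp(est + zq * s)),
                }
            )
    return pd.DataFrame(rows)
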