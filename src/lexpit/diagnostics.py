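"""Goodness of fit and scale-of-effect diagnostics.

Three practical tools for deciding whether an exposure acts on the
additive (risk-difference) or multiplicative (odds-ratio) scale:

* a weighted Hosmer-Lemeshow chi-squared statistic, computed on the
  expansion-weighted (study-base) scale, used comparatively -- lower is
  better-calibrated;
* a risk-exposure scatter: crude weighted risk by exposure bin, whose
  shape (linear vs. curved) suggests the effect scale;
* a dual-scale comparison that fits the exposure additively,
  multiplicatively, and on both scales at once, reporting coefficients,
  Wald z statistics and goodness of fit side by side without an
  automatic verdict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CaseControlDesign
from .estimation import FitOptions, FitResult, fit_lexpit
from .inference import influence_vectors, linearized_covariance
from .model import LexpitSpec

logger = logging.getLogger(__name__)

__all__ = [
    "GofResult",
    "weighted_hosmer_lemeshow",
    "risk_exposure_scatter",
    "dual_scale_comparison",
    "DualScaleReport",
]


@dataclass(frozen=True)
class GofResult:
    """Weighted Hosmer-Lemeshow statistic and its group table."""

    statistic: float
    n_groups: int
    group_table: pd.DataFrame  # observed, expected, weight per group


def _group_by_weight(order_w: np.ndarray, n_groups: int) -> np.ndarray:
    """Assign sorted observations to groups of near-equal total weight."""
    cw = np.cumsum(order_w)
    total = cw[-1]
    # position of each observation's weight midpoint on the cumulative scale
    mid = cw - order_w / 2.0
    g = np.minimum((mid / total * n_groups).astype(int), n_groups - 1)
    return g


def weighted_hosmer_lemeshow(
    fit: FitResult | None,
    data: pd.DataFrame | None = None,
    n_groups: int = 10,
    y: np.ndarray | None = None,
    risks: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> GofResult:
    """Weighted Hosmer-Lemeshow goodness-of-fit statistic.

    Observations are ranked by fitted risk and partitioned into
    ``n_groups`` groups of nearly equal *total weight* (weights span
    orders of magnitude between cases and expanded controls, so equal
    weight -- not equal count -- stabilizes the expected counts on the
    population scale).  With ``O_g = sum w y``, ``E_g = sum w R_hat``
    and ``W_g = sum w`` per group,

        X^2 = sum_g (O_g - E_g)^2 / (E_g (1 - E_g / W_g)).

    When all weights equal 1 and groups are deciles of fitted risk this
    is the classical Hosmer-Lemeshow statistic.  No p-value is attached:
    under expansion weighting the reference distribution is nonstandard,
    and the statistic is meant for model comparison (lower = better).

    Either pass a :class:`FitResult`, or pass ``y``/``risks``/
    ``weights`` arrays directly.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be at least 2")
    if fit is not None:
        y = fit.y
        risks = fit.clipped_risks()
        weights = fit.weights
    if y is None or risks is None:
        raise ValueError("provide either a fit or explicit y and risks")
    y = np.asarray(y, dtype=float)
    risks = np.asarray(risks, dtype=float)
    weights = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    order = np.argsort(risks, kind="stable")
    g = _group_by_weight(weights[order], n_groups)
    ys, rs, ws = y[order], risks[order], weights[order]

    rows = []
    for gi in range(n_groups):
        m = g == gi
        if not np.any(m):
            continue
        rows.append(
            {
                "observed": float(np.sum(ws[m] * ys[m])),
                "expected": float(np.sum(ws[m] * rs[m])),
                "weight": float(np.sum(ws[m])),
                "n": int(m.sum()),
            }
        )
    # merge groups whose expected count is degenerate (E = 0 or E = W)
    merged: list[dict] = []
    for row in rows:
        if merged and (
            merged[-1]["expected"] <= 0.0
            or merged[-1]["expected"] >= merged[-1]["weight"]
        ):
            logger.info("merging a degenerate goodness-of-fit group with its neighbour")
            for k in ("observed", "expected", "weight", "n"):
                merged[-1][k] += row[k]
        else:
            merged.append(dict(row))
    while len(merged) > 1 and (
        merged[-1]["expected"] <= 0.0 or merged[-1]["expected"] >= merged[-1]["weight"]
    ):
        last = merged.pop()
        logger.info("merging a degenerate goodness-of-fit group with its neighbour")
        for k in ("observed", "expected", "weight", "n"):
            merged[-1][k] += last[k]

    table = pd.DataFrame(merged)
    denom = table["expected"] * (1.0 - table["expected"] / table["weight"])
    stat = float(np.sum((table["observed"] - table["expected"]) ** 2 / denom))
    return GofResult(statistic=stat, n_groups=len(table), group_table=table)


def risk_exposure_scatter(
    data: pd.DataFrame,
    exposure: str,
    n_bins: int = 10,
    outcome: str = "outcome",
    weight_col: str = "weight",
) -> pd.DataFrame:
    """Crude weighted risk by exposure bin.

    Bins contain near-equal total weight.  Per bin the table reports the
    exposure midpoint, the weighted mean exposure, the crude weighted
    risk ``sum(w y) / sum(w)`` and the total weight.  A straight-line
    pattern suggests an additive (risk-difference) effect; exponential
    curvature suggests a multiplicative one.
    """
    if exposure not in data.columns:
        raise ValueError(f"exposure column {exposure!r} not found")
    x = data[exposure].to_numpy(dtype=float)
    if not np.issubdtype(x.dtype, np.number):
        raise ValueError(f"exposure {exposure!r} must be numeric")
    y = data[outcome].to_numpy(dtype=float)
    w = (
        data[weight_col].to_numpy(dtype=float)
        if weight_col in data.columns
        else np.ones(len(data))
    )
    order = np.argsort(x, kind="stable")
    g = _group_by_weight(w[order], n_bins)
    xs, ys, ws = x[order], y[order], w[order]
    rows = []
    for gi in np.unique(g):
        m = g == gi
        rows.append(
            {
                "bin": int(gi),
                "midpoint": float((xs[m].min() + xs[m].max()) / 2.0),
                "mean_exposure": float(np.average(xs[m], weights=ws[m])),
                "risk": float(np.sum(ws[m] * ys[m]) / np.sum(ws[m])),
                "weight": float(np.sum(ws[m])),
                "n": int(m.sum()),
            }
        )
    if len(rows) < 2:
        raise ValueError("fewer than 2 nonempty exposure bins; widen the data or reduce n_bins")
    return pd.DataFrame(rows)


def plot_risk_exposure(table: pd.DataFrame, path: str | None = None, exposure: str = "exposure"):
    """Render the risk-exposure scatter (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(table["mean_exposure"], table["risk"], "o-")
    ax.set_xlabel(exposure)
    ax.set_ylabel("crude weighted risk")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


@dataclass
class DualScaleReport:
    """Side-by-side additive / multiplicative / joint fits for one variable."""

    variable: str
    summary: pd.DataFrame
    gof: dict
    fits: dict = field(repr=False)
    joint_available: bool = True
    notes: str = ""


def _fit_with_se(data, spec, design, weight_col, n_groups):
    fit = fit_lexpit(data, spec, design=design, weight_col=weight_col,
                     options=FitOptions())
    se = None
    try:
        cov = linearized_covariance(influence_vectors(fit))
        se = cov.se
    except Exception as err:  # singular information etc.
        logger.warning("variance unavailable for a dual-scale fit: %s", err)
    gof = weighted_hosmer_lemeshow(fit, n_groups=n_groups).statistic
    return fit, se, gof


def dual_scale_comparison(
    data: pd.DataFrame,
    spec: LexpitSpec,
    design: CaseControlDesign | None,
    variable: str,
    weight_col: str | None = None,
    n_groups: int = 10,
) -> DualScaleReport:
    """Compare additive vs. multiplicative treatment of one variable.

    Fits three models -- the variable additive-only, multiplicative-only,
    and on both scales jointly (other covariates as in ``spec``) -- and
    reports each coefficient with its linearized SE and Wald z, plus the
    weighted Hosmer-Lemeshow statistic per model.  The relative |z| of
    the two coefficients in the joint model indicates which scale the
    data favor; no automatic verdict is made.
    """
    if variable not in data.columns:
        raise ValueError(f"variable {variable!r} not found in the data")
    base_add = tuple(c for c in spec.additive if c != variable)
    base_mult = tuple(c for c in spec.multiplicative if c != variable)

    def make_spec(add: bool, mult: bool) -> LexpitSpec:
        return LexpitSpec(
            additive=base_add + ((variable,) if add else ()),
            multiplicative=base_mult + ((variable,) if mult else ()),
            tau=spec.tau,
            centers=spec.centers,
            scales=spec.scales,
            allow_dual=add and mult,
        )

    fits, gof, rows = {}, {}, []
    for name, (add, mult) in {
        "additive": (True, False),
        "multiplicative": (False, True),
        "joint": (True, True),
    }.items():
        try:
            fit, se, g = _fit_with_se(data, make_spec(add, mult), design, weight_col, n_groups)
        except Exception as err:
            if name == "joint":
                logger.warning("joint dual-scale model failed: %s", err)
                fits[name] = None
                continue
            raise
        if name == "joint" and not (fit.converged or fit.active_constraints):
            logger.warning("joint dual-scale model did not converge; reporting single-scale fits")
            fits[name] = None
            continue
        fits[name], gof[name] = fit, g
        names = fit.param_names
        for scale_label, want in (("additive", add), ("multiplicative", mult)):
            if not want:
                continue
            if scale_label == "additive":
                k = names.index(variable)
            else:
                k = len(fit.spec.additive) + 1 + fit.spec.multiplicative.index(variable)
            est = fit.theta[k]
            s = se[k] if se is not None else np.nan
            rows.append(
                {
                    "model": name,
                    "scale": scale_label,
                    "estimate": est,
                    "se": s,
                    "z": est / s if s and np.isfinite(s) and s > 0 else np.nan,
                    "gof": g,
                    "converged": fit.converged,
                }
            )

    joint_ok = fits.get("joint") is not None
    return DualScaleReport(
        variable=variable,
        summary=pd.DataFrame(rows),
        gof=gof,
        fits=fits,
        joint_available=joint_ok,
        notes="" if joint_ok else "joint model unavailable; single-scale fits only",
    )
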