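"""Reading subject/design tables, run configuration and report rendering."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import CaseControlDesign
from .estimation import FitResult
from .inference import CovarianceEstimate
from .model import risk_difference_report

logger = logging.getLogger(__name__)

__all__ = [
    "read_subject_table",
    "read_design_table",
    "render_report",
    "results_to_dict",
    "results_from_dict",
    "RunConfig",
]


def read_subject_table(
    path,
    outcome: str = "outcome",
    stratum: str = "stratum",
    categorical: Sequence[str] | None = None,
    trend: Mapping[str, Sequence] | None = None,
    references: Mapping[str, object] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Load and validate a delimited subject table.

    The outcome column must be coded 0/1.  Columns named in
    ``categorical`` are expanded to 0/1 indicator columns
    (``name=level``), omitting a reference level (first observed, or the
    one given in ``references``).  Columns named in ``trend`` are
    ordinal scores: the mapping value lists the levels in order and the
    column is replaced by integer codes 0, 1, 2, ...  Rows with missing
    values are dropped with a logged count (complete-case analysis).
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if outcome not in df.columns:
        raise ValueError(f"subject table has no outcome column {outcome!r}")
    vals = set(pd.unique(df[outcome].dropna()))
    if not vals <= {0, 1}:
        raise ValueError(
            f"outcome column {outcome!r} must be coded 0/1, found {sorted(map(str, vals))}"
        )

    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.info("dropped %d row(s) with missing values (complete-case)", n0 - len(df))
    df = df.reset_index(drop=True)

    for name, levels in (trend or {}).items():
        if name not in df.columns:
            raise ValueError(f"trend column {name!r} not found")
        codes = {lev: k for k, lev in enumerate(levels)}
        unknown = set(df[name].unique()) - set(levels)
        if unknown:
            raise ValueError(
                f"trend column {name!r} has unlisted level(s): {sorted(map(str, unknown))}"
            )
        df[name] = df[name].map(codes).astype(float)

    references = dict(references or {})
    for name in categorical or ():
        if name not in df.columns:
            raise ValueError(f"categorical column {name!r} not found")
        levels = list(pd.unique(df[name]))
        ref = references.get(name, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not observed in column {name!r}")
        logger.info("expanding %r with reference level %r", name, ref)
        for lev in levels:
            if lev == ref:
                continue
            df[f"{name}={lev}"] = (df[name] == lev).astype(float)
        df = df.drop(columns=[name])

    return df


def read_design_table(path, tau: float = 1.0, sep: str | None = None) -> CaseControlDesign:
    """Load a design table (columns stratum, population_size, n_controls)."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    cases_col = "n_cases" if "n_cases" in df.columns else None
    return CaseControlDesign.from_frame(df, tau=tau, cases_col=cases_col)


def results_to_dict(
    fit: FitResult, covariance: CovarianceEstimate | None = None
) -> dict:
    """Machine-readable fit summary (JSON-serializable, lossless
    round-trip of the coefficient values)."""
    out = {
        "model": {
            "additive": list(fit.spec.additive),
            "multiplicative": list(fit.spec.multiplicative),
            "tau": fit.spec.tau,
            "centers": dict(fit.spec.centers),
            "scales": dict(fit.spec.scales),
        },
        "coefficients": {
            "beta": fit.params.beta.tolist(),
            "gamma0": fit.params.gamma0,
            "gamma": fit.params.gamma.tolist(),
        },
        "param_names": fit.param_names,
        "loglik": float(fit.loglik),
        "converged": bool(fit.converged),
        "n_iterations": fit.n_iterations,
        "n_active_constraints": len(fit.active_constraints),
        "n_obs": int(len(fit.y)),
        "n_cases": int(fit.y.sum()),
        "weight_total": float(fit.weights.sum()),
        "message": fit.message,
    }
    if covariance is not None:
        out["covariance"] = {
            "matrix": covariance.matrix.tolist(),
            "method": covariance.method,
            "df_note": covariance.df_note,
        }
    return out


def results_from_dict(payload: dict) -> dict:
    """Re-parse a saved result; coefficient arrays come back bit-exact."""
    coef = payload["coefficients"]
    return {
        "beta": np.asarray(coef["beta"], dtype=float),
        "gamma0": float(coef["gamma0"]),
        "gamma": np.asarray(coef["gamma"], dtype=float),
        "covariance": (
            np.asarray(payload["covariance"]["matrix"], dtype=float)
            if "covariance" in payload
            else None
        ),
        "payload": payload,
    }


def render_report(
    fit: FitResult,
    covariance: CovarianceEstimate | None = None,
    diagnostics: Mapping[str, float] | None = None,
    scale_factor: float = 100_000.0,
    level: float = 0.95,
) -> str:
    """Human-readable regression report.

    Additive effects appear as risk differences per ``scale_factor``
    persons per risk period with Wald intervals; multiplicative effects
    as residual odds ratios.  A metadata block records tau, the scale,
    sample sizes, weight totals, convergence and constraint activity.
    """
    V = covariance.matrix if covariance is not None else None
    table = risk_difference_report(
        fit.params, fit.spec, covariance=V, scale_factor=scale_factor, level=level
    )
    lines = []
    if not fit.converged:
        lines.append("*" * 66)
        lines.append("*** WARNING: THE FIT DID NOT CONVERGE -- do not interpret ***")
        if fit.message:
            lines.append(f"*** {fit.message}")
        lines.append("*" * 66)
    lines.append("lexpit regression")
    lines.append("=" * 66)
    pct = int(round(level * 100))
    lines.append(
        f"{'term':<22}{'scale':<16}{'estimate':>10}{f'  {pct}% CI':<20}"
    )
    lines.append("-" * 66)
    for _, row in table.iterrows():
        if row["scale"] == "additive":
            label = f"RD per {scale_factor:g}"
            est = f"{row['estimate']:.1f}"
        elif row["scale"] == "baseline":
            label = f"risk per {scale_factor:g}"
            est = f"{row['estimate']:.1f}"
        else:
            label = "residual OR"
            est = f"{row['estimate']:.2f}"
        if np.isfinite(row["lower"]):
            fmt = ".1f" if row["scale"] != "multiplicative" else ".2f"
            ci = f"({row['lower']:{fmt}}, {row['upper']:{fmt}})"
        else:
            ci = "(no covariance)"
        lines.append(f"{row['term']:<22}{label:<16}{est:>10}  {ci:<20}")
    lines.append("-" * 66)
    lines.append(
        f"tau = {fit.spec.tau:g}; n = {len(fit.y)} ({int(fit.y.sum())} cases); "
        f"weighted study base = {fit.weights.sum():,.0f}"
    )
    lines.append(
        f"pseudo-log-likelihood = {fit.loglik:.4f}; converged = {fit.converged}; "
        f"active constraints = {len(fit.active_constraints)}"
    )
    if covariance is not None:
        lines.append(f"variance: {covariance.method} ({covariance.df_note})")
    if diagnostics:
        for k, v in diagnostics.items():
            lines.append(f"{k}: {v:.4g}")
    return "\n".join(lines)


@dataclass
class RunConfig:
    """Validated configuration for a command-line run."""

    data_path: str
    design_path: str | None = None
    output_path: str | None = None
    additive: tuple[str, ...] = ()
    multiplicative: tuple[str, ...] = ()
    tau: float = 1.0
    centers: dict = field(default_factory=dict)
    scales: dict = field(default_factory=dict)
    outcome: str = "outcome"
    stratum: str = "stratum"
    weight_col: str | None = None
    variance: str = "linearized"
    boot_reps: int = 500
    seed: int | None = None
    scale_factor: float = 100_000.0
    n_groups: int = 10
    allow_nonconverged: bool = False

    def __post_init__(self) -> None:
        if not self.data_path:
            raise ValueError("config field 'data_path' is required")
        if self.variance not in ("linearized", "bootstrap", "none"):
            raise ValueError(
                f"config field 'variance' must be linearized|bootstrap|none, got {self.variance!r}"
            )
        if not self.tau > 0:
            raise ValueError(f"config field 'tau' must be positive, got {self.tau}")
        if self.design_path is None and self.weight_col is None:
            raise ValueError("either 'design_path' or 'weight_col' must be set")
        if not self.additive and not self.multiplicative:
            raise ValueError("at least one covariate must be named in a model block")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        try:
            return cls(**payload)
        except TypeError as err:
            raise ValueError(f"unrecognized config field: {err}") from err


def save_results(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_results(path) -> dict:
    with open(path) as fh:
        return results_from_dict(json.load(fh))
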