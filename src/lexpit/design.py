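"""Stratified case-control sampling designs and expansion weights.

A population-based case-control study with complete case ascertainment
identifies every incident case in a well-defined study base and draws a
simple random sample of controls within each sampling stratum (for
example residence x age x gender cells of a census frame).  Expansion
weights -- 1 for cases, ``N_j / n_j`` for the controls of stratum ``j``
-- project the sample back onto the study base, which is what allows a
case-control sample to estimate absolute risks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Stratum",
    "CaseControlDesign",
    "compute_sampling_weights",
    "expansion_totals",
]


@dataclass(frozen=True)
class Stratum:
    """One sampling stratum of the study base.

    Parameters
    ----------
    label : str
        Unique stratum identifier.
    population_size : int
        Number of persons in the study base belonging to this stratum
        (``N_j``, typically a census count).
    n_controls_sampled : int
        Number of controls drawn from the stratum (``n_j``).
    n_cases : int
        Number of ascertained cases in the stratum; informational, not
        used for weighting (cases always carry weight 1).
    """

    label: str
    population_size: int
    n_controls_sampled: int
    n_cases: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 0 or self.n_controls_sampled < 0 or self.n_cases < 0:
            raise ValueError(f"stratum {self.label!r}: counts must be non-negative")
        if self.n_controls_sampled > self.population_size:
            raise ValueError(
                f"stratum {self.label!r}: sampled {self.n_controls_sampled} controls "
                f"from a population of only {self.population_size}"
            )
        if self.n_controls_sampled > 0 and self.population_size == 0:
            raise ValueError(f"stratum {self.label!r}: controls sampled from an empty population")

    @property
    def control_weight(self) -> float:
        """Expansion weight N_j / n_j for controls of this stratum."""
        if self.n_controls_sampled == 0:
            raise ZeroDivisionError(
                f"stratum {self.label!r} sampled no controls; its control weight is undefined"
            )
        return self.population_size / self.n_controls_sampled

    @property
    def sampling_fraction(self) -> float:
        """Probability of selection for a control, n_j / N_j."""
        if self.population_size == 0:
            return 0.0
        return self.n_controls_sampled / self.population_size


@dataclass(frozen=True)
class CaseControlDesign:
    """A stratified case-control sampling design.

    Holds the strata of the study base and the length ``tau`` of the
    risk (case-ascertainment) period, in whatever time unit the user
    declares (commonly years).
    """

    strata: tuple[Stratum, ...]
    tau: float = 1.0

    def __post_init__(self) -> None:
        labels = [s.label for s in self.strata]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate stratum labels: {dupes}")
        if not self.tau > 0:
            raise ValueError(f"risk-period length tau must be positive, got {self.tau}")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        tau: float = 1.0,
        label_col: str = "stratum",
        population_col: str = "population_size",
        controls_col: str = "n_controls",
        cases_col: str | None = None,
    ) -> "CaseControlDesign":
        """Build a design from a table with one row per stratum."""
        missing = {label_col, population_col, controls_col} - set(frame.columns)
        if missing:
            raise ValueError(f"design table is missing columns: {sorted(missing)}")
        strata = tuple(
            Stratum(
                label=str(row[label_col]),
                population_size=int(row[population_col]),
                n_controls_sampled=int(row[controls_col]),
                n_cases=int(row[cases_col]) if cases_col else 0,
            )
            for _, row in frame.iterrows()
        )
        return cls(strata=strata, tau=tau)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": [s.label for s in self.strata],
                "population_size": [s.population_size for s in self.strata],
                "n_controls": [s.n_controls_sampled for s in self.strata],
                "n_cases": [s.n_cases for s in self.strata],
            }
        )

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.strata]

    def __getitem__(self, label: str) -> Stratum:
        for s in self.strata:
            if s.label == label:
                return s
        raise KeyError(f"unknown stratum label {label!r}")

    @property
    def population_total(self) -> int:
        return sum(s.population_size for s in self.strata)

    def control_weights(self) -> Mapping[str, float]:
        """Map stratum label -> control expansion weight (strata with
        no sampled controls are omitted)."""
        return {
            s.label: s.control_weight for s in self.strata if s.n_controls_sampled > 0
        }


def compute_sampling_weights(
    design: CaseControlDesign | None,
    data: pd.DataFrame,
    outcome: str = "outcome",
    stratum: str = "stratum",
    weight_col: str | None = None,
    case_weight_col: str | None = None,
    out_col: str = "weight",
) -> pd.DataFrame:
    """Attach expansion weights to a subject table.

    Cases (``outcome == 1``) receive weight 1; controls in stratum *j*
    receive ``N_j / n_j``.  Row order is preserved.

    Parameters
    ----------
    design :
        Sampling design, or ``None`` when an explicit ``weight_col`` is
        given.
    data :
        Subject table with a binary outcome column and a stratum column.
    weight_col :
        Name of an explicit per-row weight column.  If both a design and
        a weight column are supplied, the explicit column wins and a
        warning is logged (this accommodates designs whose sampling
        fractions were computed elsewhere).
    case_weight_col :
        Optional column with case weights, overriding the default weight
        of 1 for incompletely ascertained cases.
    """
    if outcome not in data.columns:
        raise ValueError(f"subject table has no outcome column {outcome!r}")
    y = _validate_binary(data[outcome], outcome)

    if weight_col is not None:
        if weight_col not in data.columns:
            raise ValueError(f"explicit weight column {weight_col!r} not found")
        if design is not None:
            logger.warning(
                "both a design and an explicit weight column %r were given; "
                "using the explicit weights",
                weight_col,
            )
        w = data[weight_col].to_numpy(dtype=float)
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise ValueError(f"weight column {weight_col!r} must be finite and positive")
        out = data.copy()
        out[out_col] = w
        return out

    if design is None:
        raise ValueError("either a design or an explicit weight column is required")
    if stratum not in data.columns:
        raise ValueError(f"subject table has no stratum column {stratum!r}")

    labels = data[stratum].astype(str).to_numpy()
    known = set(design.labels)
    unknown = sorted(set(labels) - known)
    if unknown:
        raise ValueError(f"subject table contains unknown stratum label(s): {unknown}")
    unused = sorted(known - set(labels))
    if unused:
        logger.info("design strata absent from the data are ignored: %s", unused)

    w = np.ones(len(data), dtype=float)
    is_control = y == 0
    cw = {s.label: s for s in design.strata}
    for lab in np.unique(labels[is_control]):
        s = cw[lab]
        if s.n_controls_sampled == 0:
            raise ValueError(
                f"stratum {lab!r} has controls in the data but n_controls = 0 in the "
                "design; the expansion weight N/n is undefined"
            )
        w[is_control & (labels == lab)] = s.control_weight

    if case_weight_col is not None:
        if case_weight_col not in data.columns:
            raise ValueError(f"case weight column {case_weight_col!r} not found")
        cwts = data[case_weight_col].to_numpy(dtype=float)
        w[y == 1] = cwts[y == 1]

    out = data.copy()
    out[out_col] = w
    return out


def expansion_totals(
    data: pd.DataFrame,
    outcome: str = "outcome",
    stratum: str = "stratum",
    weight_col: str = "weight",
) -> pd.DataFrame:
    """Per-stratum weighted control totals and raw case counts.

    With design-derived weights, the weighted number of controls in
    stratum *j* equals ``(N_j/n_j) * n_j = N_j`` exactly, so the table
    estimates the size of the study base each stratum represents.
    """
    for col in (outcome, stratum, weight_col):
        if col not in data.columns:
            raise ValueError(f"column {col!r} not found; attach weights first")
    y = _validate_binary(data[outcome], outcome)
    df = pd.DataFrame(
        {
            "stratum": data[stratum].astype(str).to_numpy(),
            "case": y,
            "w": data[weight_col].to_numpy(dtype=float),
        }
    )
    grouped = df.groupby("stratum", sort=True)
    out = pd.DataFrame(
        {
            "n_cases": grouped["case"].sum().astype(int),
            "n_controls": grouped.apply(lambda g: int((g["case"] == 0).sum()), include_groups=False),
            "weighted_controls": grouped.apply(
                lambda g: float(g.loc[g["case"] == 0, "w"].sum()), include_groups=False
            ),
        }
    )
    out["weighted_total"] = out["weighted_controls"] + grouped.apply(
        lambda g: float(g.loc[g["case"] == 1, "w"].sum()), include_groups=False
    )
    return out


def _validate_binary(series: pd.Series, name: str) -> np.ndarray:
    y = series.to_numpy()
    vals = set(pd.unique(series.dropna()))
    if not vals <= {0, 1, 0.0, 1.0, False, True}:
        raise ValueError(f"outcome column {name!r} must be coded 0/1, found values {sorted(vals)}")
    return np.asarray(y, dtype=float).astype(int)
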