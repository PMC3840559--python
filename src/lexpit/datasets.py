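"""Built-in study-design constants and worked-example data.

The reference design is the sampling frame of a population-based
case-control study of lung cancer conducted in the Lombardy region of
Northern Italy (the EAGLE study): controls were drawn from the census in
90 strata defined by region of residence (5), age band (9) and gender
(2), over a 34-month (~3-year) case-ascertainment period.  The
projected control population and the number of sampled controls per
stratum are reproduced here; they parameterize the default synthetic
scenario and the worked two-stratum gender example.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import CaseControlDesign, Stratum

__all__ = [
    "lombardy_strata",
    "gender_design",
    "gender_example_data",
    "GENDER_TOTALS",
]

_REGIONS = ["Milan", "Monza", "Brescia", "Pavia", "Varese"]
_AGE_BANDS = [
    (35, 39), (40, 44), (45, 49), (50, 54), (55, 59),
    (60, 64), (65, 69), (70, 74), (75, 80),
]

# (population, controls sampled) per age band x region, males then females
_MALE = [
    [(70630, 3), (12352, 1), (22479, 1), (9202, 2), (9866, 1)],
    [(58166, 9), (10045, 4), (18816, 2), (7958, 1), (8156, 3)],
    [(50727, 25), (9143, 3), (16644, 3), (7046, 5), (7698, 2)],
    [(55952, 56), (9677, 3), (17760, 18), (7508, 3), (8155, 7)],
    [(51407, 145), (8281, 8), (14665, 33), (5951, 8), (6783, 25)],
    [(55106, 209), (9083, 17), (14682, 47), (6765, 15), (7127, 20)],
    [(45477, 251), (7043, 26), (11334, 42), (5855, 30), (5765, 41)],
    [(35965, 242), (5423, 22), (8995, 30), (4518, 20), (4640, 27)],
    [(24960, 149), (3430, 10), (6291, 18), (3417, 8), (3278, 22)],
]
_FEMALE = [
    [(68084, 5), (11717, 1), (20391, 1), (0, 0), (9509, 2)],
    [(57734, 2), (10122, 1), (17455, 1), (7410, 4), (8061, 1)],
    [(53942, 13), (9387, 4), (16248, 7), (6979, 3), (7754, 6)],
    [(63060, 27), (10307, 1), (17739, 3), (7424, 7), (8545, 2)],
    [(58781, 61), (9022, 2), (15140, 7), (6085, 5), (7099, 6)],
    [(63452, 43), (9607, 5), (15885, 8), (7352, 4), (7675, 3)],
    [(56296, 73), (8152, 5), (12439, 9), (7199, 7), (6822, 4)],
    [(50119, 63), (7090, 3), (13220, 7), (6763, 4), (6083, 4)],
    [(43166, 62), (5610, 1), (11221, 10), (5732, 3), (5404, 9)],
]

# study-base margins by gender: control population, sampled controls,
# ascertained cases over the ~3-year period
GENDER_TOTALS = {
    "male": {"population": 774_221, "n_controls": 1_617, "n_cases": 1_537},
    "female": {"population": 851_550, "n_controls": 499, "n_cases": 406},
}


def lombardy_strata() -> pd.DataFrame:
    """The 90-stratum Lombardy control sampling frame.

    One row per gender x age band x region cell with its projected
    population and number of sampled controls.  One cell (Pavia women
    35-39) is empty in the frame and carries zero counts.
    """
    rows = []
    for gender, table in (("male", _MALE), ("female", _FEMALE)):
        for (lo, hi), line in zip(_AGE_BANDS, table):
            for region, (pop, n) in zip(_REGIONS, line):
                rows.append(
                    {
                        "stratum": f"{gender}|{lo}-{hi}|{region}",
                        "gender": gender,
                        "female": int(gender == "female"),
                        "age_lo": lo,
                        "age_hi": hi,
                        "region": region,
                        "population_size": pop,
                        "n_controls": n,
                    }
                )
    return pd.DataFrame(rows)


def gender_design(tau: float = 3.0) -> CaseControlDesign:
    """Two-stratum design collapsing the frame to gender margins."""
    return CaseControlDesign(
        strata=tuple(
            Stratum(
                label=g,
                population_size=t["population"],
                n_controls_sampled=t["n_controls"],
                n_cases=t["n_cases"],
            )
            for g, t in GENDER_TOTALS.items()
        ),
        tau=tau,
    )


def gender_example_data() -> pd.DataFrame:
    """Subject table for the worked gender-only example.

    All ascertained cases (1,537 men; 406 women) plus the sampled
    controls (1,617 men; 499 women), with a female indicator as the
    single covariate.
    """
    parts = []
    for g, t in GENDER_TOTALS.items():
        fem = int(g == "female")
        parts.append(
            pd.DataFrame(
                {
                    "outcome": np.repeat([1, 0], [t["n_cases"], t["n_controls"]]),
                    "female": fem,
                    "stratum": g,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)
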