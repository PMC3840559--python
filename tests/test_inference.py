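"""Influence-function variance: closed forms, simulation and bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from lexpit import (
    LexpitSpec,
    bootstrap_covariance,
    fit_lexpit,
    influence_vectors,
    linearized_covariance,
    wald_intervals,
)
from lexpit.model import ParameterVector
from lexpit.synthetic import PopulationConfig, gender_scenario, simulate_study

from conftest import make_case_control_frame


def test_influences_sum_to_zero_at_interior_optimum(small_design):
    rng = np.random.default_rng(2)
    data = make_case_control_frame(rng, n=250)
    fit = fit_lexpit(data, LexpitSpec(additive=("x",)), design=small_design)
    infl = influence_vectors(fit)
    # first-order condition: weighted score total vanishes
    assert np.max(np.abs(infl.vectors.sum(axis=0))) < 1e-6


def test_intercept_only_variance_is_binomial():
    """Cohort data, intercept-only: Var(expit(g0_hat)) ~ p(1-p)/n."""
    rng = np.random.default_rng(4)
    n = 400
    y = rng.binomial(1, 0.3, n)
    data = pd.DataFrame({"outcome": y})
    fit = fit_lexpit(data, LexpitSpec())
    infl = influence_vectors(fit)
    cov = linearized_covariance(infl)
    phat = y.mean()
    # influence of observation i has the closed form (y_i - p)/(n p (1-p))
    expected_infl = (y - phat) / (n * phat * (1 - phat))
    assert np.allclose(infl.vectors[:, 0], expected_infl, rtol=1e-6)
    # delta method to the probability scale
    var_prob = (phat * (1 - phat)) ** 2 * cov.matrix[0, 0]
    assert var_prob == pytest.approx(phat * (1 - phat) / n, rel=2 / n * 1.5 + 1e-3)


def test_covariance_symmetric_psd(small_design):
    rng = np.random.default_rng(6)
    data = make_case_control_frame(rng, n=300)
    fit = fit_lexpit(data, LexpitSpec(additive=("x",)), design=small_design)
    cov = linearized_covariance(influence_vectors(fit))
    assert np.allclose(cov.matrix, cov.matrix.T)
    eig = np.linalg.eigvalsh(cov.matrix)
    assert eig.min() >= -1e-10 * np.trace(cov.matrix)


def test_covariance_invariant_to_weight_scaling(small_design):
    """theta_hat and its influence-based covariance ignore w -> c*w."""
    from lexpit import compute_sampling_weights

    rng = np.random.default_rng(9)
    data = make_case_control_frame(rng, n=250)
    spec = LexpitSpec(additive=("x",))
    wdata = compute_sampling_weights(small_design, data)
    fit1 = fit_lexpit(wdata, spec, weight_col="weight")
    wdata["w3"] = 3.0 * wdata.weight
    fit2 = fit_lexpit(wdata, spec, weight_col="w3")
    c1 = linearized_covariance(influence_vectors(fit1))
    c2 = linearized_covariance(influence_vectors(fit2))
    assert np.allclose(c1.matrix, c2.matrix, rtol=1e-6)


def test_wald_interval_multiplier_and_transforms(small_design):
    rng = np.random.default_rng(12)
    data = make_case_control_frame(rng, n=300)
    data["z"] = rng.normal(size=len(data))
    fit = fit_lexpit(data, LexpitSpec(additive=("x",), multiplicative=("z",)), design=small_design)
    cov = linearized_covariance(influence_vectors(fit))
    table = wald_intervals(fit, cov, level=0.95)
    k = 0  # additive coefficient row
    width = table.upper.iloc[k] - table.estimate.iloc[k]
    assert width / table.se.iloc[k] == pytest.approx(1.959964, abs=1e-6)
    # residual-OR interval is the exponential of the gamma endpoints
    row = table[table.term == "z"].iloc[0]
    assert row.residual_or == pytest.approx(np.exp(row.estimate))
    assert row.residual_or_lower == pytest.approx(np.exp(row.lower))

    # zero SE -> degenerate interval at the estimate
    zero = wald_intervals(fit, np.zeros_like(cov.matrix))
    assert (zero.lower == zero.estimate).all() and (zero.upper == zero.estimate).all()


def test_interval_shape_from_known_se():
    """estimate 4.6e-5, SE 3.265e-5 -> about (-1.8, 11.0) per 100,000."""
    est, se = 4.6e-5, 3.265e-5
    zq = norm.ppf(0.975)
    lo, hi = (est - zq * se) * 1e5, (est + zq * se) * 1e5
    assert lo == pytest.approx(-1.8, abs=0.05)
    assert hi == pytest.approx(11.0, abs=0.05)


def test_linearized_se_tracks_monte_carlo_sd():
    """Gender-only design: mean linearized SE within 15% of the MC SD."""
    cfg = gender_scenario(population_scale=0.1)
    betas, ses = [], []
    for s in range(120):
        study = simulate_study(cfg, seed=40_000 + s)
        fit = fit_lexpit(study.data, cfg.spec, design=study.design)
        cov = linearized_covariance(influence_vectors(fit))
        betas.append(fit.params.beta[0])
        ses.append(cov.se[0])
    mc_sd = np.std(betas, ddof=1)
    assert np.mean(ses) == pytest.approx(mc_sd, rel=0.15)


def test_bootstrap_agrees_with_linearization():
    """Stratified bootstrap SEs within 20% of linearized SEs, elementwise."""
    rows = pd.DataFrame(
        {
            "stratum": ["a", "b"],
            "female": [0, 1],
            "population_size": [20_000, 25_000],
            "n_controls": [150, 120],
        }
    )
    spec = LexpitSpec(additive=("female",), multiplicative=("z",))
    truth = ParameterVector(beta=[0.004], gamma0=-4.6, gamma=[0.5])

    def cov_model(rng, row, n):
        return {"female": np.full(n, float(row["female"])), "z": rng.normal(0, 1, n)}

    cfg = PopulationConfig(
        strata=rows, covariate_model=cov_model, true_params=truth, spec=spec
    )
    study = simulate_study(cfg, seed=42)
    fit = fit_lexpit(study.data, spec, design=study.design)
    lin = linearized_covariance(influence_vectors(fit))
    boot = bootstrap_covariance(fit, n_reps=400, seed=7)
    assert np.all(np.abs(boot.se / lin.se - 1) < 0.2)


def test_centered_case_stratum_understates_gender_only_variance():
    """The fixed-case-count (centered) treatment captures case-mix
    variation only; for absolute-risk estimates it must not exceed the
    Poisson (random disease process) treatment."""
    cfg = gender_scenario(population_scale=0.1)
    study = simulate_study(cfg, seed=77)
    fit = fit_lexpit(study.data, cfg.spec, design=study.design)
    infl = influence_vectors(fit)
    v_pois = linearized_covariance(infl, case_strategy="poisson").se[0]
    v_cent = linearized_covariance(infl, case_strategy="centered").se[0]
    assert v_cent < v_pois


def test_single_unit_control_stratum_collapsed(caplog):
    rng = np.random.default_rng(15)
    from lexpit import CaseControlDesign, Stratum

    design = CaseControlDesign(
        strata=(
            Stratum(label="a", population_size=500, n_controls_sampled=30),
            Stratum(label="b", population_size=200, n_controls_sampled=1),
        )
    )
    n = 80
    data = pd.DataFrame(
        {
            "outcome": np.r_[np.ones(49, int), np.zeros(31, int)],
            "x": rng.binomial(1, 0.5, n).astype(float),
            "stratum": ["a"] * 79 + ["b"],
        }
    )
    fit = fit_lexpit(data, LexpitSpec(additive=("x",)), design=design)
    with caplog.at_level("WARNING", logger="lexpit.inference"):
        cov = linearized_covariance(influence_vectors(fit))
    assert any("single unit" in r.message for r in caplog.records)
    assert np.all(np.isfinite(cov.matrix))
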