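"""Constrained pseudo-likelihood maximization against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from lexpit import (
    LexpitSpec,
    ParameterVector,
    build_feasible_region,
    fit_lexpit,
    pseudo_log_likelihood,
)
from lexpit.estimation import _loglik_grad, _loglik_raw

from conftest import make_case_control_frame


# ---------------------------------------------------------------------------
# pseudo-log-likelihood


def test_loglik_matches_hand_sum_on_three_rows():
    """Weighted Bernoulli terms summed by hand for fixed parameters."""
    spec = LexpitSpec(additive=("x",))
    params = ParameterVector(beta=[0.1], gamma0=-1.0, gamma=[])
    data = pd.DataFrame(
        {"outcome": [1, 0, 1], "x": [0.0, 1.0, 1.0], "w": [1.0, 5.0, 5.0]}
    )
    r0 = math.exp(-1) / (1 + math.exp(-1))
    r1 = 0.1 + r0
    expected = 1 * math.log(r0) + 5 * math.log(1 - r1) + 5 * math.log(r1)
    got = pseudo_log_likelihood(params, spec, data, weight_col="w")
    assert got == pytest.approx(expected, rel=1e-12)


def test_loglik_at_half_risk_is_minus_n_log2():
    spec = LexpitSpec()
    params = ParameterVector(beta=[], gamma0=0.0, gamma=[])
    n = 17
    data = pd.DataFrame({"outcome": np.random.default_rng(0).binomial(1, 0.5, n)})
    assert pseudo_log_likelihood(params, spec, data) == pytest.approx(-n * math.log(2))


def test_loglik_is_minus_inf_outside_feasible_region():
    spec = LexpitSpec(additive=("x",))
    params = ParameterVector(beta=[2.0], gamma0=0.0, gamma=[])  # risk > 1 at x=1
    data = pd.DataFrame({"outcome": [1], "x": [1.0]})
    assert pseudo_log_likelihood(params, spec, data) == -np.inf


def test_analytic_gradient_matches_finite_differences():
    rng = np.random.default_rng(5)
    n = 60
    X = rng.normal(size=(n, 2)) * 0.05
    Z = rng.normal(size=(n, 1))
    y = rng.binomial(1, 0.4, n).astype(float)
    w = rng.uniform(0.5, 4.0, n)
    theta = np.array([0.01, -0.02, -0.5, 0.3])
    _, g = _loglik_grad(theta, y, X, Z, w)
    eps = 1e-6
    for k in range(theta.size):
        d = np.zeros_like(theta)
        d[k] = eps
        num = (_loglik_raw(theta + d, y, X, Z, w) - _loglik_raw(theta - d, y, X, Z, w)) / (2 * eps)
        assert g[k] == pytest.approx(num, rel=1e-5, abs=1e-7)


# ---------------------------------------------------------------------------
# feasible region


def test_feasible_region_deduplicates_patterns():
    X = np.array([[0.0], [1.0], [1.0], [0.0], [1.0]])
    Z = np.zeros((5, 0))
    region = build_feasible_region(X, Z)
    assert region.n_patterns == 2
    assert sorted(region.counts.tolist()) == [2, 3]

    # all rows identical -> a single pattern
    region1 = build_feasible_region(np.ones((7, 1)), np.zeros((7, 0)))
    assert region1.n_patterns == 1


def test_gender_only_data_has_two_patterns(gender_data, gender_design_obj, gender_spec):
    fit = fit_lexpit(gender_data, gender_spec, design=gender_design_obj)
    assert fit.feasible_region.n_patterns == 2


# ---------------------------------------------------------------------------
# fitting: oracles


def test_worked_example_estimates(gender_data, gender_design_obj, gender_spec):
    """Weighted gender-only fit: risks ~2.0 and ~0.5 per 1,000, RD ~-1.5."""
    fit = fit_lexpit(gender_data, gender_spec, design=gender_design_obj)
    assert fit.converged
    p_male = 1_537 / (1_537 + 774_221)
    p_female = 406 / (406 + 851_550)
    assert fit.params.baseline_risk == pytest.approx(p_male, rel=1e-8)
    assert fit.params.beta[0] == pytest.approx(p_female - p_male, rel=1e-8)


def test_empty_additive_matches_weighted_logistic():
    """With no additive terms the optimum is the weighted logistic MLE."""
    import statsmodels.api as sm

    rng = np.random.default_rng(11)
    n = 400
    z1 = rng.normal(size=n)
    z2 = rng.binomial(1, 0.3, n).astype(float)
    p = 1 / (1 + np.exp(1.2 - 0.7 * z1 + 0.5 * z2))
    y = (rng.random(n) < p).astype(int)
    w = rng.integers(1, 8, n).astype(float)
    data = pd.DataFrame({"outcome": y, "z1": z1, "z2": z2, "w": w})
    fit = fit_lexpit(data, LexpitSpec(multiplicative=("z1", "z2")), weight_col="w")
    oracle = sm.GLM(
        y,
        np.c_[np.ones(n), z1, z2],
        family=sm.families.Binomial(),
        freq_weights=w,
    ).fit()
    ours = np.r_[fit.params.gamma0, fit.params.gamma]
    assert np.max(np.abs(ours - oracle.params) / np.abs(oracle.params)) < 1e-6


def test_empty_multiplicative_matches_group_proportions():
    """Unit weights + binary x: beta is the difference of event proportions."""
    rng = np.random.default_rng(21)
    n = 300
    x = rng.binomial(1, 0.5, n).astype(float)
    y = (rng.random(n) < 0.2 + 0.3 * x).astype(int)
    data = pd.DataFrame({"outcome": y, "x": x})
    fit = fit_lexpit(data, LexpitSpec(additive=("x",)))
    p0 = y[x == 0].mean()
    p1 = y[x == 1].mean()
    assert fit.params.baseline_risk == pytest.approx(p0, abs=1e-8)
    assert fit.params.beta[0] == pytest.approx(p1 - p0, abs=1e-8)


def test_two_parameter_optimum_matches_grid_search():
    """Dense grid over (beta, gamma0) agrees to grid resolution."""
    rng = np.random.default_rng(31)
    n = 250
    x = rng.binomial(1, 0.4, n).astype(float)
    y = (rng.random(n) < 0.1 + 0.2 * x).astype(int)
    data = pd.DataFrame({"outcome": y, "x": x})
    fit = fit_lexpit(data, LexpitSpec(additive=("x",)))

    X = x[:, None]
    Z = np.zeros((n, 0))
    betas = np.linspace(-0.4, 0.6, 401)
    gamma0s = np.linspace(-4.0, 0.0, 401)
    best, argbest = -np.inf, None
    for b in betas:
        for g in gamma0s:
            ll = _loglik_raw(np.array([b, g]), y.astype(float), X, Z, np.ones(n))
            if ll > best:
                best, argbest = ll, (b, g)
    db = betas[1] - betas[0]
    dg = gamma0s[1] - gamma0s[0]
    assert fit.params.beta[0] == pytest.approx(argbest[0], abs=db)
    assert fit.params.gamma0 == pytest.approx(argbest[1], abs=dg)
    assert fit.loglik >= best - 1e-9


# ---------------------------------------------------------------------------
# fitting: invariances and constraints


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_monotone_improvement_and_feasibility(seed):
    rng = np.random.default_rng(seed)
    data = make_case_control_frame(rng, n=150)
    spec = LexpitSpec(additive=("x",))
    fit = fit_lexpit(data, spec)
    # likelihood at the optimum beats the feasible start (beta=0, logistic)
    ybar = data.outcome.mean()
    start = ParameterVector(beta=[0.0], gamma0=math.log(ybar / (1 - ybar)), gamma=[])
    assert fit.loglik >= pseudo_log_likelihood(start, spec, data) - 1e-9
    risks = fit.feasible_region.risks(fit.theta)
    assert np.all(risks >= -1e-8) and np.all(risks <= 1 + 1e-8)


@pytest.mark.parametrize("seed", [7, 8])
def test_weight_scaling_and_row_order_invariance(seed, small_design):
    rng = np.random.default_rng(seed)
    data = make_case_control_frame(rng, n=200)
    spec = LexpitSpec(additive=("x",))
    fit = fit_lexpit(data, spec, design=small_design)

    # multiplying all weights by c > 0 leaves the optimum unchanged
    from lexpit import compute_sampling_weights

    wdata = compute_sampling_weights(small_design, data)
    wdata["w5"] = 5.0 * wdata.weight
    fit_scaled = fit_lexpit(wdata, spec, weight_col="w5")
    assert np.allclose(fit.theta, fit_scaled.theta, atol=1e-7)

    perm = rng.permutation(len(data))
    fit_perm = fit_lexpit(data.iloc[perm].reset_index(drop=True), spec, design=small_design)
    assert np.allclose(fit.theta, fit_perm.theta, atol=1e-7)


def test_unit_weight_fit_equals_cohort_fit(small_design):
    """With all weights 1 the pseudo-likelihood is the exact likelihood."""
    rng = np.random.default_rng(13)
    data = make_case_control_frame(rng, n=180)
    spec = LexpitSpec(additive=("x",))
    cohort = fit_lexpit(data, spec)  # no design: weights 1
    explicit = fit_lexpit(data.assign(one=1.0), spec, weight_col="one")
    assert np.allclose(cohort.theta, explicit.theta, atol=1e-9)


def test_constant_covariate_raises_by_name():
    data = pd.DataFrame({"outcome": [0, 1, 0, 1], "flat": [2.0] * 4})
    with pytest.raises(ValueError, match="flat"):
        fit_lexpit(data, LexpitSpec(additive=("flat",)))


def test_all_case_or_all_control_data_rejected():
    data = pd.DataFrame({"outcome": [1, 1], "x": [0.0, 1.0]})
    with pytest.raises(ValueError, match="at least one case and one control"):
        fit_lexpit(data, LexpitSpec(additive=("x",)))


def test_active_constraint_reported_when_risk_pinned_at_one():
    """A covariate pattern whose members are all cases pins its fitted
    risk at the upper feasibility bound."""
    data = pd.DataFrame(
        {
            "outcome": np.r_[np.ones(30, int), np.ones(20, int), np.zeros(40, int)],
            "x": np.r_[np.ones(30), np.zeros(60)],
        }
    )
    fit = fit_lexpit(data, LexpitSpec(additive=("x",)))
    risks = np.clip(fit.fitted_risks, 0, 1)
    assert risks.max() >= 1 - 1e-6
    assert len(fit.active_constraints) >= 1
    assert fit.params.baseline_risk == pytest.approx(1 / 3, abs=1e-4)
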