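"""Survival probabilities and skew-normal conditional means of random effects."""

import numpy as np
import pytest
from scipy.special import ndtr
from scipy.stats import norm

from semijm.likelihood import MvnOptions
from semijm.model_core import (
    CholeskyCov,
    DiscretizationScheme,
    HazardDesign,
    JointParams,
    LongitudinalDesign,
    ModelSpec,
)
from semijm.profiles import (
    conditional_mean_b_given_alive,
    partly_conditional_profile,
    survival_prob_marginal,
    survival_terms,
)
from semijm._mvncdf import mvn_cdf
from semijm.synthetic_data import hers_like_designs, hers_like_params

ACCURATE = MvnOptions()


def _q1_spec():
    return ModelSpec(
        DiscretizationScheme(tuple(float(j) for j in range(7))),
        LongitudinalDesign(("1", "visit"), ("1",)),
        HazardDesign(("1",), ("1",)),
    )


def _q1_params(a=0.9, gamma=0.7, sig2=2.3):
    return JointParams(beta=[0.0, 0.0], alpha_D=[0.0], gamma_D=[0.0],
                       alpha_S=[a], gamma_S=[gamma], sigma2_eps=1.0,
                       cov=CholeskyCov(np.zeros((1, 1)), [sig2]))


# --------------------------------------------------------------------------
# survival probability
# --------------------------------------------------------------------------

def test_survival_prob_is_one_at_first_visit_and_nonincreasing():
    spec = hers_like_designs()
    params = hers_like_params()
    cov = {"vl_low": 1.0, "vl_mid": 0.0, "vl_high": 0.0, "symptoms": 1.0,
           "therapy": 1.0}
    probs = [survival_prob_marginal(params, spec, cov, j, options=ACCURATE)
             for j in range(1, 13)]
    assert probs[0] == 1.0
    assert np.all(np.diff(probs) <= 1e-12)


def test_survival_prob_factorizes_at_gamma_zero():
    spec = _q1_spec()
    params = _q1_params(gamma=0.0)
    for j in (2, 4, 6):
        val = survival_prob_marginal(params, spec, {}, j)
        assert val == pytest.approx(ndtr(0.9) ** (j - 1), abs=1e-12)


def test_survival_prob_matches_monte_carlo():
    spec = hers_like_designs()
    params = hers_like_params()
    cov = {"vl_low": 0.0, "vl_mid": 1.0, "vl_high": 0.0, "symptoms": 2.0,
           "therapy": 0.0}
    j = 6
    val = survival_prob_marginal(params, spec, cov, j, options=ACCURATE)
    rng = np.random.default_rng(8)
    n = 2_000_000
    b = rng.multivariate_normal(np.zeros(2), params.sigma, size=n,
                                method="cholesky")
    probs = np.ones(n)
    for k in range(1, j):
        lp = spec.hazards.x_death(cov, k, 12) @ params.alpha_S \
            + b @ params.gamma_S
        probs *= ndtr(lp)
    est, se = probs.mean(), probs.std() / np.sqrt(n)
    assert abs(val - est) < 3 * se


def test_alive_through_includes_current_visit_hazard():
    spec = _q1_spec()
    params = _q1_params()
    t_default = survival_terms(params, spec, {}, 4)
    t_through = survival_terms(params, spec, {}, 4, alive_through=True)
    assert t_default.K == 3 and t_through.K == 4


# --------------------------------------------------------------------------
# conditional mean of b given being alive
# --------------------------------------------------------------------------

def test_conditional_mean_zero_cases():
    spec = _q1_spec()
    params = _q1_params()
    assert conditional_mean_b_given_alive(params, spec, {}, 1)[0] == 0.0
    p0 = _q1_params(gamma=0.0)
    for j in (2, 5):
        assert conditional_mean_b_given_alive(p0, spec, {}, j)[0] == 0.0


def test_conditional_mean_q1_analytic_identity():
    # single survival factor Phi(a + gamma b): Stein's lemma gives
    # E(b | alive) = gamma sig2 phi(a~) / (sqrt(1 + gamma^2 sig2) Phi(a~))
    a, gamma, sig2 = 0.9, 0.7, 2.3
    spec = _q1_spec()
    params = _q1_params(a, gamma, sig2)
    got = conditional_mean_b_given_alive(params, spec, {}, 2,
                                         options=ACCURATE)[0]
    atil = a / np.sqrt(1 + gamma ** 2 * sig2)
    ref = gamma * sig2 * norm.pdf(atil) / (np.sqrt(1 + gamma ** 2 * sig2)
                                           * norm.cdf(atil))
    assert got == pytest.approx(ref, abs=1e-8)


def test_conditional_mean_matches_rejection_sampling_q2():
    spec = hers_like_designs()
    params = hers_like_params()
    cov = {"vl_low": 1.0, "vl_mid": 0.0, "vl_high": 0.0, "symptoms": 1.0,
           "therapy": 1.0}
    j = 6
    got = conditional_mean_b_given_alive(params, spec, cov, j,
                                         options=ACCURATE)
    rng = np.random.default_rng(21)
    n = 1_500_000
    b = rng.multivariate_normal(np.zeros(2), params.sigma, size=n,
                                method="cholesky")
    accept_p = np.ones(n)
    for k in range(1, j):
        lp = spec.hazards.x_death(cov, k, 12) @ params.alpha_S \
            + b @ params.gamma_S
        accept_p *= ndtr(lp)
    acc = rng.random(n) < accept_p
    ref = b[acc].mean(axis=0)
    se = b[acc].std(axis=0) / np.sqrt(acc.sum())
    assert np.all(np.abs(got - ref) < 3 * se)


def test_mvn_cdf_gradient_matches_central_differences():
    from semijm.profiles import _mvn_cdf_gradient

    rng = np.random.default_rng(4)
    K = 5
    A = rng.normal(0.4, 0.2, (K, 2))
    omega = np.eye(K) + A @ np.array([[9.0, -0.4], [-0.4, 0.5]]) @ A.T
    u = rng.normal(1.0, 0.5, K)
    val, grad = _mvn_cdf_gradient(u, omega, ACCURATE)
    step = 1e-5
    for k in range(K):
        up, dn = u.copy(), u.copy()
        up[k] += step
        dn[k] -= step
        num = (mvn_cdf(up, omega, reltol=1e-6, n_max=2 ** 14)
               - mvn_cdf(dn, omega, reltol=1e-6, n_max=2 ** 14)) / (2 * step)
        assert grad[k] == pytest.approx(num, rel=2e-3, abs=1e-5)


def test_underflow_survival_probability_is_rejected():
    spec = _q1_spec()
    params = _q1_params(a=-15.0, gamma=0.1)
    with pytest.raises(ValueError, match="underflow"):
        conditional_mean_b_given_alive(params, spec, {}, 5)


# --------------------------------------------------------------------------
# partly conditional profiles
# --------------------------------------------------------------------------

def test_profile_equals_unconditional_at_j1_and_gamma_zero():
    spec = hers_like_designs()
    params = hers_like_params()
    cov = {"vl_low": 1.0, "vl_mid": 0.0, "vl_high": 0.0, "symptoms": 1.0,
           "therapy": 1.0}
    prof = partly_conditional_profile(params, spec, cov, visits=[1, 2, 3])
    assert prof["partly_conditional"][0] == pytest.approx(
        prof["unconditional"][0], abs=1e-12)
    p0 = hers_like_params()
    p0.gamma_S = np.zeros(2)
    prof0 = partly_conditional_profile(p0, spec, cov)
    np.testing.assert_allclose(prof0["partly_conditional"],
                               prof0["unconditional"], atol=1e-12)


def test_survivor_selection_gap_nonnegative_and_nondecreasing():
    # gamma_S1 = 0, gamma_S2 > 0 with z = (1, j) and uncorrelated intercept /
    # slope: survival selects better slopes, so the mortal-cohort mean sits
    # above the unconditional one and the gap grows with j.  (A negative
    # intercept-slope covariance can produce a tiny negative gap at early
    # visits through the intercept; the uncorrelated case isolates the
    # selection effect.)
    spec = hers_like_designs()
    params = hers_like_params()
    params.gamma_S = np.array([0.0, 1.192])
    params.cov = CholeskyCov(np.zeros((2, 2)), [29.120, 0.539])
    cov = {"vl_low": 1.0, "vl_mid": 0.0, "vl_high": 0.0, "symptoms": 1.0,
           "therapy": 1.0}
    prof = partly_conditional_profile(params, spec, cov, options=ACCURATE)
    gap = (prof["partly_conditional"] - prof["unconditional"]).to_numpy()
    assert np.all(gap >= -1e-10)
    assert np.all(np.diff(gap) >= -1e-8)


def test_profile_bands_from_draws():
    spec = hers_like_designs()
    base = hers_like_params()
    rng = np.random.default_rng(0)
    draws = []
    for _ in range(8):
        p = hers_like_params()
        p.beta = base.beta + rng.normal(0, 0.05, base.beta.size)
        draws.append(p)
    cov = {"vl_low": 1.0, "vl_mid": 0.0, "vl_high": 0.0, "symptoms": 1.0,
           "therapy": 1.0}
    prof = partly_conditional_profile(draws, spec, cov, visits=[1, 4])
    assert {"pc_lower", "pc_upper"} <= set(prof.columns)
    assert np.all(prof["pc_lower"] <= prof["pc_upper"])
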