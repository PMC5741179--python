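"""Likelihood factors, the orthant-probability reduction, and its oracles."""

import numpy as np
import pytest

from semijm.likelihood import (
    MvnOptions,
    ProbitTermSet,
    build_orthant_problem,
    collect_probit_terms,
    death_loglik_given_b,
    dropout_loglik_given_b,
    expectation_probit_product,
    longitudinal_loglik_given_b,
    marginal_loglik_dataset,
    marginal_loglik_patient,
)
from semijm.model_core import (
    CholeskyCov,
    Dataset,
    JointParams,
    PatientRecord,
    recover_cholesky,
)
from semijm.synthetic_data import SimConfig, simulate_dataset
from tests.conftest import (
    enumerate_event_outcomes,
    gh_marginal_loglik,
    mc_probit_expectation,
    small_params,
    small_spec,
)

ACCURATE = MvnOptions()


# --------------------------------------------------------------------------
# complete-data factors given b
# --------------------------------------------------------------------------

def _one_patient_dataset(record, spec):
    return Dataset([record], spec)


def test_longitudinal_loglik_trivial_values():
    spec = small_spec(M=3, q=1)
    params = small_params(q=1)
    params.sigma2_eps = 1.0
    # a single observation exactly at its mean: -log(2 pi)/2
    rec = PatientRecord(0, [1], [params.beta[0] + params.beta[1]],
                        D_star=3, delta_D=0, S_star=3, delta_S=0)
    ds = _one_patient_dataset(rec, spec)
    assert longitudinal_loglik_given_b(rec, params, [0.0], ds) == \
        pytest.approx(-0.5 * np.log(2 * np.pi))
    empty = PatientRecord(1, [], [], D_star=1, delta_D=0, S_star=1, delta_S=1)
    ds2 = _one_patient_dataset(empty, spec)
    assert longitudinal_loglik_given_b(empty, params, [0.0], ds2) == 0.0


def test_longitudinal_loglik_matches_mvn_density():
    spec = small_spec(M=3, q=1)
    params = small_params(q=1)
    rng = np.random.default_rng(5)
    rec = PatientRecord(0, [1, 3], rng.normal(9, 2, 2), D_star=3, delta_D=1,
                        S_star=3, delta_S=0)
    ds = _one_patient_dataset(rec, spec)
    b = np.array([0.7])
    from scipy.stats import multivariate_normal
    dm = ds.design(rec)
    idx = rec.observed_visits - 1
    mu = dm["X"][idx] @ params.beta + dm["Z"][idx] @ b
    ref = multivariate_normal.logpdf(rec.y_obs, mu,
                                     params.sigma2_eps * np.eye(2))
    assert longitudinal_loglik_given_b(rec, params, b, ds) == \
        pytest.approx(ref, abs=1e-12)


def test_event_loglik_trivial_values():
    spec = small_spec(M=3, q=1)
    # linear predictors exactly zero
    params = small_params(q=1, gamma_D=0.0, gamma_S=0.0)
    params.alpha_D = np.array([0.0])
    rec = PatientRecord(0, [1], [10.0], D_star=1, delta_D=0, S_star=2,
                        delta_S=0)
    ds = _one_patient_dataset(rec, spec)
    assert dropout_loglik_given_b(rec, params, [0.0], ds) == \
        pytest.approx(np.log(0.5))
    rec2 = PatientRecord(1, [1], [10.0], D_star=2, delta_D=1, S_star=2,
                         delta_S=0)
    ds2 = _one_patient_dataset(rec2, spec)
    assert dropout_loglik_given_b(rec2, params, [0.0], ds2) == \
        pytest.approx(np.log(0.25))


def test_event_loglik_sums_to_one_over_outcomes():
    # brute-force enumeration over the semicompeting outcome space at fixed b
    spec = small_spec(M=3, q=1)
    params = small_params(q=1)
    b = np.array([1.3])
    total = 0.0
    for d, dD, s, dS in enumerate_event_outcomes(3):
        rec = PatientRecord(0, [], [], D_star=d, delta_D=dD, S_star=s,
                            delta_S=dS)
        ds = _one_patient_dataset(rec, spec)
        total += np.exp(dropout_loglik_given_b(rec, params, b, ds)
                        + death_loglik_given_b(rec, params, b, ds))
    assert total == pytest.approx(1.0, abs=1e-12)


# --------------------------------------------------------------------------
# probit term collection
# --------------------------------------------------------------------------

def test_collect_terms_structure():
    spec = small_spec(M=3, q=1)
    params = small_params(q=1)
    # completer: all signs +1, K = 2M
    rec = PatientRecord(0, [1], [10.0], D_star=3, delta_D=0, S_star=3,
                        delta_S=0)
    terms = collect_probit_terms(rec, params, _one_patient_dataset(rec, spec))
    assert terms.K == 6 and np.all(terms.signs == 1.0)
    # dropout at 2 then death at 3: terminal signs flip
    rec2 = PatientRecord(1, [1], [10.0], D_star=2, delta_D=1, S_star=3,
                         delta_S=1)
    terms2 = collect_probit_terms(rec2, params,
                                  _one_patient_dataset(rec2, spec))
    assert terms2.K == 5
    np.testing.assert_array_equal(terms2.signs, [1, -1, 1, 1, -1])


def test_terms_reproduce_event_likelihood_at_random_b(q2_dataset):
    ds, cfg, _ = q2_dataset
    rng = np.random.default_rng(0)
    for p in ds.patients[:5]:
        terms = collect_probit_terms(p, cfg.params, ds)
        assert terms.K == p.D_star + p.S_star
        for _ in range(20):
            b = rng.normal(0, 3, 2)
            lhs = terms.log_product_at(b)
            rhs = (dropout_loglik_given_b(p, cfg.params, b, ds)
                   + death_loglik_given_b(p, cfg.params, b, ds))
            assert lhs == pytest.approx(rhs, abs=1e-11)


# --------------------------------------------------------------------------
# orthant reduction
# --------------------------------------------------------------------------

def test_expectation_trivial_and_scalar_identity():
    # K=1, a=0, c=0: plain Phi(0)
    t = ProbitTermSet(np.array([1.0]), np.array([0.0]), np.zeros((1, 1)))
    assert expectation_probit_product(t, [0.0], [[4.0]]) == pytest.approx(0.5)
    # K=1 general: Phi(s(a + c mu) / sqrt(1 + c'Sigma c)) exactly
    t = ProbitTermSet(np.array([-1.0]), np.array([0.8]), np.array([[0.6]]))
    mu, sig = np.array([0.3]), np.array([[2.5]])
    from scipy.stats import norm
    ref = norm.cdf(-1.0 * (0.8 + 0.6 * 0.3) / np.sqrt(1 + 0.36 * 2.5))
    assert expectation_probit_product(t, mu, sig) == pytest.approx(ref,
                                                                   abs=1e-10)


def test_expectation_matches_mc_oracle_k6():
    rng = np.random.default_rng(11)
    sigma = np.array([[9.0, -0.5], [-0.5, 0.5]])
    terms = ProbitTermSet(
        signs=rng.choice([-1.0, 1.0], 6),
        offsets=rng.normal(1.0, 0.8, 6),
        coefs=rng.normal(0.3, 0.3, (6, 2)),
    )
    mu = rng.normal(0, 0.5, 2)
    val = expectation_probit_product(terms, mu, sigma, ACCURATE)
    est, se = mc_probit_expectation(terms, mu, sigma, n=2_000_000, seed=4)
    assert abs(val - est) < 3 * se


def test_expectation_monotone_in_offsets():
    rng = np.random.default_rng(2)
    sigma = np.array([[4.0, 0.2], [0.2, 0.5]])
    terms = ProbitTermSet(
        signs=np.ones(5),
        offsets=rng.normal(0.5, 0.5, 5),
        coefs=rng.normal(0.2, 0.2, (5, 2)),
    )
    base = expectation_probit_product(terms, np.zeros(2), sigma, ACCURATE)
    for k in range(5):
        bumped = ProbitTermSet(terms.signs, terms.offsets.copy(), terms.coefs)
        bumped.offsets[k] += 0.5
        val = expectation_probit_product(bumped, np.zeros(2), sigma, ACCURATE)
        assert val >= base - 1e-6


# --------------------------------------------------------------------------
# marginal likelihood
# --------------------------------------------------------------------------

def test_marginal_loglik_factorizes_at_gamma_zero(small_dataset):
    ds, cfg, _ = small_dataset
    params = small_params(q=1, gamma_D=0.0, gamma_S=0.0)
    from semijm.likelihood import _gaussian_marginal_loglik
    for p in ds.patients[:10]:
        joint = marginal_loglik_patient(p, params, ds)
        split = (_gaussian_marginal_loglik(p, params, ds)
                 + dropout_loglik_given_b(p, params, np.zeros(1), ds)
                 + death_loglik_given_b(p, params, np.zeros(1), ds))
        assert joint == pytest.approx(split, abs=1e-10)


def test_marginal_loglik_matches_gh_oracle(q2_dataset):
    ds, cfg, _ = q2_dataset
    for p in ds.patients[:12]:
        mine = marginal_loglik_patient(p, cfg.params, ds, ACCURATE)
        oracle = gh_marginal_loglik(p, cfg.params, ds)
        assert mine == pytest.approx(oracle, rel=1e-4)


def test_marginal_loglik_invariant_to_cov_parameterization(q2_dataset):
    ds, cfg, _ = q2_dataset
    sigma = cfg.params.cov.sigma
    params2 = JointParams(
        beta=cfg.params.beta, alpha_D=cfg.params.alpha_D,
        gamma_D=cfg.params.gamma_D, alpha_S=cfg.params.alpha_S,
        gamma_S=cfg.params.gamma_S, sigma2_eps=cfg.params.sigma2_eps,
        cov=recover_cholesky(sigma),
    )
    p = ds.patients[0]
    a = marginal_loglik_patient(p, cfg.params, ds, ACCURATE)
    b = marginal_loglik_patient(p, params2, ds, ACCURATE)
    assert a == pytest.approx(b, abs=1e-10)


def test_dataset_loglik_sums_and_is_order_invariant(q2_dataset):
    ds, cfg, _ = q2_dataset
    total, per = marginal_loglik_dataset(ds, cfg.params, ACCURATE,
                                         per_patient=True)
    ref = np.array([marginal_loglik_patient(p, cfg.params, ds, ACCURATE)
                    for p in ds])
    np.testing.assert_allclose(per, ref, atol=1e-10)
    assert total == pytest.approx(ref.sum(), abs=1e-10)
    # permutation invariance
    perm = list(reversed(ds.patients))
    ds_perm = Dataset(perm, ds.spec)
    total_perm = marginal_loglik_dataset(ds_perm, cfg.params, ACCURATE)
    assert total_perm == pytest.approx(total, abs=1e-10)
    # single-patient dataset equals the patient value
    ds1 = Dataset([ds.patients[3]], ds.spec)
    assert marginal_loglik_dataset(ds1, cfg.params, ACCURATE) == \
        pytest.approx(ref[3], abs=1e-12)


def test_batched_evaluation_close_to_reference(q2_dataset):
    ds, cfg, _ = q2_dataset
    accurate = marginal_loglik_dataset(ds, cfg.params, ACCURATE)
    batched = marginal_loglik_dataset(ds, cfg.params, MvnOptions.batched())
    assert batched == pytest.approx(accurate, abs=0.05)


def test_marginal_loglik_rejects_bad_dimensions(small_dataset):
    ds, cfg, _ = small_dataset
    bad = small_params(q=1)
    bad.beta = np.array([1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        marginal_loglik_dataset(ds, bad)
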