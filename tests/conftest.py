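"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import ndtr

from semijm.likelihood import (
    _gaussian_marginal_loglik,
    _posterior_b_moments,
    collect_probit_terms,
)
from semijm.model_core import (
    CholeskyCov,
    Dataset,
    DiscretizationScheme,
    HazardDesign,
    JointParams,
    LongitudinalDesign,
    ModelSpec,
)
from semijm.synthetic_data import SimConfig, simulate_dataset


# --------------------------------------------------------------------------
# small model specifications
# --------------------------------------------------------------------------

def small_spec(M: int = 3, q: int = 1) -> ModelSpec:
    """Intercept(+slope) model with intercept-only hazards."""
    random = ("1",) if q == 1 else ("1", "visit")
    return ModelSpec(
        scheme=DiscretizationScheme(tuple(float(j) for j in range(M + 1))),
        longitudinal=LongitudinalDesign(fixed=("1", "visit"), random=random),
        hazards=HazardDesign(dropout=("1",), death=("1",)),
    )


def small_params(q: int = 1, gamma_D=0.3, gamma_S=0.4) -> JointParams:
    if q == 1:
        cov = CholeskyCov(np.zeros((1, 1)), [4.0])
        gD, gS = [gamma_D], [gamma_S]
    else:
        cov = CholeskyCov(np.array([[0.0, 0.0], [-0.04, 0.0]]), [9.0, 0.5])
        gD, gS = [gamma_D, 0.2], [gamma_S, 0.5]
    return JointParams(
        beta=[10.0, -0.5], alpha_D=[1.2], gamma_D=gD, alpha_S=[2.0],
        gamma_S=gS, sigma2_eps=2.0, cov=cov,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """100 patients, M=3, q=1, informative dropout and death."""
    spec = small_spec(M=3, q=1)
    params = small_params(q=1)
    cfg = SimConfig(n_patients=100, spec=spec, params=params,
                    covariate_sampler=lambda rng: {}, p_intermittent=0.05,
                    seed=42)
    ds, truth = simulate_dataset(cfg)
    return ds, cfg, truth


@pytest.fixture(scope="session")
def q2_dataset():
    """60 patients, M=4, q=2 random intercept + slope."""
    spec = small_spec(M=4, q=2)
    params = small_params(q=2)
    cfg = SimConfig(n_patients=60, spec=spec, params=params,
                    covariate_sampler=lambda rng: {}, p_intermittent=0.05,
                    seed=7)
    ds, truth = simulate_dataset(cfg)
    return ds, cfg, truth


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def gh_marginal_loglik(patient, params, dataset, n_nodes: int = 33) -> float:
    """Adaptive Gauss-Hermite oracle for the patient marginal log-likelihood:
    tensor-product Hermite quadrature on the posterior-standardized scale of
    the random effects, entirely independent of the orthant-probability
    reduction under test."""
    mu, cov = _posterior_b_moments(patient, params, dataset)
    terms = collect_probit_terms(patient, params, dataset)
    L = np.linalg.cholesky(cov)
    x, w = hermegauss(n_nodes)
    qdim = mu.size
    grids = np.meshgrid(*([x] * qdim), indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    wgrids = np.meshgrid(*([w] * qdim), indexing="ij")
    ws = np.prod(np.stack([g.ravel() for g in wgrids], axis=1), axis=1)
    b = mu + pts @ L.T
    args = terms.signs * (terms.offsets + b @ terms.coefs.T)
    vals = np.prod(ndtr(args), axis=1)
    expectation = float((ws * vals).sum() / np.sqrt(2.0 * np.pi) ** qdim)
    return _gaussian_marginal_loglik(patient, params, dataset) + np.log(expectation)


def mc_probit_expectation(terms, mean, cov, n: int, seed: int = 0,
                          chunk: int = 1_000_000):
    """Plain Monte-Carlo oracle for E[prod Phi(s(a + c'b))], b ~ N(mean, cov).
    Returns (estimate, standard error)."""
    rng = np.random.default_rng(seed)
    mean = np.asarray(mean, float)
    L = np.linalg.cholesky(np.asarray(cov, float))
    total, total_sq, done = 0.0, 0.0, 0
    while done < n:
        m = min(chunk, n - done)
        b = mean + rng.standard_normal((m, mean.size)) @ L.T
        vals = np.prod(ndtr(terms.signs * (terms.offsets + b @ terms.coefs.T)),
                       axis=1)
        total += vals.sum()
        total_sq += (vals ** 2).sum()
        done += m
    est = total / n
    se = np.sqrt(max(total_sq / n - est ** 2, 0.0) / n)
    return est, se


def enumerate_event_outcomes(M: int):
    """All observable (D*, delta_D, S*, delta_S) outcomes when C = M:
    both events observed (d <= s), dropout then administrative censoring of
    death, death before dropout, and neither event."""
    outcomes = []
    for s in range(1, M + 1):
        for d in range(1, s + 1):
            outcomes.append((d, 1, s, 1))
    for d in range(1, M + 1):
        outcomes.append((d, 1, M, 0))
    for s in range(1, M + 1):
        outcomes.append((s, 0, s, 1))
    outcomes.append((M, 0, M, 0))
    return outcomes
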