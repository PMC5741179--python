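"""Unconditional and partly-conditional (mortal-cohort) mean profiles.

The unconditional profile ``E(Y_ij | x) = x_ij' beta`` describes an immortal
cohort — it implicitly extrapolates the outcome beyond death.  The partly
conditional profile targets the dynamic cohort of survivors,

    E(Y_ij | S_i >= j, x, z) = x_ij' beta + z_ij' E(b_i | S_i >= j, x),

and is available in closed form because b conditional on survival follows a
multivariate skew-normal law: its density is proportional to
``phi(b; 0, Sigma) * prod_{k} Phi(a_k + c_k' b)`` with one survival factor per
survived hazard.  By Stein's lemma the conditional mean is

    E(b | S >= j) = Sigma A' grad_u log Phi_K(u; I + A Sigma A'),

with u_k = a_k (the hazard covariate part), A row k = c_k', and each partial
derivative of the MVN CDF reducing to a normal density times a conditional
(K-1)-dimensional MVN CDF.

"Alive at visit j" is encoded by default as having survived the hazards of
visits 1..j-1 (so S >= 1 is vacuous); set ``alive_through=True`` to also
include visit j's own hazard term.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtr

from ._mvncdf import mvn_cdf
from .likelihood import (
    MvnOptions,
    ProbitTermSet,
    build_orthant_problem,
    expectation_probit_product,
)
from .model_core import JointParams, ModelSpec

__all__ = [
    "survival_terms",
    "survival_prob_marginal",
    "conditional_mean_b_given_alive",
    "partly_conditional_profile",
]

_DEFAULT_MVN = MvnOptions()


def survival_terms(
    params: JointParams, spec: ModelSpec, covariates: dict, j: int,
    alive_through: bool = False,
) -> ProbitTermSet:
    """Probit survival factors implied by being alive at visit j."""
    last = j if alive_through else j - 1
    M = spec.M
    h = spec.hazards
    W = h.W_S(spec.q)
    offs = np.array([h.x_death(covariates, k, M) @ params.alpha_S
                     for k in range(1, last + 1)])
    coefs = np.array([params.gamma_S_at(k) @ W for k in range(1, last + 1)])
    return ProbitTermSet(
        signs=np.ones(last),
        offsets=offs.reshape(last),
        coefs=coefs.reshape(last, spec.q),
    )


def survival_prob_marginal(
    params: JointParams, spec: ModelSpec, covariates: dict, j: int,
    alive_through: bool = False, options: MvnOptions = _DEFAULT_MVN,
) -> float:
    """P(S >= j | x): the (j-1)-dimensional MVN CDF with limits at the hazard
    covariate parts and covariance I + A Sigma A'.  j = 1 gives 1."""
    if not 1 <= j <= spec.M + (0 if alive_through else 1):
        raise ValueError(f"visit j={j} outside 1..M")
    terms = survival_terms(params, spec, covariates, j, alive_through)
    if terms.K == 0:
        return 1.0
    return expectation_probit_product(terms, np.zeros(spec.q), params.sigma, options)


def _mvn_cdf_gradient(u: np.ndarray, omega: np.ndarray,
                      options: MvnOptions) -> tuple[float, np.ndarray]:
    """(Phi_K(u; omega), dPhi_K/du): each partial is the marginal normal
    density at u_k times the conditional (K-1)-dim CDF given W_k = u_k."""
    K = u.size
    if K == 0:
        return 1.0, np.zeros(0)
    value = mvn_cdf(u, omega, abstol=options.abstol, reltol=options.reltol,
                    n_max=options.n_max)
    grad = np.empty(K)
    for k in range(K):
        vkk = omega[k, k]
        dens = np.exp(-0.5 * u[k] ** 2 / vkk) / np.sqrt(2.0 * np.pi * vkk)
        if K == 1:
            grad[k] = dens
            continue
        rest = np.delete(np.arange(K), k)
        cond_mean = omega[rest, k] * (u[k] / vkk)
        cond_cov = omega[np.ix_(rest, rest)] - np.outer(
            omega[rest, k], omega[k, rest]) / vkk
        grad[k] = dens * mvn_cdf(
            u[rest] - cond_mean, cond_cov,
            abstol=options.abstol, reltol=options.reltol, n_max=options.n_max,
        )
    return value, grad


def conditional_mean_b_given_alive(
    params: JointParams, spec: ModelSpec, covariates: dict, j: int,
    alive_through: bool = False, options: MvnOptions = _DEFAULT_MVN,
) -> np.ndarray:
    """E(b | S >= j, x): mean of the skew-normal conditional law of the random
    effects given survival; the zero vector at j = 1 (or when gamma_S = 0)."""
    terms = survival_terms(params, spec, covariates, j, alive_through)
    sigma = params.sigma
    q = spec.q
    if terms.K == 0 or not np.any(terms.coefs):
        return np.zeros(q)
    prob = build_orthant_problem(terms, np.zeros(q), sigma)
    value, grad = _mvn_cdf_gradient(prob.upper, prob.cov, options)
    if value < 1e-13:
        raise ValueError(
            f"survival probability underflow at visit {j} (P < 1e-13); "
            "conditional mean is not computable"
        )
    A = terms.signs[:, None] * terms.coefs
    return sigma @ A.T @ (grad / value)


def partly_conditional_profile(
    params_or_draws, spec: ModelSpec, covariates: dict,
    visits=None, alive_through: bool = False,
    options: MvnOptions = _DEFAULT_MVN,
) -> pd.DataFrame:
    """Profile grid for one covariate pattern.

    ``params_or_draws`` is a single :class:`JointParams` (point curves) or a
    sequence of them (posterior draws: the returned frame adds the 2.5% and
    97.5% bands of the partly conditional mean over draws).  Columns:
    ``visit``, ``unconditional``, ``partly_conditional`` (+ bands).
    """
    if visits is None:
        visits = range(1, spec.M + 1)
    visits = list(visits)
    single = isinstance(params_or_draws, JointParams)
    draws = [params_or_draws] if single else list(params_or_draws)

    uncond = np.empty((len(draws), len(visits)))
    cond = np.empty_like(uncond)
    for i, params in enumerate(draws):
        for jj, j in enumerate(visits):
            x = spec.longitudinal.x(covariates, j, spec.M)
            z = spec.longitudinal.z(covariates, j, spec.M)
            mean_b = conditional_mean_b_given_alive(
                params, spec, covariates, j, alive_through, options)
            uncond[i, jj] = x @ params.beta
            cond[i, jj] = x @ params.beta + z @ mean_b
    out = pd.DataFrame({
        "visit": visits,
        "unconditional": uncond.mean(axis=0),
        "partly_conditional": cond.mean(axis=0),
    })
    if not single:
        out["pc_lower"] = np.quantile(cond, 0.025, axis=0)
        out["pc_upper"] = np.quantile(cond, 0.975, axis=0)
    return out
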