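"""Maximum-likelihood estimation of the joint model with profile-likelihood CIs.

The closed-form marginal likelihood (see :mod:`semijm.likelihood`) is
maximized over an unconstrained parameterization: raw regression and
association coefficients, log innovation variances, raw generalized
autoregressive parameters, and log sigma2_eps.  The default optimizer is
Nelder–Mead with one restart from the incumbent; because the internal MVN CDF
uses fixed quasi-Monte-Carlo points, the objective is deterministic and the
fit is reproducible.

Standard errors come from a central-difference Hessian of the log-likelihood;
they are flagged unreliable when the MVN integration tolerance is within an
order of magnitude of the curvature differences (the documented failure mode
of Monte-Carlo-noisy likelihoods).  Interval estimation therefore prefers the
profile-likelihood route: the profile is evaluated on a grid, smoothed by a
quadratic least-squares fit, and inverted through the likelihood-ratio 95%
cutoff (drop of 1.92).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .likelihood import MvnOptions, marginal_loglik_dataset
from .model_core import CholeskyCov, Dataset, JointParams

__all__ = [
    "MLEResult",
    "ProfileCI",
    "fit_mle",
    "profile_ci",
    "fit_lmm_ignorable",
    "pack_params",
    "unpack_params",
    "param_names",
]

_CHI2_95_HALF = 3.841458820694124 / 2.0  # LRT cutoff for one parameter


# --------------------------------------------------------------------------
# unconstrained packing
# --------------------------------------------------------------------------

def _dims(dataset: Dataset) -> dict:
    spec = dataset.spec
    q = spec.q
    return {
        "p": spec.longitudinal.p,
        "pD": spec.hazards.p_dropout,
        "pS": spec.hazards.p_death,
        "qD": spec.hazards.W_D(q).shape[0],
        "qS": spec.hazards.W_S(q).shape[0],
        "q": q,
    }


def pack_params(params: JointParams) -> np.ndarray:
    """theta -> unconstrained vector (variances on the log scale)."""
    q = params.cov.q
    tril = params.cov.lam[np.tril_indices(q, -1)]
    return np.concatenate([
        params.beta, params.alpha_D, np.ravel(params.gamma_D),
        params.alpha_S, np.ravel(params.gamma_S),
        [np.log(params.sigma2_eps)],
        tril, np.log(params.cov.innovation_vars),
    ])


def unpack_params(x: np.ndarray, dims: dict) -> JointParams:
    p, pD, pS, qD, qS, q = (dims[k] for k in ("p", "pD", "pS", "qD", "qS", "q"))
    pos = 0

    def take(n):
        nonlocal pos
        out = x[pos:pos + n]
        pos += n
        return out

    beta = take(p)
    alpha_D = take(pD)
    gamma_D = take(qD)
    alpha_S = take(pS)
    gamma_S = take(qS)
    sigma2_eps = float(np.exp(take(1)[0]))
    lam = np.zeros((q, q))
    lam[np.tril_indices(q, -1)] = take(q * (q - 1) // 2)
    ivar = np.exp(take(q))
    return JointParams(
        beta=beta, alpha_D=alpha_D, gamma_D=gamma_D, alpha_S=alpha_S,
        gamma_S=gamma_S, sigma2_eps=sigma2_eps,
        cov=CholeskyCov(lam=lam, innovation_vars=ivar),
    )


def param_names(dims: dict) -> list:
    names = []
    names += [f"beta[{k}]" for k in range(dims["p"])]
    names += [f"alpha_D[{k}]" for k in range(dims["pD"])]
    names += [f"gamma_D[{k}]" for k in range(dims["qD"])]
    names += [f"alpha_S[{k}]" for k in range(dims["pS"])]
    names += [f"gamma_S[{k}]" for k in range(dims["qS"])]
    names += ["log_sigma2_eps"]
    q = dims["q"]
    names += [f"lambda[{k},{l}]" for k in range(q) for l in range(k)]
    names += [f"log_innovation_var[{k}]" for k in range(q)]
    return names


# --------------------------------------------------------------------------
# ML fit
# --------------------------------------------------------------------------

@dataclass
class MLEResult:
    params: JointParams
    x: np.ndarray
    loglik: float
    n_iter: int
    n_eval: int
    converged: bool
    history: list = field(default_factory=list)
    se: np.ndarray | None = None
    se_reliable: bool | None = None
    dims: dict | None = None

    def names(self) -> list:
        return param_names(self.dims)


def _objective(dataset: Dataset, dims: dict, options: MvnOptions, history: list,
               free_idx=None, x_full=None):
    def negloglik(x):
        if free_idx is not None:
            xf = x_full.copy()
            xf[free_idx] = x
        else:
            xf = x
        try:
            ll = marginal_loglik_dataset(dataset, unpack_params(xf, dims), options)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        history.append(ll)
        return -ll

    return negloglik


def fit_mle(
    dataset: Dataset,
    init: JointParams,
    options: dict | None = None,
) -> MLEResult:
    """Maximize the marginal log-likelihood from ``init``.

    ``options``: ``maxiter`` (default 2000), ``tol`` (1e-5 on the
    log-likelihood), ``restarts`` (default 1 extra Nelder–Mead run from the
    incumbent), ``mvn`` (an :class:`MvnOptions`; the fast profile by
    default), ``compute_se`` (default False), ``method`` ("nelder-mead" or
    any scipy gradient method).
    """
    opts = {"maxiter": 2000, "tol": 1e-5, "restarts": 1,
            "mvn": MvnOptions.batched(), "compute_se": False,
            "method": "nelder-mead", "free_idx": None}
    opts.update(options or {})
    dims = _dims(dataset)
    history: list = []
    x_init = pack_params(init)
    free_idx = opts["free_idx"]
    if free_idx is not None:
        free_idx = np.asarray(free_idx, int)
        f = _objective(dataset, dims, opts["mvn"], history, free_idx,
                       x_init.copy())
        x0 = x_init[free_idx]
    else:
        f = _objective(dataset, dims, opts["mvn"], history)
        x0 = x_init
    if not np.isfinite(-f(x0)) or f(x0) >= 1e12:
        raise ValueError(
            "log-likelihood is not finite at the initial value; "
            "use a method-of-moments LMM start"
        )
    best = None
    n_eval = 0
    n_iter = 0
    for _ in range(1 + int(opts["restarts"])):
        if opts["method"] == "nelder-mead":
            res = minimize(
                f, x0, method="Nelder-Mead",
                options={"maxiter": opts["maxiter"], "fatol": opts["tol"],
                         "xatol": 1e-6},
            )
        else:
            res = minimize(f, x0, method=opts["method"],
                           options={"maxiter": opts["maxiter"]})
        n_eval += res.nfev
        n_iter += getattr(res, "nit", res.nfev)
        if best is None or res.fun < best.fun:
            best = res
        x0 = best.x
    if free_idx is not None:
        x_best = x_init.copy()
        x_best[free_idx] = best.x
    else:
        x_best = best.x
    params = unpack_params(x_best, dims)
    result = MLEResult(
        params=params, x=x_best, loglik=-best.fun, n_iter=n_iter,
        n_eval=n_eval, converged=bool(best.success), history=history,
        dims=dims,
    )
    if opts["compute_se"]:
        se, reliable = _hessian_se(f, best.x, opts["mvn"])
        if free_idx is not None:
            full_se = np.full(x_best.size, np.nan)
            full_se[free_idx] = se
            se = full_se
        result.se, result.se_reliable = se, reliable
    return result


def _hessian_se(f, x: np.ndarray, mvn: MvnOptions, step: float = 1e-3):
    """Central-difference Hessian of the negative log-likelihood; SEs from its
    inverse.  Flagged unreliable when the integration tolerance is within an
    order of magnitude of the curvature differences."""
    n = x.size
    H = np.empty((n, n))
    f0 = f(x)
    diffs = []
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = step
            ej = np.zeros(n); ej[j] = step
            if i == j:
                d2 = f(x + ei) - 2 * f0 + f(x - ei)
            else:
                d2 = (f(x + ei + ej) - f(x + ei - ej)
                      - f(x - ei + ej) + f(x - ei - ej)) / 4.0
            H[i, j] = H[j, i] = d2 / step ** 2
            diffs.append(abs(d2))
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(n, np.nan), False
    curvature_scale = np.median([d for d in diffs if d > 0] or [0.0])
    reliable = bool(curvature_scale > 10.0 * mvn.reltol) and np.all(np.diag(H) > 0)
    return se, reliable


# --------------------------------------------------------------------------
# profile likelihood
# --------------------------------------------------------------------------

@dataclass
class ProfileCI:
    estimate: float
    lower: float
    upper: float
    grid: np.ndarray
    profile: np.ndarray
    quad_coefs: np.ndarray
    warned: bool = False


def profile_ci(
    dataset: Dataset,
    mle: MLEResult,
    param_index: int,
    grid_size: int = 10,
    half_width: float | None = None,
    options: dict | None = None,
) -> ProfileCI:
    """Profile-likelihood point estimate and 95% CI for one raw parameter.

    The profile log-likelihood is evaluated on ``grid_size`` points around the
    MLE (re-optimizing all other parameters, warm-started), smoothed by a
    quadratic least-squares fit, and inverted at the LRT drop of 1.92.  If the
    smoothed profile is non-concave the grid is widened once with a warning.
    """
    opts = {"maxiter": 400, "tol": 1e-6, "mvn": MvnOptions.batched(),
            "free_idx": None}
    opts.update(options or {})
    dims = mle.dims or _dims(dataset)
    x_hat = mle.x.copy()
    if half_width is None:
        if mle.se is not None and np.isfinite(mle.se[param_index]) \
                and mle.se[param_index] > 0:
            half_width = 2.0 * float(mle.se[param_index])
        else:
            half_width = max(0.5 * abs(x_hat[param_index]), 0.25)

    allowed = (set(int(i) for i in opts["free_idx"])
               if opts["free_idx"] is not None else set(range(x_hat.size)))
    free_idx = np.array(
        [i for i in range(x_hat.size) if i != param_index and i in allowed],
        dtype=int,
    )

    def profile_at(value: float, warm: np.ndarray) -> tuple[float, np.ndarray]:
        x_full = x_hat.copy()
        x_full[param_index] = value
        x_full[free_idx] = warm
        if free_idx.size == 0:
            f = _objective(dataset, dims, opts["mvn"], [])
            return -f(x_full), warm
        f = _objective(dataset, dims, opts["mvn"], [], free_idx, x_full)
        res = minimize(f, x_full[free_idx], method="Nelder-Mead",
                       options={"maxiter": opts["maxiter"], "fatol": opts["tol"]})
        return -res.fun, res.x

    warned = False
    for attempt in range(2):
        grid = x_hat[param_index] + np.linspace(-half_width, half_width, grid_size)
        prof = np.empty(grid_size)
        warm = x_hat[free_idx]
        center_first = np.argsort(np.abs(grid - x_hat[param_index]))
        warms = {}
        for g in center_first:
            prof[g], w = profile_at(grid[g], warm)
            warms[g] = w
            warm = w
        coefs = np.polyfit(grid, prof, 2)
        if coefs[0] < 0:
            break
        warned = True
        warnings.warn(
            "profile log-likelihood non-concave on grid; widening", UserWarning
        )
        half_width *= 2.5
    a, b, c = coefs
    if a >= 0:
        # still non-concave: fall back to the raw argmax and an interval from
        # the grid extremes
        est = float(grid[np.argmax(prof)])
        return ProfileCI(est, float(grid[0]), float(grid[-1]), grid, prof,
                         coefs, warned=True)
    est = -b / (2.0 * a)
    delta = np.sqrt(_CHI2_95_HALF / (-a))
    return ProfileCI(float(est), float(est - delta), float(est + delta),
                     grid, prof, coefs, warned)


# --------------------------------------------------------------------------
# ignorable-missingness LMM baseline
# --------------------------------------------------------------------------

def fit_lmm_ignorable(
    dataset: Dataset, init: JointParams, options: dict | None = None
) -> MLEResult:
    """Fit the longitudinal submodel alone, treating dropout and death as
    ignorable: identical to the joint fit with the gammas frozen at zero,
    where the event factors separate from (beta, sigma2_eps, Sigma) and are
    dropped.  Returned hazard coefficients are placeholders (zeros)."""
    opts = {"maxiter": 2000, "tol": 1e-6, "restarts": 1,
            "mvn": MvnOptions.batched()}
    opts.update(options or {})
    dims = _dims(dataset)
    history: list = []
    # indices of the longitudinal parameters in the packed vector
    p = dims["p"]
    n_haz = dims["pD"] + dims["qD"] + dims["pS"] + dims["qS"]
    q = dims["q"]
    long_idx = np.concatenate([
        np.arange(p),
        np.arange(p + n_haz, p + n_haz + 1 + q * (q - 1) // 2 + q),
    ])
    x_full = pack_params(init)
    x_full[p:p + n_haz] = 0.0  # gammas (and hazard coefficients) frozen at 0

    from .likelihood import _gaussian_marginal_loglik

    def negloglik(x):
        xf = x_full.copy()
        xf[long_idx] = x
        try:
            params = unpack_params(xf, dims)
            ll = sum(_gaussian_marginal_loglik(pt, params, dataset)
                     for pt in dataset)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        history.append(ll)
        return -ll

    x0 = x_full[long_idx]
    best = None
    for _ in range(1 + int(opts["restarts"])):
        res = minimize(negloglik, x0, method="Nelder-Mead",
                       options={"maxiter": opts["maxiter"],
                                "fatol": opts["tol"]})
        if best is None or res.fun < best.fun:
            best = res
        x0 = best.x
    xf = x_full.copy()
    xf[long_idx] = best.x
    return MLEResult(
        params=unpack_params(xf, dims), x=xf, loglik=-best.fun,
        n_iter=best.nit, n_eval=best.nfev, converged=bool(best.success),
        history=history, dims=dims,
    )
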