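"""Bayesian estimation by Gibbs sampling with probit data augmentation.

The sampler targets the posterior of the complete-data model — random effects
``b_i`` retained as latent variables, so no orthant probabilities are needed:

    prod_i f(Y_i^o | b_i) f(d_i, delta_D | b_i) f(s_i, delta_S | b_i) f(b_i) x prior.

Each probit Bernoulli factor is augmented with a latent normal ``h_ij ~
N(lp_ij, 1)`` whose sign encodes the event (event occurred iff h_ij <= 0,
since the hazard is 1 - Phi(lp)).  With independent normal priors on the
regression/association coefficients and inverse-gamma priors on the variance
components, every full conditional is then conjugate: truncated normals for
h, multivariate normals for (alpha, gamma), b_i and beta, a normal for each
generalized autoregressive parameter lambda_kl, and inverse gammas for
sigma2_eps and the innovation variances.

Default priors follow the motivating analysis: N(0, 100) on beta and lambda,
weakly informative N(0, 4) on the probit-scale hazard coefficients,
inverse-gamma(0.001, 0.001) on sigma2_eps and inverse-gamma(0.01, 1) on the
innovation variances.  Visit-constant gamma and constant W matrices are
assumed (the motivating configuration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr, ndtri

from ._gibbs_kernels import collapsed_loglik, probit_loglik
from .model_core import CholeskyCov, Dataset, JointParams

__all__ = ["PriorSpec", "PosteriorDraws", "sample_posterior", "diagnostics"]

_TINY = 1e-300


@dataclass(frozen=True)
class PriorSpec:
    """Independent priors; every hyperparameter is overridable.

    Variance hyperparameters are prior *variances* of the normal priors;
    the inverse-gamma pairs are (shape, scale).
    """

    beta_var: float = 100.0
    lambda_var: float = 100.0
    alpha_var: float = 4.0
    gamma_var: float = 4.0
    sigma2_eps_ig: tuple = (0.001, 0.001)
    innovation_ig: tuple = (0.01, 1.0)

    def __post_init__(self):
        for v in (self.beta_var, self.lambda_var, self.alpha_var, self.gamma_var):
            if v <= 0:
                raise ValueError("prior variances must be positive")
        for a, b in (self.sigma2_eps_ig, self.innovation_ig):
            if a <= 0 or b <= 0:
                raise ValueError("inverse-gamma hyperparameters must be positive")


# --------------------------------------------------------------------------
# data layout
# --------------------------------------------------------------------------

class _Blocks:
    """Flat row-wise arrays for the three submodels, built once per fit."""

    def __init__(self, dataset: Dataset):
        spec = dataset.spec
        if spec.hazards.visit_varying_gamma:
            raise NotImplementedError(
                "the Gibbs sampler supports visit-constant gamma only"
            )
        self.q = spec.q
        self.N = len(dataset)
        pid_y, Xl, Zl, y = [], [], [], []
        pid_D, XD, eD = [], [], []
        pid_S, XS, eS = [], [], []
        for i, p in enumerate(dataset):
            dm = dataset.design(p)
            idx = p.observed_visits - 1
            pid_y.extend([i] * p.n_obs)
            Xl.append(dm["X"][idx])
            Zl.append(dm["Z"][idx])
            y.append(p.y_obs)
            pid_D.extend([i] * p.D_star)
            XD.append(dm["XD"][: p.D_star])
            ev = np.zeros(p.D_star)
            ev[-1] = p.delta_D
            eD.append(ev)
            pid_S.extend([i] * p.S_star)
            XS.append(dm["XS"][: p.S_star])
            ev = np.zeros(p.S_star)
            ev[-1] = p.delta_S
            eS.append(ev)
        p_dim = spec.longitudinal.p
        self.pid_y = np.asarray(pid_y, int)
        self.Xl = np.vstack(Xl) if Xl else np.zeros((0, p_dim))
        self.Zl = np.vstack(Zl) if Zl else np.zeros((0, self.q))
        self.y = np.concatenate(y) if y else np.zeros(0)
        self.pid_D = np.asarray(pid_D, int)
        self.XD = np.vstack(XD) if XD else np.zeros((0, spec.hazards.p_dropout))
        self.event_D = np.concatenate(eD).astype(bool) if eD else np.zeros(0, bool)
        self.pid_S = np.asarray(pid_S, int)
        self.XS = np.vstack(XS) if XS else np.zeros((0, spec.hazards.p_death))
        self.event_S = np.concatenate(eS).astype(bool) if eS else np.zeros(0, bool)
        self.WD = spec.hazards.W_D(self.q)
        self.WS = spec.hazards.W_S(self.q)
        # per-patient sufficient statistics of the hazard designs (constant)
        self.SXD = _bincount_cols(self.pid_D, self.XD, self.N) \
            if self.XD.size else np.zeros((self.N, self.XD.shape[1]))
        self.SXS = _bincount_cols(self.pid_S, self.XS, self.N) \
            if self.XS.size else np.zeros((self.N, self.XS.shape[1]))
        self.XtXD = self.XD.T @ self.XD
        self.XtXS = self.XS.T @ self.XS
        # per-patient constants
        self.ZtZ = np.zeros((self.N, self.q, self.q))
        for r in range(self.Zl.shape[0]):
            z = self.Zl[r]
            self.ZtZ[self.pid_y[r]] += np.outer(z, z)
        self.nD = np.bincount(self.pid_D, minlength=self.N).astype(float)
        self.nS = np.bincount(self.pid_S, minlength=self.N).astype(float)
        self.XtX = self.Xl.T @ self.Xl
        self.n_y = self.y.size


def _bincount_cols(pid: np.ndarray, mat: np.ndarray, N: int) -> np.ndarray:
    """Column-wise np.bincount: per-patient sums of rows of ``mat``."""
    out = np.empty((N, mat.shape[1]))
    for k in range(mat.shape[1]):
        out[:, k] = np.bincount(pid, weights=mat[:, k], minlength=N)
    return out


def _trunc_normal(lp: np.ndarray, event: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """h ~ N(lp, 1) truncated to h <= 0 on event rows, h > 0 otherwise."""
    u = rng.random(lp.size)
    z = np.empty(lp.size)
    ev = event
    z[ev] = ndtri(np.clip(u[ev] * ndtr(-lp[ev]), _TINY, 1.0))
    z[~ev] = -ndtri(np.clip(u[~ev] * ndtr(lp[~ev]), _TINY, 1.0))
    return lp + z


def _draw_coef(U: np.ndarray, h: np.ndarray, prior_prec: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """Draw from N((U'U + P)^-1 U'h, (U'U + P)^-1) — probit-scale regression
    with unit residual variance."""
    prec = U.T @ U + np.diag(prior_prec)
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, U.T @ h)
    eps = rng.standard_normal(prior_prec.size)
    return mean + np.linalg.solve(L.T, eps)


# --------------------------------------------------------------------------
# posterior container
# --------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Posterior draws with chain labels; arrays are (chains, draws, ...)."""

    beta: np.ndarray
    alpha_D: np.ndarray
    gamma_D: np.ndarray
    alpha_S: np.ndarray
    gamma_S: np.ndarray
    sigma2_eps: np.ndarray
    lam: np.ndarray              # (C, D, q, q) strictly lower triangular
    innovation_vars: np.ndarray  # (C, D, q)
    b_mean: np.ndarray | None = None   # posterior mean of each b_i over draws
    tuning: dict | None = None   # adapted MH proposals (reusable across fits
                                 # of same-design datasets)

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def to_dict(self) -> dict:
        """Scalar-expanded dict (chains, draws) per named parameter."""
        out = {}
        for name in ("beta", "alpha_D", "gamma_D", "alpha_S", "gamma_S"):
            arr = getattr(self, name)
            for k in range(arr.shape[2]):
                out[f"{name}[{k}]"] = arr[:, :, k]
        out["sigma2_eps"] = self.sigma2_eps
        q = self.innovation_vars.shape[2]
        for k in range(q):
            out[f"innovation_var[{k}]"] = self.innovation_vars[:, :, k]
            for l in range(k):
                out[f"lambda[{k},{l}]"] = self.lam[:, :, k, l]
        return out

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd and central 95% interval per scalar parameter."""
        rows = []
        for name, arr in self.to_dict().items():
            flat = arr.reshape(-1)
            rows.append({
                "param": name,
                "mean": flat.mean(),
                "sd": flat.std(ddof=1),
                "2.5%": np.quantile(flat, 0.025),
                "97.5%": np.quantile(flat, 0.975),
            })
        return pd.DataFrame(rows).set_index("param")

    def iter_params(self, max_draws: int | None = None) -> Iterator[JointParams]:
        """Yield pooled draws as JointParams (optionally thinned)."""
        C, D = self.n_chains, self.n_draws
        total = C * D
        take = total if max_draws is None else min(max_draws, total)
        idx = np.linspace(0, total - 1, take).astype(int)
        for t in idx:
            c, d = divmod(int(t), D)
            yield JointParams(
                beta=self.beta[c, d],
                alpha_D=self.alpha_D[c, d],
                gamma_D=self.gamma_D[c, d],
                alpha_S=self.alpha_S[c, d],
                gamma_S=self.gamma_S[c, d],
                sigma2_eps=float(self.sigma2_eps[c, d]),
                cov=CholeskyCov(self.lam[c, d], self.innovation_vars[c, d]),
            )

    def mean_params(self) -> JointParams:
        """Posterior-mean parameter point (covariance from mean lambda/sigma2)."""
        return JointParams(
            beta=self.beta.mean((0, 1)),
            alpha_D=self.alpha_D.mean((0, 1)),
            gamma_D=self.gamma_D.mean((0, 1)),
            alpha_S=self.alpha_S.mean((0, 1)),
            gamma_S=self.gamma_S.mean((0, 1)),
            sigma2_eps=float(self.sigma2_eps.mean()),
            cov=CholeskyCov(self.lam.mean((0, 1)), self.innovation_vars.mean((0, 1))),
        )


# --------------------------------------------------------------------------
# the sampler
# --------------------------------------------------------------------------

def sample_posterior(
    dataset: Dataset,
    prior: PriorSpec | None = None,
    chains: int = 3,
    warmup: int = 5000,
    draws: int = 15000,
    seed: int = 0,
    fixed: dict | None = None,
    init_scale: float = 1.0,
    tuning: dict | None = None,
) -> PosteriorDraws:
    """Gibbs sampling of the joint posterior.

    ``fixed`` optionally pins parameters (keys among ``beta``, ``alpha_D``,
    ``gamma_D``, ``alpha_S``, ``gamma_S``, ``sigma2_eps``, ``cov``) at given
    values — useful for conjugate subchecks and misspecification experiments.
    Chains use independent substreams of ``seed`` and dispersed initial
    values; results are reproducible given the seed.
    """
    prior = prior or PriorSpec()
    fixed = fixed or {}
    blocks = _Blocks(dataset)
    spec = dataset.spec
    q = blocks.q
    p = spec.longitudinal.p
    pD, pS = spec.hazards.p_dropout, spec.hazards.p_death
    qD, qS = blocks.WD.shape[0], blocks.WS.shape[0]

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(chains)

    store = {
        "beta": np.empty((chains, draws, p)),
        "alpha_D": np.empty((chains, draws, pD)),
        "gamma_D": np.empty((chains, draws, qD)),
        "alpha_S": np.empty((chains, draws, pS)),
        "gamma_S": np.empty((chains, draws, qS)),
        "sigma2_eps": np.empty((chains, draws)),
        "lam": np.empty((chains, draws, q, q)),
        "innovation_vars": np.empty((chains, draws, q)),
    }
    b_accum = np.zeros((blocks.N, q))

    tuning_out: dict = {}
    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        state = _init_state(blocks, p, pD, pS, qD, qS, q, rng, init_scale, fixed)
        if tuning:
            for key, val in tuning.items():
                state[key] = np.array(val, copy=True) if hasattr(val, "ndim") \
                    else val
        for it in range(warmup + draws):
            state["_adapting"] = it < warmup
            _gibbs_step(state, blocks, prior, fixed, rng)
            if it >= warmup:
                t = it - warmup
                store["beta"][c, t] = state["beta"]
                store["alpha_D"][c, t] = state["alpha_D"]
                store["gamma_D"][c, t] = state["gamma_D"]
                store["alpha_S"][c, t] = state["alpha_S"]
                store["gamma_S"][c, t] = state["gamma_S"]
                store["sigma2_eps"][c, t] = state["sigma2_eps"]
                store["lam"][c, t] = state["lam"]
                store["innovation_vars"][c, t] = state["ivar"]
                b_accum += state["b"]
        if c == 0:
            tuning_out = {
                k: state[k] for k in state
                if k.startswith(("_mh_chol_", "_mh_logscale_",
                                 "_pmh_logscale_"))
            }

    result = PosteriorDraws(
        **store, b_mean=b_accum / (chains * draws) if blocks.N else None,
        tuning=tuning_out,
    )
    _check_health(result)
    return result


def _init_state(blocks, p, pD, pS, qD, qS, q, rng, init_scale, fixed):
    """Dispersed data-informed initial values (prior-scale jitter per chain)."""
    if blocks.n_y > p:
        beta0, *_ = np.linalg.lstsq(blocks.Xl, blocks.y, rcond=None)
        resid = blocks.y - blocks.Xl @ beta0
        s2 = max(float(resid.var()), 0.1)
    else:
        beta0, s2 = np.zeros(p), 1.0
    # two-stage starting values for the hazard blocks: crude BLUPs of the
    # random effects from the outcome rows, then a ridge-probit regression of
    # the event indicators on (X, BLUP) so that alpha AND gamma start in the
    # right region (removes warmup drag on the weakly identified gammas)
    blup = np.zeros((blocks.N, q))
    if blocks.n_y > p and blocks.N:
        e = blocks.y - blocks.Xl @ beta0
        sigma0_inv = np.diag(np.concatenate([[1.0 / max(s2, 1e-6)],
                                             np.full(q - 1, 10.0 / max(s2, 1e-6))]))
        prec = sigma0_inv[None] + blocks.ZtZ / s2
        lin = _bincount_cols(blocks.pid_y, blocks.Zl * e[:, None], blocks.N) / s2
        blup = np.linalg.solve(prec, lin[:, :, None])[:, :, 0]
    aD0, gD0 = _probit_init_joint(blocks.XD, (blup @ blocks.WD.T),
                                  blocks.pid_D, blocks.event_D, pD, qD)
    aS0, gS0 = _probit_init_joint(blocks.XS, (blup @ blocks.WS.T),
                                  blocks.pid_S, blocks.event_S, pS, qS)
    state = {
        "beta": fixed.get("beta", beta0 + init_scale * rng.normal(0, 0.5, p)),
        "alpha_D": fixed.get("alpha_D", aD0 + rng.normal(0, 0.25 * init_scale, pD)),
        "gamma_D": fixed.get("gamma_D", gD0 + rng.normal(0, 0.15 * init_scale, qD)),
        "alpha_S": fixed.get("alpha_S", aS0 + rng.normal(0, 0.25 * init_scale, pS)),
        "gamma_S": fixed.get("gamma_S", gS0 + rng.normal(0, 0.15 * init_scale, qS)),
        "sigma2_eps": fixed.get("sigma2_eps", s2 * np.exp(rng.normal(0, 0.3))),
        "b": blup.copy(),
    }
    state["beta"] = np.atleast_1d(np.asarray(state["beta"], float))
    cov0 = fixed.get("cov")
    if cov0 is not None:
        state["lam"] = cov0.lam.copy()
        state["ivar"] = cov0.innovation_vars.copy()
    else:
        state["lam"] = np.zeros((q, q))
        state["ivar"] = np.full(q, max(s2, 1.0)) * np.exp(rng.normal(0, 0.3, q))
    return state


def _probit_init_joint(X: np.ndarray, bw: np.ndarray, pid: np.ndarray,
                       event: np.ndarray, p: int, qp: int):
    """Starting values for (alpha, gamma): ridge probit of the event rows on
    the hazard design augmented with the BLUP random-effect columns."""
    if X.shape[0] < 5 * (p + qp):
        return np.zeros(p), np.zeros(qp)
    U = np.hstack([X, bw[pid]])
    coef = _probit_init(U, event, p + qp)
    return coef[:p], coef[p:]


def _probit_init(X: np.ndarray, event: np.ndarray, p: int) -> np.ndarray:
    """Ridge-stabilized Newton probit fit of the marginal (no-random-effect)
    hazard — a cheap, well-placed starting value for alpha."""
    if X.shape[0] < 5 * p:
        return np.zeros(p)
    from scipy.stats import norm

    s = np.where(event, -1.0, 1.0)
    a = np.zeros(p)
    for _ in range(25):
        lp = np.clip(s * (X @ a), -30, 30)
        ratio = np.exp(norm.logpdf(lp) - log_ndtr(lp))
        grad = X.T @ (s * ratio) - a / 100.0
        wdiag = ratio * (lp + ratio)
        H = (X * wdiag[:, None]).T @ X + np.eye(p) / 100.0
        step = np.linalg.solve(H, grad)
        a = a + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return a if np.all(np.isfinite(a)) else np.zeros(p)


def _sigma_from_state(state) -> np.ndarray:
    q = state["ivar"].size
    L = np.eye(q) - np.tril(state["lam"], -1)
    Linv = np.linalg.inv(L)
    return (Linv * state["ivar"]) @ Linv.T


def _gibbs_step(state, blocks: _Blocks, prior: PriorSpec, fixed: dict,
                rng: np.random.Generator) -> None:
    q = state["ivar"].size
    N = blocks.N
    B = state["b"]

    # --- probit latents and hazard coefficients -------------------------
    for proc, pid, X, event, W in (
        ("D", blocks.pid_D, blocks.XD, blocks.event_D, blocks.WD),
        ("S", blocks.pid_S, blocks.XS, blocks.event_S, blocks.WS),
    ):
        alpha_name, gamma_name = f"alpha_{proc}", f"gamma_{proc}"
        BW = B @ W.T            # (N, q^.)
        rows_bw = BW[pid]
        lp = X @ state[alpha_name] + rows_bw @ state[gamma_name]
        h = _trunc_normal(lp, event, rng) if lp.size else lp
        state[f"h_{proc}"] = h
        a_fix = alpha_name in fixed
        g_fix = gamma_name in fixed
        if a_fix and g_fix:
            continue
        if blocks.N == 0:
            # no data: draw the coefficients from their priors
            if not a_fix:
                state[alpha_name] = rng.normal(
                    0, np.sqrt(prior.alpha_var), X.shape[1])
            if not g_fix:
                state[gamma_name] = rng.normal(
                    0, np.sqrt(prior.gamma_var), rows_bw.shape[1])
            continue
        if not a_fix and not g_fix:
            U = np.hstack([X, rows_bw])
            pr = np.concatenate([
                np.full(X.shape[1], 1.0 / prior.alpha_var),
                np.full(rows_bw.shape[1], 1.0 / prior.gamma_var),
            ])
            coef = _draw_coef(U, h, pr, rng)
            state[alpha_name] = coef[: X.shape[1]]
            state[gamma_name] = coef[X.shape[1]:]
        elif not a_fix:
            resid = h - rows_bw @ state[gamma_name]
            state[alpha_name] = _draw_coef(
                X, resid, np.full(X.shape[1], 1.0 / prior.alpha_var), rng)
        else:
            resid = h - X @ state[alpha_name]
            state[gamma_name] = _draw_coef(
                rows_bw, resid, np.full(rows_bw.shape[1], 1.0 / prior.gamma_var), rng)

    # --- collapsed gamma moves -------------------------------------------
    # The conjugate (alpha, gamma) | b update above mixes slowly along the
    # gamma-b ridge (gamma regresses on latent covariates).  Immediately
    # before redrawing b we therefore also update each (alpha, gamma) from
    # its conditional with b analytically integrated out (Metropolis steps on
    # a cheap closed-form Gaussian marginal); together with the b redraw this
    # is a valid blocked (alpha, gamma, b) update.
    if N:
        for proc in ("D", "S"):
            if f"gamma_{proc}" not in fixed:
                _collapsed_hazard_update(state, blocks, prior, fixed, rng, proc)

    # --- random effects --------------------------------------------------
    if N:
        sigma = _sigma_from_state(state)
        sigma_inv = np.linalg.inv(sigma)
        s2e = state["sigma2_eps"]
        gD = blocks.WD.T @ state["gamma_D"]
        gS = blocks.WS.T @ state["gamma_S"]
        prec = (
            sigma_inv[None]
            + blocks.ZtZ / s2e
            + blocks.nD[:, None, None] * np.outer(gD, gD)[None]
            + blocks.nS[:, None, None] * np.outer(gS, gS)[None]
        )
        lin = np.zeros((N, q))
        if blocks.n_y:
            e = blocks.y - blocks.Xl @ state["beta"]
            lin += _bincount_cols(blocks.pid_y, blocks.Zl * e[:, None], N) / s2e
        if blocks.pid_D.size:
            rD = np.bincount(
                blocks.pid_D,
                weights=state["h_D"] - blocks.XD @ state["alpha_D"],
                minlength=N,
            )
            lin += rD[:, None] * gD[None]
        if blocks.pid_S.size:
            rS = np.bincount(
                blocks.pid_S,
                weights=state["h_S"] - blocks.XS @ state["alpha_S"],
                minlength=N,
            )
            lin += rS[:, None] * gS[None]
        eps = rng.standard_normal((N, q))
        if q == 2:
            B = _sample_b_q2(prec, lin, eps)
        else:
            mean = np.linalg.solve(prec, lin[:, :, None])[:, :, 0]
            Lp = np.linalg.cholesky(prec)
            B = mean + np.linalg.solve(
                np.transpose(Lp, (0, 2, 1)), eps[:, :, None])[:, :, 0]
        state["b"] = B

    # --- fixed effects and residual variance ------------------------------
    if "beta" not in fixed and blocks.n_y:
        s2e = state["sigma2_eps"]
        resid_y = blocks.y - np.einsum("ij,ij->i", blocks.Zl, B[blocks.pid_y])
        prec = blocks.XtX / s2e + np.eye(blocks.Xl.shape[1]) / prior.beta_var
        mean = np.linalg.solve(prec, blocks.Xl.T @ resid_y / s2e)
        L = np.linalg.cholesky(prec)
        eps = rng.standard_normal(mean.size)
        state["beta"] = mean + np.linalg.solve(L.T, eps)
    elif "beta" not in fixed:
        state["beta"] = rng.normal(0, np.sqrt(prior.beta_var), state["beta"].size)

    if "sigma2_eps" not in fixed:
        a0, b0 = prior.sigma2_eps_ig
        if blocks.n_y:
            r = (blocks.y - blocks.Xl @ state["beta"]
                 - np.einsum("ij,ij->i", blocks.Zl, B[blocks.pid_y]))
            state["sigma2_eps"] = _inv_gamma(
                a0 + 0.5 * blocks.n_y, b0 + 0.5 * float(r @ r), rng)
        else:
            state["sigma2_eps"] = _inv_gamma(a0, b0, rng)

    # --- random-effects covariance (modified Cholesky) --------------------
    if "cov" not in fixed:
        a0, b0 = prior.innovation_ig
        lam = state["lam"]
        ivar = state["ivar"]
        for k in range(q):
            if N and k > 0:
                pred = B[:, :k]
                prec = pred.T @ pred / ivar[k] + np.eye(k) / prior.lambda_var
                mean = np.linalg.solve(prec, pred.T @ B[:, k] / ivar[k])
                L = np.linalg.cholesky(prec)
                lam[k, :k] = mean + np.linalg.solve(
                    L.T, rng.standard_normal(k))
            elif k > 0:
                lam[k, :k] = rng.normal(0, np.sqrt(prior.lambda_var), k)
            if N:
                e = B[:, k] - (B[:, :k] @ lam[k, :k] if k else 0.0)
                ivar[k] = _inv_gamma(a0 + 0.5 * N, b0 + 0.5 * float(e @ e), rng)
            else:
                ivar[k] = _inv_gamma(a0, b0, rng)
        state["lam"], state["ivar"] = lam, ivar

    # --- h-collapsed hazard coefficient moves ------------------------------
    # Classic probit data augmentation mixes slowly when event probabilities
    # are far from 1/2 (the latents remember the coefficients).  A Metropolis
    # update against the exact Bernoulli-probit likelihood given b removes
    # that memory; it is placed last so the latents are refreshed (first step
    # of the next sweep) before anything uses them again.
    if N:
        for proc in ("D", "S"):
            if f"gamma_{proc}" in fixed and f"alpha_{proc}" in fixed:
                continue
            _probit_mh_update(state, blocks, prior, fixed, rng, proc)


def _probit_mh_update(state, blocks: _Blocks, prior: PriorSpec, fixed: dict,
                      rng: np.random.Generator, proc: str,
                      n_steps: int = 8) -> None:
    """Metropolis update of (alpha_proc, gamma_proc) against the exact probit
    event likelihood given the current random effects (latent h integrated
    out).  Uses the same adapted proposal machinery as the b-collapsed move."""
    from scipy.special import log_ndtr

    if proc == "D":
        pid, X, W, event = blocks.pid_D, blocks.XD, blocks.WD, blocks.event_D
    else:
        pid, X, W, event = blocks.pid_S, blocks.XS, blocks.WS, blocks.event_S
    if not pid.size:
        return
    rows_bw = (state["b"] @ W.T)[pid]
    sign = np.where(event, -1.0, 1.0)
    U = np.ascontiguousarray(np.hstack([X, rows_bw]))
    p_dim = X.shape[1]
    q_dim = W.shape[0]
    a_prec = 1.0 / prior.alpha_var
    g_prec = 1.0 / prior.gamma_var
    a_fixed = f"alpha_{proc}" in fixed
    g_fixed = f"gamma_{proc}" in fixed

    def logpost(theta: np.ndarray) -> float:
        a, g = theta[:p_dim], theta[p_dim:]
        return (probit_loglik(U, sign, theta)
                - 0.5 * a_prec * float(a @ a) - 0.5 * g_prec * float(g @ g))

    theta = np.concatenate([state[f"alpha_{proc}"], state[f"gamma_{proc}"]])
    d = theta.size
    mask = np.ones(d)
    if a_fixed:
        mask[:p_dim] = 0.0
    if g_fixed:
        mask[p_dim:] = 0.0
    key_s = f"_pmh_logscale_{proc}"
    key_chol = f"_mh_chol_{proc}"       # share the learned shape with move A
    log_s = state.setdefault(key_s, np.log(0.3))
    chol = state.get(key_chol)
    if chol is None:
        chol = np.eye(d) * 0.1
    lp = logpost(theta)
    accepted = 0
    for _ in range(n_steps):
        prop = theta + np.exp(log_s) * mask * (chol @ rng.standard_normal(d))
        lp_new = logpost(prop)
        if np.log(rng.random()) < lp_new - lp:
            theta, lp = prop, lp_new
            accepted += 1
    if state.get("_adapting", False):
        state[key_s] = float(np.clip(
            log_s + 0.5 * (accepted / n_steps - 0.28),
            np.log(1e-4), np.log(10.0)))
    if not a_fixed:
        state[f"alpha_{proc}"] = theta[:p_dim]
    if not g_fixed:
        state[f"gamma_{proc}"] = theta[p_dim:]


def _batch_inv(mats: np.ndarray) -> np.ndarray:
    """Inverse of stacked symmetric matrices (explicit 2x2 fast path)."""
    if mats.shape[1] == 2:
        a, b, c = mats[:, 0, 0], mats[:, 0, 1], mats[:, 1, 1]
        det = a * c - b * b
        out = np.empty_like(mats)
        out[:, 0, 0] = c / det
        out[:, 1, 1] = a / det
        out[:, 0, 1] = out[:, 1, 0] = -b / det
        return out
    return np.linalg.inv(mats)


def _collapsed_hazard_update(state, blocks: _Blocks, prior: PriorSpec,
                             fixed: dict, rng: np.random.Generator, proc: str,
                             n_steps: int = 30) -> None:
    """Metropolis update of (alpha_proc, gamma_proc) from their conditional
    with the random effects integrated out.

    Given the latents, b_i is Gaussian with moments (m_i, V_i) computed from
    the outcome rows and the *other* process's rows; the target process's
    latent rows then have the exchangeable marginal
    ``h_i - X alpha ~ N(1 w_i, I + v_i J)`` with ``w_i = gamma' W m_i`` and
    ``v_i = gamma' W V_i W' gamma``, whose likelihood has a closed form in
    per-patient sufficient statistics.  Proposal scales adapt during warmup.
    """
    N = blocks.N
    sigma = _sigma_from_state(state)
    sigma_inv = np.linalg.inv(sigma)
    s2e = state["sigma2_eps"]

    if proc == "D":
        pid, X, W = blocks.pid_D, blocks.XD, blocks.WD
        n_rows, SX, XtX = blocks.nD, blocks.SXD, blocks.XtXD
        h = state["h_D"]
        other_g = blocks.WS.T @ state["gamma_S"]
        other_n = blocks.nS
        other_resid = (
            np.bincount(blocks.pid_S,
                        weights=state["h_S"] - blocks.XS @ state["alpha_S"],
                        minlength=N)
            if blocks.pid_S.size else np.zeros(N)
        )
    else:
        pid, X, W = blocks.pid_S, blocks.XS, blocks.WS
        n_rows, SX, XtX = blocks.nS, blocks.SXS, blocks.XtXS
        h = state["h_S"]
        other_g = blocks.WD.T @ state["gamma_D"]
        other_n = blocks.nD
        other_resid = (
            np.bincount(blocks.pid_D,
                        weights=state["h_D"] - blocks.XD @ state["alpha_D"],
                        minlength=N)
            if blocks.pid_D.size else np.zeros(N)
        )
    if not h.size:
        return

    # moments of b_i given outcome rows + other process's latents
    prec = sigma_inv[None] + blocks.ZtZ / s2e \
        + other_n[:, None, None] * np.outer(other_g, other_g)[None]
    lin = other_resid[:, None] * other_g[None]
    if blocks.n_y:
        e = blocks.y - blocks.Xl @ state["beta"]
        lin = lin + _bincount_cols(blocks.pid_y, blocks.Zl * e[:, None], N) / s2e
    V = _batch_inv(prec)
    m = np.einsum("nij,nj->ni", V, lin)

    # sufficient statistics of the target latent rows: per-patient sums plus
    # global quadratic pieces (the squared-residual total only enters summed)
    Sh = np.bincount(pid, weights=h, minlength=N)
    hh = float(h @ h)
    Xh = X.T @ h
    q = state["ivar"].size
    if W.shape == (q, q) and np.array_equal(W, np.eye(q)):
        Wm = m
        WVW_flat = np.ascontiguousarray(V.reshape(N, -1))
    else:
        Wm = m @ W.T                                   # (N, q_proc)
        WVW = np.einsum("ab,nbc,dc->nad", W, V, W)     # (N, q_proc, q_proc)
        WVW_flat = np.ascontiguousarray(WVW.reshape(N, -1))

    p_dim = X.shape[1]
    q_dim = W.shape[0]
    a_prec = 1.0 / prior.alpha_var
    g_prec = 1.0 / prior.gamma_var
    a_fixed = f"alpha_{proc}" in fixed
    Wm = np.ascontiguousarray(Wm)
    Sh_c = np.ascontiguousarray(Sh)
    SX_c = np.ascontiguousarray(SX)
    nr_c = np.ascontiguousarray(n_rows)
    Xh_c = np.ascontiguousarray(Xh)
    XtX_c = np.ascontiguousarray(XtX)

    def logpost(theta: np.ndarray) -> float:
        a, g = theta[:p_dim], theta[p_dim:]
        ll = collapsed_loglik(Wm, WVW_flat, Sh_c, SX_c, nr_c, hh, Xh_c,
                              XtX_c, np.ascontiguousarray(a),
                              np.ascontiguousarray(g))
        return ll - 0.5 * a_prec * float(a @ a) - 0.5 * g_prec * float(g @ g)

    theta = np.concatenate([state[f"alpha_{proc}"], state[f"gamma_{proc}"]])
    d = theta.size
    mask = np.ones(d)
    if a_fixed:
        mask[:p_dim] = 0.0

    # adaptive-Metropolis proposal: scaled Cholesky of the empirical
    # covariance of past collapsed draws (learned during warmup)
    key_s = f"_mh_logscale_{proc}"
    key_hist = f"_mh_hist_{proc}"
    key_chol = f"_mh_chol_{proc}"
    log_s = state.setdefault(key_s, np.log(0.3))
    chol = state.get(key_chol)
    if chol is None:
        chol = np.eye(d) * 0.1
        state[key_chol] = chol
    adapting = state.get("_adapting", False)

    lp = logpost(theta)
    accepted = 0
    for _ in range(n_steps):
        prop = theta + np.exp(log_s) * mask * (chol @ rng.standard_normal(d))
        lp_new = logpost(prop)
        if np.log(rng.random()) < lp_new - lp:
            theta, lp = prop, lp_new
            accepted += 1
    if adapting:
        rate = accepted / n_steps
        log_s += 0.5 * (rate - 0.28)
        state[key_s] = float(np.clip(log_s, np.log(1e-4), np.log(10.0)))
        hist = state.setdefault(key_hist, [])
        hist.append(theta.copy())
        if len(hist) >= 100 and len(hist) % 50 == 0:
            emp = np.cov(np.asarray(hist[-500:]).T) + 1e-8 * np.eye(d)
            state[key_chol] = np.linalg.cholesky(emp) * (2.38 / np.sqrt(d))
            state[key_s] = 0.0
    if not a_fixed:
        state[f"alpha_{proc}"] = theta[:p_dim]
    state[f"gamma_{proc}"] = theta[p_dim:]


def _sample_b_q2(prec: np.ndarray, lin: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Vectorized draw from N(prec^-1 lin, prec^-1) for stacked 2x2 precisions
    (closed-form inverse and Cholesky avoid batched LAPACK overhead)."""
    a = prec[:, 0, 0]
    b = prec[:, 0, 1]
    c = prec[:, 1, 1]
    det = a * c - b * b
    m0 = (c * lin[:, 0] - b * lin[:, 1]) / det
    m1 = (a * lin[:, 1] - b * lin[:, 0]) / det
    l11 = np.sqrt(a)
    l21 = b / l11
    l22 = np.sqrt(c - l21 * l21)
    # solve L' x = eps
    x1 = eps[:, 1] / l22
    x0 = (eps[:, 0] - l21 * x1) / l11
    return np.stack([m0 + x0, m1 + x1], axis=1)


def _inv_gamma(shape: float, scale: float, rng: np.random.Generator) -> float:
    # tiny shapes (vague priors with no data) can underflow the gamma draw
    g = max(rng.gamma(shape), 1e-290)
    return float(min(scale / g, 1e290))


def _check_health(result: PosteriorDraws) -> None:
    """Ill-conditioning is reported, not silently ignored."""
    for name, arr in result.to_dict().items():
        if not np.all(np.isfinite(arr)):
            raise RuntimeError(f"non-finite posterior draws in {name}")
    if np.any(result.sigma2_eps <= 0) or np.any(result.innovation_vars <= 0):
        raise RuntimeError("non-positive variance draws: sampler is unhealthy")


# --------------------------------------------------------------------------
# convergence diagnostics
# --------------------------------------------------------------------------

def diagnostics(draws: PosteriorDraws | dict) -> pd.DataFrame:
    """Gelman-Rubin statistics and effective sample sizes per parameter
    (via arviz), plus posterior mean/sd trace summaries."""
    import arviz as az

    d = draws.to_dict() if isinstance(draws, PosteriorDraws) else draws
    idata = az.from_dict(posterior={k: np.asarray(v) for k, v in d.items()})
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for k in d:
        arr = np.asarray(d[k])
        rows.append({
            "param": k,
            "rhat": float(rhat[k].values),
            "ess": float(ess[k].values),
            "mean": arr.mean(),
            "sd": arr.std(ddof=1),
        })
    return pd.DataFrame(rows).set_index("param")
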