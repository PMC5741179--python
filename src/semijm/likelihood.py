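"""Complete-data likelihood factors and the closed-form marginal likelihood.

Given the random effects, a patient's likelihood factorizes into a Gaussian
density for the observed longitudinal rows and two sequences of probit
Bernoulli factors for dropout and death.  Using 1 - Phi(x) = Phi(-x), the
dropout x death part is a product of K <= 2M signed probit terms
``Phi(s_k (a_k + c_k' b))``.  Marginalizing b then has a closed form: with
iid standard normal augmentation variables ``eps_k`` (Phi(t) = P(eps_k <= t))
and b ~ N(mu_b, Sigma_b),

    E prod_k Phi(s_k (a_k + c_k' b)) = P(W <= u),   W ~ N(0, I_K + A Sigma_b A'),

where row k of A is ``s_k c_k'`` and ``u_k = s_k (a_k + c_k' mu_b)`` — a
K-dimensional normal orthant probability.  The patient's marginal
log-likelihood is the marginal Gaussian log-density of the observed outcomes
plus the log of this expectation taken under the posterior of b given the
outcomes.

Terms whose coefficient vector is zero (e.g. when gamma = 0) factor out as
exact scalar normal CDFs, so the likelihood reduces *exactly* to the
ignorable-missingness factorization in that case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import log_ndtr, ndtr

from ._mvncdf import mvn_cdf, mvn_cdf_many
from .model_core import Dataset, JointParams, PatientRecord

__all__ = [
    "MvnOptions",
    "ProbitTermSet",
    "OrthantProblem",
    "longitudinal_loglik_given_b",
    "dropout_loglik_given_b",
    "death_loglik_given_b",
    "collect_probit_terms",
    "build_orthant_problem",
    "expectation_probit_product",
    "log_expectation_probit_product",
    "marginal_loglik_patient",
    "marginal_loglik_dataset",
]

_LOG2PI = np.log(2.0 * np.pi)

# Arguments of log Phi are capped below at this value to guard against
# -inf log-likelihoods from extreme linear predictors; log_ndtr(-38) ~ -726,
# close to the smallest representable double on the log scale.
_PROBIT_ARG_FLOOR = -38.0

# Floor applied to orthant probabilities before taking logs.
_LOG_PROB_FLOOR = -745.0


@dataclass(frozen=True)
class MvnOptions:
    """Accuracy knobs for the internal MVN CDF (see :mod:`semijm._mvncdf`).

    ``fast()`` is the profile used inside optimization loops, trading
    tolerance for roughly an order of magnitude in speed.
    """

    abstol: float = 1e-9
    reltol: float = 3e-5
    n_max: int = 4096
    batch_n: int | None = None   # fixed shared QMC budget: enables the
                                 # vectorized multi-problem evaluator

    @staticmethod
    def fast() -> "MvnOptions":
        return MvnOptions(abstol=1e-8, reltol=5e-4, n_max=1024)

    @staticmethod
    def batched(n_points: int = 512) -> "MvnOptions":
        """Throughput profile for optimization loops: one fixed point set
        shared across patients (no per-problem adaptivity)."""
        return MvnOptions(batch_n=n_points)

    def cdf(self, upper, cov) -> float:
        return mvn_cdf(upper, cov, abstol=self.abstol, reltol=self.reltol,
                       n_max=self.n_max)


_DEFAULT_MVN = MvnOptions()


@dataclass
class ProbitTermSet:
    """Signed affine probit factors: dropout x death likelihood given b equals
    ``prod_k Phi(signs_k * (offsets_k + coefs_k' b))``."""

    signs: np.ndarray      # (K,) in {+1, -1}
    offsets: np.ndarray    # (K,)
    coefs: np.ndarray      # (K, q)

    @property
    def K(self) -> int:
        return self.signs.size

    def log_product_at(self, b: np.ndarray) -> float:
        """log prod_k Phi(s_k (a_k + c_k' b)) at a fixed b."""
        args = self.signs * (self.offsets + self.coefs @ np.asarray(b, float))
        return float(np.sum(log_ndtr(np.maximum(args, _PROBIT_ARG_FLOOR))))


@dataclass
class OrthantProblem:
    """Upper limits and covariance whose zero-mean MVN CDF equals an
    expectation of a probit product.  K = 0 means the value is 1."""

    upper: np.ndarray
    cov: np.ndarray

    @property
    def K(self) -> int:
        return self.upper.size

    def value(self, options: MvnOptions = _DEFAULT_MVN) -> float:
        if self.K == 0:
            return 1.0
        return options.cdf(self.upper, self.cov)


# --------------------------------------------------------------------------
# complete-data factors (given b)
# --------------------------------------------------------------------------

def longitudinal_loglik_given_b(
    patient: PatientRecord, params: JointParams, b, dataset: Dataset
) -> float:
    """Gaussian log-density of the observed outcome rows given b: mean
    X_i beta + Z_i b, covariance sigma2_eps * I over the observed visits only
    (intermittent gaps are simply dropped).  Zero observed rows give 0."""
    n = patient.n_obs
    if n == 0:
        return 0.0
    dm = dataset.design(patient)
    idx = patient.observed_visits - 1
    mu = dm["X"][idx] @ params.beta + dm["Z"][idx] @ np.asarray(b, float)
    r = patient.y_obs - mu
    s2 = params.sigma2_eps
    return float(-0.5 * n * (_LOG2PI + np.log(s2)) - 0.5 * (r @ r) / s2)


def _hazard_sequence_loglik(
    last: int, delta: int, xmat: np.ndarray, alpha: np.ndarray,
    gammas: np.ndarray, W: np.ndarray, b,
) -> float:
    """Shared form of the dropout/death sequence likelihood: survival factors
    Phi(lp_j) for j < last, then Phi(lp_last) if censored or 1 - Phi(lp_last)
    if the event is observed."""
    js = np.arange(1, last + 1)
    lps = xmat[:last] @ alpha + (gammas[:last] * (W @ np.asarray(b, float))).sum(axis=1)
    signs = np.ones(last)
    if delta == 1:
        signs[-1] = -1.0
    args = np.maximum(signs * lps, _PROBIT_ARG_FLOOR)
    del js
    return float(np.sum(log_ndtr(args)))


def _gamma_matrix(params: JointParams, which: str, M: int) -> np.ndarray:
    g = params.gamma_D if which == "D" else params.gamma_S
    if g.ndim == 1:
        return np.tile(g, (M, 1))
    return g


def dropout_loglik_given_b(
    patient: PatientRecord, params: JointParams, b, dataset: Dataset
) -> float:
    """log f(D* = d, delta_D | b): survival through visits 1..d-1 plus the
    terminal factor at d (survival factor when delta_D = 0, even when the
    terminating event was death or censoring)."""
    dm = dataset.design(patient)
    gam = _gamma_matrix(params, "D", dataset.spec.M)
    return _hazard_sequence_loglik(
        patient.D_star, patient.delta_D, dm["XD"], params.alpha_D, gam, dm["WD"], b
    )


def death_loglik_given_b(
    patient: PatientRecord, params: JointParams, b, dataset: Dataset
) -> float:
    """log f(S* = s, delta_S | b), same sequential form as dropout."""
    dm = dataset.design(patient)
    gam = _gamma_matrix(params, "S", dataset.spec.M)
    return _hazard_sequence_loglik(
        patient.S_star, patient.delta_S, dm["XS"], params.alpha_S, gam, dm["WS"], b
    )


# --------------------------------------------------------------------------
# probit term collection and the orthant reduction
# --------------------------------------------------------------------------

def collect_probit_terms(
    patient: PatientRecord, params: JointParams, dataset: Dataset
) -> ProbitTermSet:
    """Rewrite the dropout x death likelihood given b as K = D* + S* signed
    probit factors (1 - Phi(x) = Phi(-x) flips the terminal sign when the
    event is observed)."""
    dm = dataset.design(patient)
    M = dataset.spec.M
    q = dataset.spec.q
    rows_s, rows_a, rows_c = [], [], []
    for which, last, delta, xmat, alpha, W in (
        ("D", patient.D_star, patient.delta_D, dm["XD"], params.alpha_D, dm["WD"]),
        ("S", patient.S_star, patient.delta_S, dm["XS"], params.alpha_S, dm["WS"]),
    ):
        gam = _gamma_matrix(params, which, M)
        offs = xmat[:last] @ alpha
        coefs = gam[:last] @ W              # (last, q)
        signs = np.ones(last)
        if delta == 1:
            signs[-1] = -1.0
        rows_s.append(signs)
        rows_a.append(offs)
        rows_c.append(coefs)
    return ProbitTermSet(
        signs=np.concatenate(rows_s),
        offsets=np.concatenate(rows_a),
        coefs=np.vstack(rows_c).reshape(-1, q),
    )


def build_orthant_problem(terms: ProbitTermSet, mean, cov_b) -> OrthantProblem:
    """Orthant problem whose CDF equals E_{b~N(mean, cov_b)} of the probit
    product: u_k = s_k (a_k + c_k' mean), Omega = I + A Sigma_b A' with
    A row k = s_k c_k'."""
    mean = np.asarray(mean, float)
    A = terms.signs[:, None] * terms.coefs
    u = terms.signs * (terms.offsets + terms.coefs @ mean)
    omega = np.eye(terms.K) + A @ np.asarray(cov_b, float) @ A.T
    return OrthantProblem(upper=u, cov=omega)


def log_expectation_probit_product(
    terms: ProbitTermSet, mean, cov_b, options: MvnOptions = _DEFAULT_MVN
) -> float:
    """log E_{b~N(mean, cov_b)}[prod_k Phi(s_k(a_k + c_k' b))].

    Terms with a zero coefficient vector do not involve b and factor out as
    exact scalar log Phi's; the remainder is the MVN orthant probability.
    """
    if terms.K == 0:
        return 0.0
    mean = np.asarray(mean, float)
    norms = np.abs(terms.coefs).sum(axis=1)
    fixed = norms == 0.0
    out = 0.0
    if np.any(fixed):
        args = terms.signs[fixed] * terms.offsets[fixed]
        out += float(np.sum(log_ndtr(np.maximum(args, _PROBIT_ARG_FLOOR))))
    if np.any(~fixed):
        sub = ProbitTermSet(
            signs=terms.signs[~fixed],
            offsets=terms.offsets[~fixed],
            coefs=terms.coefs[~fixed],
        )
        prob = build_orthant_problem(sub, mean, cov_b)
        if prob.K == 1:
            # exact scalar shortcut: E Phi(s(a + c'b)) = Phi(u / sqrt(1 + c'Sc))
            out += float(log_ndtr(prob.upper[0] / np.sqrt(prob.cov[0, 0])))
        else:
            out += max(np.log(max(prob.value(options), 0.0)), _LOG_PROB_FLOOR)
    return out


def expectation_probit_product(
    terms: ProbitTermSet, mean, cov_b, options: MvnOptions = _DEFAULT_MVN
) -> float:
    """E_{b~N(mean, cov_b)}[prod_k Phi(s_k(a_k + c_k' b))], in [0, 1]."""
    return float(np.exp(log_expectation_probit_product(terms, mean, cov_b, options)))


# --------------------------------------------------------------------------
# marginal likelihood
# --------------------------------------------------------------------------

def _posterior_b_moments(
    patient: PatientRecord, params: JointParams, dataset: Dataset
):
    """Moments of b given the observed outcome rows (the prior if none):
    Sigma_post = (Z'Z / sigma2_eps + Sigma^-1)^-1,
    mu_post = Sigma_post Z' (y - X beta) / sigma2_eps."""
    sigma = params.sigma
    q = sigma.shape[0]
    if patient.n_obs == 0:
        return np.zeros(q), sigma
    dm = dataset.design(patient)
    idx = patient.observed_visits - 1
    X, Z = dm["X"][idx], dm["Z"][idx]
    s2 = params.sigma2_eps
    try:
        prec = Z.T @ Z / s2 + np.linalg.inv(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("random-effects covariance is not invertible") from exc
    cov_post = np.linalg.inv(prec)
    cov_post = 0.5 * (cov_post + cov_post.T)
    mu_post = cov_post @ (Z.T @ (patient.y_obs - X @ params.beta)) / s2
    return mu_post, cov_post


def _gaussian_marginal_loglik(
    patient: PatientRecord, params: JointParams, dataset: Dataset
) -> float:
    """log N(y_obs; X beta, Z Sigma Z' + sigma2_eps I) over observed visits."""
    n = patient.n_obs
    if n == 0:
        return 0.0
    dm = dataset.design(patient)
    idx = patient.observed_visits - 1
    X, Z = dm["X"][idx], dm["Z"][idx]
    V = Z @ params.sigma @ Z.T + params.sigma2_eps * np.eye(n)
    r = patient.y_obs - X @ params.beta
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError("marginal outcome covariance is not positive definite") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    quad = r @ cho_solve((c, low), r)
    return float(-0.5 * (n * _LOG2PI + logdet + quad))


def marginal_loglik_patient(
    patient: PatientRecord,
    params: JointParams,
    dataset: Dataset,
    options: MvnOptions = _DEFAULT_MVN,
) -> float:
    """Closed-form marginal log-likelihood of one patient: random effects are
    integrated out of the complete-data likelihood analytically, leaving a
    Gaussian marginal for the outcomes times an MVN orthant probability for
    the event-history factors under the outcome posterior of b."""
    ll = _gaussian_marginal_loglik(patient, params, dataset)
    terms = collect_probit_terms(patient, params, dataset)
    mu_post, cov_post = _posterior_b_moments(patient, params, dataset)
    return ll + log_expectation_probit_product(terms, mu_post, cov_post, options)


def marginal_loglik_dataset(
    dataset: Dataset,
    params: JointParams,
    options: MvnOptions = _DEFAULT_MVN,
    per_patient: bool = False,
):
    """Total marginal log-likelihood (sum over patients; order-independent).

    Uses a vectorized evaluation: the Gaussian outcome marginals and the
    posterior moments of b are computed for all patients at once via the
    Woodbury identity, and the orthant covariance is assembled from the 2x2
    matrix of quadratic forms of the two association vectors.  Only the MVN
    CDF calls remain per patient — and they vanish entirely when the gammas
    are zero (exact scalar factorization).  Agrees with the per-patient
    reference :func:`marginal_loglik_patient` to numerical identity.
    """
    if params.gamma_D.ndim == 2 or params.gamma_S.ndim == 2:
        # visit-varying gamma: reference per-patient path
        vals = np.array(
            [marginal_loglik_patient(p, params, dataset, options) for p in dataset]
        )
        return (float(vals.sum()), vals) if per_patient else float(vals.sum())

    lb = _loglik_blocks(dataset)
    N = lb["N"]
    q = dataset.spec.q
    sigma = params.sigma
    s2e = params.sigma2_eps
    vals = np.zeros(N)

    # ---- Gaussian outcome marginal via Woodbury --------------------------
    sigma_inv = np.linalg.inv(sigma)
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise ValueError("random-effects covariance is not positive definite")
    r = lb["y"] - lb["Xl"] @ params.beta
    Ztr = _sum_by_patient(lb["pid_y"], lb["Zl"] * r[:, None], N)
    rr = np.bincount(lb["pid_y"], weights=r * r, minlength=N)
    prec = sigma_inv[None] + lb["ZtZ"] / s2e          # (N, q, q)
    cov_post = _batch_inv_sym(prec)
    mu_post = np.einsum("nij,nj->ni", cov_post, Ztr) / s2e
    logdet_prec = _batch_logdet_sym(prec)
    n_i = lb["n_y_i"]
    quad = (rr - np.einsum("ni,ni->n", Ztr, mu_post)) / s2e
    vals += -0.5 * (n_i * (_LOG2PI + np.log(s2e)) + logdet_sigma
                    + logdet_prec + quad)

    # ---- probit event factors --------------------------------------------
    gD = lb["WD"].T @ params.gamma_D
    gS = lb["WS"].T @ params.gamma_S
    uD = lb["XD"] @ params.alpha_D + lb["pidD_mu"](mu_post) @ gD
    uS = lb["XS"] @ params.alpha_S + lb["pidS_mu"](mu_post) @ gS
    uD = lb["signs_D"] * uD
    uS = lb["signs_S"] * uS
    if not np.any(gD) and not np.any(gS):
        vals += np.bincount(
            lb["pid_D"],
            weights=log_ndtr(np.maximum(uD, _PROBIT_ARG_FLOOR)), minlength=N)
        vals += np.bincount(
            lb["pid_S"],
            weights=log_ndtr(np.maximum(uS, _PROBIT_ARG_FLOOR)), minlength=N)
    else:
        # 2x2 quadratic forms of the association vectors under each posterior
        QDD = np.einsum("i,nij,j->n", gD, cov_post, gD)
        QDS = np.einsum("i,nij,j->n", gD, cov_post, gS)
        QSS = np.einsum("i,nij,j->n", gS, cov_post, gS)
        if options.batch_n is not None:
            u_all = np.concatenate([uD, uS])
            for grp in lb["groups"]:
                idx = grp["idx"]
                U = u_all[grp["rowidx"]]                     # (G, K)
                blockQ = (QDD[idx, None, None] * grp["patD"]
                          + QDS[idx, None, None] * grp["patX"]
                          + QSS[idx, None, None] * grp["patS"])
                omega = np.eye(grp["K"])[None] + grp["ss"] * blockQ
                probs = mvn_cdf_many(U, omega, n_points=options.batch_n)
                vals[idx] += np.maximum(
                    np.log(np.maximum(probs, 0.0)), _LOG_PROB_FLOOR)
        else:
            oD, oS = lb["offsets_D"], lb["offsets_S"]
            for i in range(N):
                sD = lb["signs_D"][oD[i]:oD[i + 1]]
                sS = lb["signs_S"][oS[i]:oS[i + 1]]
                u = np.concatenate([uD[oD[i]:oD[i + 1]], uS[oS[i]:oS[i + 1]]])
                s = np.concatenate([sD, sS])
                kD = sD.size
                K = s.size
                if K == 0:
                    continue
                blockQ = np.empty((K, K))
                blockQ[:kD, :kD] = QDD[i]
                blockQ[:kD, kD:] = QDS[i]
                blockQ[kD:, :kD] = QDS[i]
                blockQ[kD:, kD:] = QSS[i]
                omega = np.eye(K) + np.outer(s, s) * blockQ
                if K == 1:
                    vals[i] += float(log_ndtr(u[0] / np.sqrt(omega[0, 0])))
                else:
                    p = mvn_cdf(u, omega, abstol=options.abstol,
                                reltol=options.reltol, n_max=options.n_max)
                    vals[i] += max(np.log(max(p, 0.0)), _LOG_PROB_FLOOR)
    if per_patient:
        return float(vals.sum()), vals
    return float(vals.sum())


def _sum_by_patient(pid: np.ndarray, mat: np.ndarray, N: int) -> np.ndarray:
    out = np.empty((N, mat.shape[1]))
    for k in range(mat.shape[1]):
        out[:, k] = np.bincount(pid, weights=mat[:, k], minlength=N)
    return out


def _batch_inv_sym(mats: np.ndarray) -> np.ndarray:
    if mats.shape[1] == 1:
        return 1.0 / mats
    if mats.shape[1] == 2:
        a, b, c = mats[:, 0, 0], mats[:, 0, 1], mats[:, 1, 1]
        det = a * c - b * b
        out = np.empty_like(mats)
        out[:, 0, 0] = c / det
        out[:, 1, 1] = a / det
        out[:, 0, 1] = out[:, 1, 0] = -b / det
        return out
    return np.linalg.inv(mats)


def _batch_logdet_sym(mats: np.ndarray) -> np.ndarray:
    if mats.shape[1] == 1:
        return np.log(mats[:, 0, 0])
    if mats.shape[1] == 2:
        return np.log(mats[:, 0, 0] * mats[:, 1, 1] - mats[:, 0, 1] ** 2)
    sign, val = np.linalg.slogdet(mats)
    return val


def _loglik_blocks(dataset: Dataset) -> dict:
    """Flat row-wise arrays for vectorized likelihood evaluation, cached on
    the dataset (parameter-independent)."""
    cached = getattr(dataset, "_llb", None)
    if cached is not None:
        return cached
    N = len(dataset)
    q = dataset.spec.q
    pid_y, Xl, Zl, y = [], [], [], []
    pid_D, XD, signs_D = [], [], []
    pid_S, XS, signs_S = [], [], []
    offsets_D, offsets_S = [0], [0]
    for i, p in enumerate(dataset):
        dm = dataset.design(p)
        idx = p.observed_visits - 1
        pid_y.extend([i] * p.n_obs)
        Xl.append(dm["X"][idx])
        Zl.append(dm["Z"][idx])
        y.append(p.y_obs)
        pid_D.extend([i] * p.D_star)
        XD.append(dm["XD"][: p.D_star])
        sD = np.ones(p.D_star)
        if p.delta_D:
            sD[-1] = -1.0
        signs_D.append(sD)
        offsets_D.append(offsets_D[-1] + p.D_star)
        pid_S.extend([i] * p.S_star)
        XS.append(dm["XS"][: p.S_star])
        sS = np.ones(p.S_star)
        if p.delta_S:
            sS[-1] = -1.0
        signs_S.append(sS)
        offsets_S.append(offsets_S[-1] + p.S_star)
    h = dataset.spec.hazards
    pid_y = np.asarray(pid_y, int)
    pid_D = np.asarray(pid_D, int)
    pid_S = np.asarray(pid_S, int)
    Zl = np.vstack(Zl) if Zl else np.zeros((0, q))
    ZtZ = np.zeros((N, q, q))
    np.add.at(ZtZ, pid_y, Zl[:, :, None] * Zl[:, None, :])
    lb = {
        "N": N,
        "pid_y": pid_y,
        "Xl": np.vstack(Xl) if Xl else np.zeros((0, dataset.spec.longitudinal.p)),
        "Zl": Zl,
        "y": np.concatenate(y) if y else np.zeros(0),
        "n_y_i": np.bincount(pid_y, minlength=N).astype(float),
        "ZtZ": ZtZ,
        "pid_D": pid_D,
        "XD": np.vstack(XD) if XD else np.zeros((0, h.p_dropout)),
        "signs_D": np.concatenate(signs_D) if signs_D else np.zeros(0),
        "offsets_D": np.asarray(offsets_D, int),
        "pid_S": pid_S,
        "XS": np.vstack(XS) if XS else np.zeros((0, h.p_death)),
        "signs_S": np.concatenate(signs_S) if signs_S else np.zeros(0),
        "offsets_S": np.asarray(offsets_S, int),
        "WD": h.W_D(q),
        "WS": h.W_S(q),
        "pidD_mu": lambda mu, _p=pid_D: mu[_p],
        "pidS_mu": lambda mu, _p=pid_S: mu[_p],
    }
    # static per-(D*, S*) group structures for the batched orthant path:
    # indices of each patient's rows in the concatenated [uD, uS] vector,
    # sign outer products and process-block indicator patterns
    nD_total = pid_D.size
    by_pattern: dict = {}
    for i, p in enumerate(dataset):
        by_pattern.setdefault((p.D_star, p.S_star), []).append(i)
    groups = []
    oD, oS = lb["offsets_D"], lb["offsets_S"]
    for (dstar, sstar), idx_list in sorted(by_pattern.items()):
        K = dstar + sstar
        idx = np.asarray(idx_list, int)
        rowidx = np.empty((idx.size, K), int)
        signs = np.empty((idx.size, K))
        for g, i in enumerate(idx):
            rowidx[g, :dstar] = np.arange(oD[i], oD[i] + dstar)
            rowidx[g, dstar:] = nD_total + np.arange(oS[i], oS[i] + sstar)
            signs[g, :dstar] = lb["signs_D"][oD[i]:oD[i] + dstar]
            signs[g, dstar:] = lb["signs_S"][oS[i]:oS[i] + sstar]
        m = np.concatenate([np.zeros(dstar), np.ones(sstar)])
        patD = np.outer(1 - m, 1 - m)
        patS = np.outer(m, m)
        patX = np.ones((K, K)) - patD - patS
        groups.append({
            "idx": idx, "K": K, "rowidx": rowidx,
            "ss": signs[:, :, None] * signs[:, None, :],
            "patD": patD, "patX": patX, "patS": patS,
        })
    lb["groups"] = groups
    dataset._llb = lb
    return lb
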