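"""Model specification for the joint longitudinal / semicompeting-risks model.

The model has three linked submodels sharing one vector of random effects
``b_i ~ N(0, Sigma)`` per patient:

* longitudinal:  ``Y_ij = x_ij' beta + z_ij' b_i + eps_ij``, ``eps ~ N(0, sigma2_eps)``
  at scheduled visits ``j = 1..M``;
* dropout hazard: ``P(D_i = j | D_i >= j, b_i) = 1 - Phi(x_D,ij' alpha_D + (W_D b_i)' gamma_D)``;
* death hazard:   ``P(S_i = j | S_i >= j, b_i) = 1 - Phi(x_S,ij' alpha_S + (W_S b_i)' gamma_S)``.

Dropout and death are *semicompeting*: death can censor dropout but death
remains observable (e.g. from registries) after dropout.  Time is discrete —
the continuous follow-up window is partitioned into M intervals, each
containing one scheduled measurement.

The random-effects covariance is parameterized by its modified Cholesky
decomposition ``L Sigma L' = G`` (unit-lower-triangular L with entries
``-lambda_kl``; ``G = diag(sigma2_k)``), so positive innovation variances are
the only constraint needed for positive definiteness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import ndtr

__all__ = [
    "DiscretizationScheme",
    "LongitudinalDesign",
    "HazardDesign",
    "ModelSpec",
    "CholeskyCov",
    "JointParams",
    "PatientRecord",
    "Dataset",
    "build_sigma",
    "recover_cholesky",
    "discretize_time",
    "probit_hazard",
    "hers_scheme",
]


# --------------------------------------------------------------------------
# time discretization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscretizationScheme:
    """Partition of continuous follow-up time [0, T_total] into M visit intervals.

    ``cutpoints`` are the M+1 increasing boundaries, starting at 0.  Interval
    j (1-based) is [cutpoints[j-1], cutpoints[j]), half-open, except the last
    interval which is closed on the right so that the mapping is a surjection
    onto {1..M}.
    """

    cutpoints: tuple

    def __post_init__(self):
        cp = np.asarray(self.cutpoints, dtype=float)
        if cp.ndim != 1 or cp.size < 2:
            raise ValueError("cutpoints must be a 1-d sequence of length >= 2")
        if cp[0] != 0.0:
            raise ValueError("first cutpoint must be 0")
        if np.any(np.diff(cp) <= 0):
            raise ValueError("cutpoints must be strictly increasing")
        object.__setattr__(self, "cutpoints", tuple(cp))

    @property
    def M(self) -> int:
        return len(self.cutpoints) - 1

    @property
    def T_total(self) -> float:
        return self.cutpoints[-1]


def discretize_time(t: float, scheme: DiscretizationScheme) -> int:
    """Map a continuous time to its 1-based visit interval.

    Half-open [left, right) intervals; a time exactly on an interior cutpoint
    belongs to the later interval; T_total belongs to the last interval.
    """
    cp = np.asarray(scheme.cutpoints)
    if t < 0 or t > scheme.T_total:
        raise ValueError(f"time {t} outside [0, {scheme.T_total}]")
    if t == scheme.T_total:
        return scheme.M
    return int(np.searchsorted(cp, t, side="right"))


def hers_scheme() -> DiscretizationScheme:
    """12-interval scheme for a HERS-like design: a first 3-month (91-day)
    interval, then 11 equal 6-month intervals out to 2093 days."""
    cp = [0.0, 91.0] + [91.0 + k * (2093.0 - 91.0) / 11.0 for k in range(1, 12)]
    return DiscretizationScheme(tuple(cp))


# --------------------------------------------------------------------------
# covariate designs
# --------------------------------------------------------------------------

def _resolve_token(token: str, covariates: dict, j: int, M: int) -> float:
    if token in ("1", "const", "intercept"):
        return 1.0
    if token == "visit":
        return float(j)
    if token == "visit_sq":
        return float(j) ** 2
    if token == "visit_frac":
        return j / M
    if token == "visit_frac_sq":
        return (j / M) ** 2
    try:
        return float(covariates[token])
    except KeyError:
        raise KeyError(f"covariate {token!r} not found in patient covariates")


def design_row(spec: Sequence[str], covariates: dict, j: int, M: int) -> np.ndarray:
    """Build one design row from declarative column tokens.

    Tokens: ``"1"`` (intercept), ``"visit"`` (j), ``"visit_sq"``,
    ``"visit_frac"`` (j/M), ``"visit_frac_sq"``, any covariate name, and
    interactions joined by ``:`` (e.g. ``"therapy:visit"``).
    """
    out = np.empty(len(spec))
    for i, token in enumerate(spec):
        val = 1.0
        for part in token.split(":"):
            val *= _resolve_token(part, covariates, j, M)
        out[i] = val
    return out


@dataclass(frozen=True)
class LongitudinalDesign:
    """Declarative fixed/random covariate specification for the outcome model.

    ``fixed`` gives x_ij (length p), ``random`` gives z_ij (length q).  The
    residual structure is iid measurement error with variance sigma2_eps
    (diagonal V_i); serial correlation is carried by the random effects.
    """

    fixed: tuple
    random: tuple = ("1", "visit")

    def __post_init__(self):
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "random", tuple(self.random))
        if len(self.fixed) < 1 or len(self.random) < 1:
            raise ValueError("designs need at least one column (p >= 1, q >= 1)")

    @property
    def p(self) -> int:
        return len(self.fixed)

    @property
    def q(self) -> int:
        return len(self.random)

    def x(self, covariates: dict, j: int, M: int) -> np.ndarray:
        return design_row(self.fixed, covariates, j, M)

    def z(self, covariates: dict, j: int, M: int) -> np.ndarray:
        return design_row(self.random, covariates, j, M)


@dataclass(frozen=True)
class HazardDesign:
    """Covariate specifications for the dropout and death hazard submodels.

    ``w_dropout`` / ``w_death`` map the q random effects into the q^D / q^S
    linear combinations entering each hazard (identity by default).  With
    ``visit_varying_gamma`` the association parameters gamma_j differ by
    visit; by default gamma_j = gamma for all j.
    """

    dropout: tuple
    death: tuple
    w_dropout: np.ndarray | None = None
    w_death: np.ndarray | None = None
    visit_varying_gamma: bool = False

    def __post_init__(self):
        object.__setattr__(self, "dropout", tuple(self.dropout))
        object.__setattr__(self, "death", tuple(self.death))

    @property
    def p_dropout(self) -> int:
        return len(self.dropout)

    @property
    def p_death(self) -> int:
        return len(self.death)

    def W_D(self, q: int) -> np.ndarray:
        return np.eye(q) if self.w_dropout is None else np.asarray(self.w_dropout, float)

    def W_S(self, q: int) -> np.ndarray:
        return np.eye(q) if self.w_death is None else np.asarray(self.w_death, float)

    def x_dropout(self, covariates: dict, j: int, M: int) -> np.ndarray:
        return design_row(self.dropout, covariates, j, M)

    def x_death(self, covariates: dict, j: int, M: int) -> np.ndarray:
        return design_row(self.death, covariates, j, M)


@dataclass(frozen=True)
class ModelSpec:
    """Bundle of the time discretization and the three covariate designs."""

    scheme: DiscretizationScheme
    longitudinal: LongitudinalDesign
    hazards: HazardDesign

    @property
    def M(self) -> int:
        return self.scheme.M

    @property
    def q(self) -> int:
        return self.longitudinal.q


# --------------------------------------------------------------------------
# covariance parameterization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CholeskyCov:
    """Modified Cholesky parameterization of the random-effects covariance.

    ``lam`` holds the generalized autoregressive coefficients as a strictly
    lower-triangular (q x q) array; ``innovation_vars`` the innovation
    variances sigma2_k > 0.  Any real lam with positive innovation variances
    yields a positive definite Sigma.
    """

    lam: np.ndarray
    innovation_vars: np.ndarray

    def __post_init__(self):
        lam = np.atleast_2d(np.asarray(self.lam, dtype=float))
        iv = np.atleast_1d(np.asarray(self.innovation_vars, dtype=float))
        q = iv.size
        if lam.shape != (q, q):
            raise ValueError(f"lam must be ({q},{q}) to match innovation_vars")
        if np.any(np.triu(lam) != 0.0):
            raise ValueError("lam must be strictly lower triangular")
        if np.any(iv <= 0):
            raise ValueError("innovation variances must be positive")
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "innovation_vars", iv)

    @property
    def q(self) -> int:
        return self.innovation_vars.size

    @property
    def sigma(self) -> np.ndarray:
        return build_sigma(self)

    @staticmethod
    def from_sigma(sigma) -> "CholeskyCov":
        return recover_cholesky(sigma)


def build_sigma(cov: CholeskyCov) -> np.ndarray:
    """Sigma = L^-1 G L^-T with unit-lower-triangular L (entries -lambda_kl)
    and G = diag(sigma2_k)."""
    q = cov.q
    L = np.eye(q) - np.tril(cov.lam, -1)
    Linv = solve_triangular(L, np.eye(q), lower=True, unit_diagonal=True)
    sigma = (Linv * cov.innovation_vars) @ Linv.T
    return 0.5 * (sigma + sigma.T)


def recover_cholesky(sigma) -> CholeskyCov:
    """Invert :func:`build_sigma`: sequential least-squares regressions of each
    random effect on its predecessors give the lambda rows and innovation
    variances.  Rejects non-positive-definite input, naming the failing
    leading principal minor."""
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    q = sigma.shape[0]
    if sigma.shape != (q, q) or not np.allclose(sigma, sigma.T, atol=1e-10):
        raise ValueError("sigma must be a symmetric square matrix")
    for k in range(1, q + 1):
        if np.linalg.det(sigma[:k, :k]) <= 0:
            raise ValueError(
                f"sigma is not positive definite: leading principal minor of "
                f"order {k} is non-positive"
            )
    lam = np.zeros((q, q))
    iv = np.empty(q)
    iv[0] = sigma[0, 0]
    for k in range(1, q):
        coefs = np.linalg.solve(sigma[:k, :k], sigma[:k, k])
        lam[k, :k] = coefs
        iv[k] = sigma[k, k] - sigma[k, :k] @ coefs
    return CholeskyCov(lam=lam, innovation_vars=iv)


# --------------------------------------------------------------------------
# parameters and data containers
# --------------------------------------------------------------------------

@dataclass
class JointParams:
    """All unknowns theta of the joint model.

    ``gamma_D`` / ``gamma_S`` are length q^D / q^S vectors, or (M, q^D) /
    (M, q^S) arrays when the hazard design declares visit-varying gamma.
    """

    beta: np.ndarray
    alpha_D: np.ndarray
    gamma_D: np.ndarray
    alpha_S: np.ndarray
    gamma_S: np.ndarray
    sigma2_eps: float
    cov: CholeskyCov

    def __post_init__(self):
        for name in ("beta", "alpha_D", "gamma_D", "alpha_S", "gamma_S"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        if self.sigma2_eps <= 0:
            raise ValueError("sigma2_eps must be positive")

    @property
    def sigma(self) -> np.ndarray:
        return self.cov.sigma

    def gamma_D_at(self, j: int) -> np.ndarray:
        return self.gamma_D[j - 1] if self.gamma_D.ndim == 2 else self.gamma_D

    def gamma_S_at(self, j: int) -> np.ndarray:
        return self.gamma_S[j - 1] if self.gamma_S.ndim == 2 else self.gamma_S

    def validate(self, spec: ModelSpec) -> None:
        d = spec.longitudinal
        h = spec.hazards
        q = d.q
        if self.beta.size != d.p:
            raise ValueError(f"beta has length {self.beta.size}, design p={d.p}")
        if self.cov.q != q:
            raise ValueError(f"cov has dimension {self.cov.q}, design q={q}")
        if self.alpha_D.size != h.p_dropout or self.alpha_S.size != h.p_death:
            raise ValueError("hazard coefficient lengths do not match designs")
        qD, qS = h.W_D(q).shape[0], h.W_S(q).shape[0]
        gD = self.gamma_D if self.gamma_D.ndim == 1 else self.gamma_D[0]
        gS = self.gamma_S if self.gamma_S.ndim == 1 else self.gamma_S[0]
        if gD.size != qD or gS.size != qS:
            raise ValueError("gamma lengths do not match W matrices")


def probit_hazard(linear_predictor: float):
    """Discrete-time probit hazard 1 - Phi(lp): larger linear predictor means
    lower event probability."""
    return 1.0 - ndtr(linear_predictor)


@dataclass
class PatientRecord:
    """One patient's observed longitudinal rows and semicompeting event data.

    ``observed_visits`` is a sorted subset of {1..M} (intermittent gaps
    allowed), all <= D_star.  ``D_star`` = min(D, S, C) with dropout indicator
    ``delta_D``; ``S_star`` = min(S, C) with death indicator ``delta_S``.
    """

    id: object
    observed_visits: np.ndarray
    y_obs: np.ndarray
    D_star: int
    delta_D: int
    S_star: int
    delta_S: int
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        self.observed_visits = np.atleast_1d(np.asarray(self.observed_visits, int))
        self.y_obs = np.atleast_1d(np.asarray(self.y_obs, float))
        self.validate()

    @property
    def n_obs(self) -> int:
        return self.observed_visits.size

    def validate(self, M: int | None = None) -> None:
        v = self.observed_visits
        if v.size != self.y_obs.size:
            raise ValueError(f"patient {self.id}: visits and outcomes differ in length")
        if v.size and (np.any(np.diff(v) <= 0) or v[0] < 1):
            raise ValueError(f"patient {self.id}: observed visits must be sorted, >= 1")
        if self.delta_D not in (0, 1) or self.delta_S not in (0, 1):
            raise ValueError(f"patient {self.id}: event indicators must be 0 or 1")
        if not (1 <= self.D_star <= self.S_star):
            raise ValueError(f"patient {self.id}: need 1 <= D_star <= S_star")
        if v.size and v[-1] > self.D_star:
            raise ValueError(f"patient {self.id}: observed visit after D_star")
        if M is not None and self.S_star > M:
            raise ValueError(f"patient {self.id}: S_star exceeds M={M}")


class Dataset:
    """A list of patient records plus the shared model specification.

    Caches per-patient design matrices (X, Z over all M visits and the two
    hazard designs), which dominate the cost of repeated likelihood calls.
    """

    def __init__(self, patients: Sequence[PatientRecord], spec: ModelSpec):
        self.patients = list(patients)
        self.spec = spec
        ids = [p.id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique")
        for p in self.patients:
            p.validate(M=spec.M)
        self._dm: dict = {}

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def design(self, patient: PatientRecord) -> dict:
        """Full-schedule design matrices for one patient: ``X``/``Z`` are
        (M, p)/(M, q); ``XD``/``XS`` the hazard designs; ``WD``/``WS`` the
        random-effect mapping matrices."""
        key = patient.id
        cached = self._dm.get(key)
        if cached is not None:
            return cached
        M = self.spec.M
        d, h = self.spec.longitudinal, self.spec.hazards
        cov = patient.covariates
        dm = {
            "X": np.array([d.x(cov, j, M) for j in range(1, M + 1)]),
            "Z": np.array([d.z(cov, j, M) for j in range(1, M + 1)]),
            "XD": np.array([h.x_dropout(cov, j, M) for j in range(1, M + 1)]),
            "XS": np.array([h.x_death(cov, j, M) for j in range(1, M + 1)]),
            "WD": h.W_D(d.q),
            "WS": h.W_S(d.q),
        }
        self._dm[key] = dm
        return dm


def validate_dataset(dataset: Dataset) -> None:
    """Re-run all record-level invariants (also done at construction)."""
    ids = [p.id for p in dataset.patients]
    if len(set(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    for p in dataset.patients:
        p.validate(M=dataset.spec.M)
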