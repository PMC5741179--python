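"""Simulate datasets from the joint model with known generating truth.

The generator emulates the structure of a HERS-like cohort: M scheduled
visits, a square-root-CD4-like Gaussian outcome with random intercept and
slope, informative dropout and death hazards driven by those random effects,
independent censoring, and ignorable intermittent missingness.  Defaults are
the cohort's conditions: M = 12 visits, N = 827 patients, intermittent
missingness probability 0.076, and true parameters set to the fitted values
of the motivating analysis (see :func:`hers_like_params`).

Latent event times are drawn by sequential Bernoulli trials over visits
j = 1..M with probit hazards; a patient with no event by visit M gets the
sentinel time M + 1 ("never during follow-up").  Observables follow the
semicompeting-risks mapping: D* = min(D, S, C) with delta_D = 1[D <= C, D <= S],
and S* = min(S, C) with delta_S = 1[S <= C] — death stays observable after
dropout, only censoring (never dropout) hides it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .model_core import (
    CholeskyCov,
    Dataset,
    DiscretizationScheme,
    HazardDesign,
    JointParams,
    LongitudinalDesign,
    ModelSpec,
    PatientRecord,
    hers_scheme,
    recover_cholesky,
)

__all__ = [
    "SimConfig",
    "simulate_patient",
    "simulate_dataset",
    "hers_like_params",
    "hers_like_config",
    "scaled_config",
    "write_dataset",
]

NEVER = "never"  # sentinel meaning M + 1 in truth tables


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    ``censoring_pmf`` is a probability vector over censoring at visits 1..M
    (independent of everything else); the default is administrative censoring
    at M.  ``p_intermittent`` is the iid probability that a pre-truncation
    visit other than the first is skipped (the enrolment measurement is never
    skipped).  With ``obs_at_death_interval`` False no measurement is taken in
    the interval where death terminates follow-up.
    """

    n_patients: int
    spec: ModelSpec
    params: JointParams
    covariate_sampler: Callable[[np.random.Generator], dict]
    censoring_pmf: np.ndarray | None = None
    p_intermittent: float = 0.076
    obs_at_death_interval: bool = False
    mar_on_previous_y: float = 0.0   # optional MAR twist: extra skip prob per
                                     # unit below the previous fitted mean
    seed: int = 0

    def __post_init__(self):
        M = self.spec.M
        if self.censoring_pmf is None:
            pmf = np.zeros(M)
            pmf[-1] = 1.0
            self.censoring_pmf = pmf
        else:
            pmf = np.asarray(self.censoring_pmf, float)
            if pmf.size != M or np.any(pmf < 0) or abs(pmf.sum() - 1.0) > 1e-12:
                raise ValueError("censoring_pmf must be a length-M probability vector")
            self.censoring_pmf = pmf
        if not 0.0 <= self.p_intermittent < 1.0:
            raise ValueError("p_intermittent must be in [0, 1)")
        self.params.validate(self.spec)


def _draw_event_time(
    xmat: np.ndarray, alpha: np.ndarray, gam: np.ndarray, Wb: np.ndarray,
    M: int, rng: np.random.Generator,
) -> int:
    """Sequential Bernoulli draw of a discrete event time; M + 1 if no event."""
    # gam @ Wb is a scalar for visit-constant gamma, a length-M vector when
    # gamma varies by visit; both broadcast against the M linear predictors.
    lps = xmat @ alpha + gam @ Wb
    for j in range(1, M + 1):
        hazard = 1.0 - ndtr(lps[j - 1])
        if rng.random() < hazard:
            return j
    return M + 1


def simulate_patient(
    config: SimConfig, covariates: dict, rng: np.random.Generator, patient_id=0
):
    """Draw one patient: latent (b, complete Y, D, S, C) and the observed
    record.  Returns ``(PatientRecord, truth_dict)``; the truth dict allows
    exact recomputation of every observed field."""
    spec, params = config.spec, config.params
    M = spec.M
    d, h = spec.longitudinal, spec.hazards
    sigma = params.sigma
    b = rng.multivariate_normal(np.zeros(d.q), sigma, method="cholesky")

    X = np.array([d.x(covariates, j, M) for j in range(1, M + 1)])
    Z = np.array([d.z(covariates, j, M) for j in range(1, M + 1)])
    y_complete = X @ params.beta + Z @ b + rng.normal(
        0.0, np.sqrt(params.sigma2_eps), M
    )

    XD = np.array([h.x_dropout(covariates, j, M) for j in range(1, M + 1)])
    XS = np.array([h.x_death(covariates, j, M) for j in range(1, M + 1)])
    D = _draw_event_time(XD, params.alpha_D, params.gamma_D, h.W_D(d.q) @ b, M, rng)
    S = _draw_event_time(XS, params.alpha_S, params.gamma_S, h.W_S(d.q) @ b, M, rng)
    C = int(rng.choice(np.arange(1, M + 1), p=config.censoring_pmf))

    D_star = min(D, S, C)
    delta_D = int(D <= C and D <= S)
    S_star = min(S, C)
    delta_S = int(S <= C)

    visits = list(range(1, D_star + 1))
    death_terminated = (S <= C) and (S <= D) and not config.obs_at_death_interval
    if death_terminated:
        visits = visits[:-1]
    kept = []
    prev_resid = 0.0
    for v in visits:
        if v == 1:
            kept.append(v)
            continue
        p_skip = config.p_intermittent + config.mar_on_previous_y * max(-prev_resid, 0.0)
        if rng.random() >= min(p_skip, 0.99):
            kept.append(v)
        prev_resid = y_complete[v - 1] - X[v - 1] @ params.beta
    kept = np.asarray(kept, int)

    record = PatientRecord(
        id=patient_id,
        observed_visits=kept,
        y_obs=y_complete[kept - 1],
        D_star=D_star,
        delta_D=delta_D,
        S_star=S_star,
        delta_S=delta_S,
        covariates=dict(covariates),
    )
    truth = {
        "id": patient_id,
        "b": b,
        "y_complete": y_complete,
        "D": D,
        "S": S,
        "C": C,
    }
    return record, truth


def simulate_dataset(config: SimConfig):
    """N independent patients from per-patient substreams of the master seed,
    so identical seeds give bit-identical datasets and increasing N does not
    perturb earlier patients.  Returns ``(Dataset, truth DataFrame)``."""
    children = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    records, rows = [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        covs = config.covariate_sampler(rng)
        rec, truth = simulate_patient(config, covs, rng, patient_id=i)
        records.append(rec)
        row = {"id": i, "D": truth["D"], "S": truth["S"], "C": truth["C"]}
        for k, val in enumerate(truth["b"]):
            row[f"b{k + 1}"] = val
        for j, val in enumerate(truth["y_complete"], start=1):
            row[f"y{j}"] = val
        rows.append(row)
    dataset = Dataset(records, config.spec)
    return dataset, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# HERS-like configuration
# --------------------------------------------------------------------------

def hers_like_designs() -> ModelSpec:
    """Covariate designs of the motivating cohort: outcome model with visit
    and baseline (viral-load group, symptoms, therapy) main effects plus their
    visit interactions; both hazards with the baseline covariates and a
    quadratic trend in j/12."""
    # order: intercept, visit, vl dummies, symptoms, therapy, vl:visit x3,
    # symptoms:visit, therapy:visit  (reference group: viral load > 30000)
    fixed = [
        "1", "visit", "vl_low", "vl_mid", "vl_high", "symptoms", "therapy",
        "vl_low:visit", "vl_mid:visit", "vl_high:visit", "symptoms:visit",
        "therapy:visit",
    ]
    hazard = [
        "1", "visit_frac", "visit_frac_sq", "vl_low", "vl_mid", "vl_high",
        "symptoms", "therapy",
    ]
    return ModelSpec(
        scheme=hers_scheme(),
        longitudinal=LongitudinalDesign(fixed=tuple(fixed), random=("1", "visit")),
        hazards=HazardDesign(dropout=tuple(hazard), death=tuple(hazard)),
    )


def hers_like_params() -> JointParams:
    """Generating truth set to the posterior means of the motivating
    analysis (sqrt-CD4 outcome; probit hazards on the j/12 scale)."""
    sigma = _sigma_from_moments(var1=29.120, var2=0.539, corr=-0.305)
    return JointParams(
        beta=np.array([
            15.080, -0.863, 10.040, 6.623, 2.977, -0.115, -4.653,
            0.464, 0.433, 0.273, -0.049, 0.109,
        ]),
        alpha_D=np.array([1.052, 1.190, -1.733, 0.733, 0.650, 0.269, -0.011, -0.043]),
        gamma_D=np.array([0.029, 0.443]),
        alpha_S=np.array([3.472, -4.272, 2.931, 2.032, 1.194, 0.539, -0.121, -0.516]),
        gamma_S=np.array([0.128, 1.192]),
        sigma2_eps=7.304,
        cov=recover_cholesky(sigma),
    )


def _sigma_from_moments(var1: float, var2: float, corr: float) -> np.ndarray:
    off = corr * np.sqrt(var1 * var2)
    return np.array([[var1, off], [off, var2]])


def hers_covariate_sampler(rng: np.random.Generator) -> dict:
    """Baseline covariates loosely mimicking the cohort: a 4-level viral-load
    group (reference = highest), symptom score 0-5, binary therapy."""
    grp = rng.integers(0, 4)
    return {
        "vl_low": float(grp == 0),
        "vl_mid": float(grp == 1),
        "vl_high": float(grp == 2),
        "symptoms": float(rng.binomial(5, 0.25)),
        "therapy": float(rng.random() < 0.35),
    }


def hers_like_config(n_patients: int = 827, seed: int = 0) -> SimConfig:
    """Full-size HERS-like study conditions: M = 12 visits, 827 patients,
    7.6% intermittent missingness, administrative censoring at visit 12."""
    return SimConfig(
        n_patients=n_patients,
        spec=hers_like_designs(),
        params=hers_like_params(),
        covariate_sampler=hers_covariate_sampler,
        p_intermittent=0.076,
        seed=seed,
    )


def scaled_config(n_patients: int = 500, M: int = 6, seed: int = 0) -> SimConfig:
    """Scaled-down simulation-study conditions: M = 6 visits, one binary
    baseline group covariate, true coefficients at the magnitudes of the
    full-size fit.  Used for parameter-recovery experiments where hundreds of
    model fits are needed."""
    cp = tuple(float(182.0 * j) for j in range(M + 1))
    spec = ModelSpec(
        scheme=DiscretizationScheme(cp),
        longitudinal=LongitudinalDesign(
            fixed=("1", "visit", "group", "group:visit"), random=("1", "visit")
        ),
        hazards=HazardDesign(
            dropout=("1", "visit_frac", "visit_frac_sq", "group"),
            death=("1", "visit_frac", "visit_frac_sq", "group"),
        ),
    )
    sigma = _sigma_from_moments(var1=29.120, var2=0.539, corr=-0.305)
    params = JointParams(
        beta=np.array([15.08, -0.863, 6.62, 0.43]),
        alpha_D=np.array([1.05, 1.19, -1.73, 0.65]),
        gamma_D=np.array([0.029, 0.443]),
        alpha_S=np.array([3.47, -4.27, 2.93, 1.19]),
        gamma_S=np.array([0.128, 1.192]),
        sigma2_eps=7.304,
        cov=recover_cholesky(sigma),
    )

    def sampler(rng: np.random.Generator) -> dict:
        return {"group": float(rng.random() < 0.5)}

    return SimConfig(
        n_patients=n_patients,
        spec=spec,
        params=params,
        covariate_sampler=sampler,
        p_intermittent=0.076,
        seed=seed,
    )


# --------------------------------------------------------------------------
# CSV export
# --------------------------------------------------------------------------

def dataset_to_frames(dataset: Dataset):
    """Long-format outcome rows and one-row-per-patient event data."""
    long_rows, event_rows = [], []
    for p in dataset:
        for v, y in zip(p.observed_visits, p.y_obs):
            long_rows.append({"id": p.id, "visit": int(v), "y": y, **p.covariates})
        event_rows.append({
            "id": p.id, "D_star": p.D_star, "delta_D": p.delta_D,
            "S_star": p.S_star, "delta_S": p.delta_S, **p.covariates,
        })
    return pd.DataFrame(long_rows), pd.DataFrame(event_rows)


def params_to_dict(params: JointParams) -> dict:
    return {
        "beta": params.beta.tolist(),
        "alpha_D": params.alpha_D.tolist(),
        "gamma_D": params.gamma_D.tolist(),
        "alpha_S": params.alpha_S.tolist(),
        "gamma_S": params.gamma_S.tolist(),
        "sigma2_eps": float(params.sigma2_eps),
        "lambda": params.cov.lam.tolist(),
        "innovation_vars": params.cov.innovation_vars.tolist(),
    }


def params_from_dict(d: dict) -> JointParams:
    return JointParams(
        beta=np.asarray(d["beta"], float),
        alpha_D=np.asarray(d["alpha_D"], float),
        gamma_D=np.asarray(d["gamma_D"], float),
        alpha_S=np.asarray(d["alpha_S"], float),
        gamma_S=np.asarray(d["gamma_S"], float),
        sigma2_eps=float(d["sigma2_eps"]),
        cov=CholeskyCov(
            lam=np.asarray(d["lambda"], float),
            innovation_vars=np.asarray(d["innovation_vars"], float),
        ),
    )


def write_dataset(dataset: Dataset, out_dir, truth: pd.DataFrame | None = None,
                  config: SimConfig | None = None) -> None:
    """Write ``long.csv``, ``events.csv`` and, when the generating truth is
    known, ``truth.json`` (parameters + seed) and ``truth.csv`` (latents)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    long_df, events_df = dataset_to_frames(dataset)
    long_df.to_csv(out / "long.csv", index=False)
    events_df.to_csv(out / "events.csv", index=False)
    if truth is not None:
        truth.to_csv(out / "truth.csv", index=False)
    if config is not None:
        payload = {
            "seed": config.seed,
            "n_patients": config.n_patients,
            "M": config.spec.M,
            "p_intermittent": config.p_intermittent,
            "params": params_to_dict(config.params),
        }
        (out / "truth.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
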