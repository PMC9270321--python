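"""Seeded synthetic cohorts with known ground truth.

Emulates a complex-survey ageing-cohort baseline: ~9,400 subjects in 70
primary sampling units nested in strata, 19 binary chronic-condition
indicators with pairwise dependence generated from a pairwise binary Markov
random field, hospitalisation near 10% prevalence, readmission counts and
length-of-stay days defined only for hospitalised subjects, and a
missing-at-random mechanism flagging ~6% of rows.  Every draw is fully
determined by the seed, and the generating parameters are returned so each
downstream estimator has a parameter-recovery test surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import _kernels
from .cohort_io import CohortTable, Variable, VariableSchema

#: the 19 chronic conditions carried by the default schema
DISEASE_NAMES = (
    "hypertension",
    "diabetes",
    "high_cholesterol",
    "heart_disease",
    "stroke",
    "asthma",
    "copd",
    "arthritis_rheumatism",
    "osteoporosis",
    "back_problem",
    "cancer",
    "kidney_failure",
    "depression",
    "alzheimer",
    "parkinson",
    "cataract",
    "glaucoma",
    "diabetic_retinopathy",
    "macular_degeneration",
)

AGE_LEVELS = ("50-59", "60-74", "75+")
#: additive threshold shift per age band — older subjects carry more disease
AGE_THRESHOLD_SHIFT = (0.0, 0.3, 0.6)


class CalibrationError(RuntimeError):
    """Prevalence calibration could not be satisfied."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort; the defaults are the study conditions.

    ``n_subjects`` and the 10 strata x 7 PSUs design mirror a baseline of
    9,412 subjects in 70 sampling units; disease prevalence and dependence
    come from the pairwise binary model; hospitalisation is calibrated to
    10% prevalence and 6.4% of rows carry a missing value by default.
    """

    n_subjects: int = 9412
    n_strata: int = 10
    psus_per_stratum: int = 7
    p_diseases: int = 19
    edge_density: float = 0.15
    coupling_range: tuple[float, float] = (0.3, 0.9)
    target_hospitalisation_prevalence: float = 0.10
    missing_fraction: float = 0.064
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_strata < 1 or self.psus_per_stratum < 1:
            raise ValueError("counts must be positive")
        if not 2 <= self.p_diseases <= 19:
            raise ValueError("p_diseases must be in [2, 19]")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ValueError("edge_density must be in [0, 1]")
        if not 0.0 < self.target_hospitalisation_prevalence < 1.0:
            raise ValueError("target prevalence must be in (0, 1)")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")


@dataclass
class TrueParameters:
    """Generating parameters returned alongside a synthetic cohort."""

    theta: np.ndarray
    tau: np.ndarray
    outcome_coefs: dict
    missing_coefs: dict
    stratum_populations: dict
    config: SimulationConfig

    def to_json(self, path) -> None:
        payload = {
            "theta": self.theta.tolist(),
            "tau": self.tau.tolist(),
            "outcome_coefs": self.outcome_coefs,
            "missing_coefs": self.missing_coefs,
            "stratum_populations": self.stratum_populations,
            "config": asdict(self.config),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# pairwise binary samplers


def _validate_ising(theta: np.ndarray, tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    theta = np.asarray(theta, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if theta.ndim != 2 or theta.shape[0] != theta.shape[1]:
        raise ValueError("theta must be a square matrix")
    p = theta.shape[0]
    if tau.shape != (p,):
        raise ValueError("tau length must match theta")
    if not (np.isfinite(theta).all() and np.isfinite(tau).all()):
        raise ValueError("parameters must be finite")
    if not np.allclose(theta, theta.T, atol=1e-12):
        raise ValueError("theta must be symmetric")
    if not np.allclose(np.diag(theta), 0.0, atol=1e-12):
        raise ValueError("theta must have zero diagonal")
    return theta, tau


def enumerate_states(theta: np.ndarray, tau: np.ndarray):
    """All 2^p states and their exact probabilities under the pairwise model."""
    theta, tau = _validate_ising(theta, tau)
    p = len(tau)
    if p > 15:
        raise ValueError(
            f"p={p} too large for state enumeration; use sample_ising_gibbs"
        )
    codes = np.arange(2**p, dtype=np.int64)
    states = ((codes[:, None] >> np.arange(p)) & 1).astype(float)
    energy = states @ tau + 0.5 * np.einsum("si,ij,sj->s", states, theta, states)
    energy -= energy.max()
    probs = np.exp(energy)
    probs /= probs.sum()
    return states.astype(np.int8), probs


def sample_ising_exact(theta, tau, n: int, seed) -> np.ndarray:
    """i.i.d. draws from the exactly normalised pairwise binary distribution.

    Enumerates all ``2^p`` states (refused for ``p > 15``) and samples rows
    from the normalised distribution ``P(x) ∝ exp(Σ τ_i x_i + Σ_{i<j} θ_ij
    x_i x_j)`` with ``x ∈ {0,1}^p``.
    """
    states, probs = enumerate_states(theta, tau)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(probs), size=n, p=probs)
    return states[idx].astype(np.int8)


def sample_ising_gibbs(
    theta, tau, n: int, burn_in: int = 200, thin: int = 10, seed: int = 0
) -> np.ndarray:
    """Single-site Gibbs draws from the pairwise binary model.

    A single chain is swept with full conditionals
    ``P(x_i = 1 | rest) = logistic(τ_i + Σ_j θ_ij x_j)``; one state is kept
    every ``thin`` sweeps after ``burn_in`` sweeps.  Deterministic under the
    seed; scales past the ``p = 15`` enumeration limit of the exact sampler.
    """
    theta, tau = _validate_ising(theta, tau)
    if burn_in < 1 or thin < 1:
        raise ValueError("burn_in and thin must be >= 1")
    seed = int(seed) % (2**32)
    return np.asarray(
        _kernels.gibbs_chain(theta, tau, int(n), int(burn_in), int(thin), seed),
        dtype=np.int8,
    )


# ---------------------------------------------------------------------------
# cohort generation


def default_schema(p_diseases: int = 19) -> VariableSchema:
    """Schema of the synthetic cohort (diseases, covariates, outcomes, design)."""
    variables = [Variable("subject_id", "count", "id")]
    variables += [Variable(d, "binary", "disease") for d in DISEASE_NAMES[:p_diseases]]
    variables += [
        Variable("sex", "categorical", "covariate", levels=("female", "male"), reference="female"),
        Variable("age_group", "categorical", "covariate", levels=AGE_LEVELS, reference="50-59"),
        Variable("residence", "categorical", "covariate", levels=("urban", "rural"), reference="urban"),
        Variable("partner", "categorical", "covariate", levels=("yes", "no"), reference="yes"),
        Variable("hospitalisation", "binary", "outcome"),
        Variable("readmission", "count", "outcome"),
        Variable("length_of_stay", "continuous", "outcome"),
        Variable("stratum", "categorical", "design", subtype="stratum",
                 levels=tuple(f"s{i + 1}" for i in range(40))),
        Variable("psu", "categorical", "design", subtype="psu",
                 levels=tuple(f"psu{i + 1}" for i in range(400))),
        Variable("weight", "continuous", "design", subtype="weight"),
    ]
    return VariableSchema(variables)


#: generative effects (log scale) for the three outcomes
DEFAULT_OUTCOME_COEFS = {
    "hospitalisation": {  # log prevalence-ratio scale
        "sex=male": float(np.log(1.41)),
        "age_group=60-74": float(np.log(1.05)),
        "age_group=75+": float(np.log(1.12)),
        "partner=no": float(np.log(1.21)),
        "residence=rural": float(np.log(1.10)),
        "multimorbidity=2": float(np.log(1.58)),
        "multimorbidity=>=3": float(np.log(2.39)),
    },
    "readmission": {  # log rate scale, excess admissions beyond the first
        "multimorbidity=>=3": 0.50,
        "sex=male": 0.10,
    },
    "length_of_stay": {  # log-days scale
        "sex=male": 0.45,
        "residence=rural": -0.55,
    },
}

DEFAULT_MISSING_COEFS = {
    "age_group=75+": 0.6,
    "sex=male": -0.2,
}

#: lognormal log-scale SD giving mean ~6, SD ~10 days after calibration
LOS_SIGMA = 1.153


def _indicator(df: pd.DataFrame, key: str) -> np.ndarray:
    name, level = key.split("=", 1)
    return (df[name].astype(str) == level).astype(float).to_numpy()


def _linear_predictor(df: pd.DataFrame, coefs: dict) -> np.ndarray:
    eta = np.zeros(len(df))
    for key, c in coefs.items():
        eta += c * _indicator(df, key)
    return eta


def generate_cohort(config: SimulationConfig) -> tuple[CohortTable, TrueParameters]:
    """Draw a full synthetic cohort plus its generating parameters.

    Covariates come from fixed marginals; diseases from the pairwise binary
    model with age-shifted thresholds; hospitalisation is Bernoulli with a
    log-link linear predictor calibrated so the cohort mean equals the target
    prevalence; readmission is ``1 + Poisson`` and length of stay lognormal,
    both only for hospitalised subjects; subjects land in strata x PSUs with
    unequal selection probabilities and weight = inverse inclusion
    probability.  Missingness is injected last when
    ``config.missing_fraction > 0``.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_subjects, config.p_diseases
    schema = default_schema(p)
    diseases = list(DISEASE_NAMES[:p])

    # --- ground-truth disease dependence graph
    theta = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    present = rng.random(len(iu[0])) < config.edge_density
    lo, hi = config.coupling_range
    vals = rng.uniform(lo, hi, size=len(iu[0])) * present
    theta[iu] = vals
    theta = theta + theta.T
    tau = rng.uniform(-4.2, -1.0, size=p)

    # --- covariates
    sex = rng.choice(["female", "male"], size=n, p=[0.537, 0.463])
    age = rng.choice(AGE_LEVELS, size=n, p=[0.483, 0.383, 0.134])
    residence = rng.choice(["urban", "rural"], size=n, p=[0.85, 0.15])
    partner = rng.choice(["yes", "no"], size=n, p=[0.637, 0.363])

    # --- diseases: thresholds shift additively with age band
    X = np.zeros((n, p), dtype=np.int8)
    for band, shift in zip(AGE_LEVELS, AGE_THRESHOLD_SHIFT):
        mask = age == band
        m = int(mask.sum())
        if m == 0:
            continue
        sub_seed = int(rng.integers(2**31))
        if p <= 15:
            draws = sample_ising_exact(theta, tau + shift, m, sub_seed)
        else:
            draws = sample_ising_gibbs(theta, tau + shift, m, burn_in=300, thin=10, seed=sub_seed)
        X[mask] = draws

    df = pd.DataFrame(X, columns=diseases).astype("Float64")
    df.insert(0, "subject_id", np.arange(1, n + 1))
    df["sex"], df["age_group"], df["residence"], df["partner"] = sex, age, residence, partner
    count = X.sum(axis=1)
    mm = np.where(count <= 1, "<=1", np.where(count == 2, "2", ">=3"))
    df["multimorbidity"] = mm

    # --- hospitalisation: log link, intercept calibrated to the target
    coefs = {k: dict(v) for k, v in DEFAULT_OUTCOME_COEFS.items()}
    eta_h = _linear_predictor(df, coefs["hospitalisation"])
    target = config.target_hospitalisation_prevalence
    b0 = float(np.log(target) - np.log(np.mean(np.exp(eta_h))))
    probs = np.exp(b0 + eta_h)
    if probs.max() >= 1.0:
        raise CalibrationError(
            f"prevalence calibration infeasible: max event probability {probs.max():.3f} >= 1"
        )
    coefs["hospitalisation"]["intercept"] = b0
    hosp = (rng.random(n) < probs).astype(float)
    df["hospitalisation"] = hosp

    hmask = hosp == 1
    # --- readmission: 1 + Poisson among hospitalised, mean calibrated to 1.55
    eta_r = _linear_predictor(df, coefs["readmission"])[hmask]
    a0 = float(np.log(0.55) - np.log(np.mean(np.exp(eta_r)))) if hmask.any() else 0.0
    coefs["readmission"]["intercept"] = a0
    readm = np.full(n, np.nan)
    readm[hmask] = 1.0 + rng.poisson(np.exp(a0 + eta_r))
    df["readmission"] = pd.array(readm, dtype="Float64")

    # --- length of stay: lognormal among hospitalised, mean ~6 days
    eta_l = _linear_predictor(df, coefs["length_of_stay"])[hmask]
    mu0 = float(np.log(6.0) - LOS_SIGMA**2 / 2 - np.log(np.mean(np.exp(eta_l)))) if hmask.any() else 0.0
    coefs["length_of_stay"]["intercept"] = mu0
    coefs["length_of_stay"]["sigma"] = LOS_SIGMA
    los = np.full(n, np.nan)
    los[hmask] = np.exp(rng.normal(mu0 + eta_l, LOS_SIGMA))
    df["length_of_stay"] = pd.array(np.round(los, 3), dtype="Float64")

    # --- survey design: strata of near-equal size, uniform PSU within,
    #     per-PSU weight factor in [1, 5] (inverse inclusion probability)
    strata_idx = rng.integers(config.n_strata, size=n)
    psu_within = rng.integers(config.psus_per_stratum, size=n)
    psu_global = strata_idx * config.psus_per_stratum + psu_within
    psu_factor = rng.uniform(1.0, 5.0, size=config.n_strata * config.psus_per_stratum)
    df["stratum"] = [f"s{i + 1}" for i in strata_idx]
    df["psu"] = [f"psu{i + 1}" for i in psu_global]
    df["weight"] = np.round(psu_factor[psu_global], 6)
    stratum_pop = (
        df.groupby("stratum", observed=True)["weight"].sum().round(6).to_dict()
    )

    # shuffle rows so sampler order never aligns with the design
    order = rng.permutation(n)
    df = df.iloc[order].reset_index(drop=True)
    df = df.drop(columns=["multimorbidity"])
    for d in diseases:
        df[d] = df[d].astype("Float64")

    table = CohortTable(df[schema.names()], schema)
    params = TrueParameters(
        theta=theta,
        tau=tau,
        outcome_coefs=coefs,
        missing_coefs=dict(DEFAULT_MISSING_COEFS),
        stratum_populations={k: float(v) for k, v in stratum_pop.items()},
        config=config,
    )
    if config.missing_fraction > 0:
        table = inject_missingness(
            table,
            params.missing_coefs,
            config.missing_fraction,
            seed=int(rng.integers(2**31)),
        )
    return table, params


def inject_missingness(
    table: CohortTable,
    missing_coefs: dict,
    fraction: float,
    seed: int,
    columns: list[str] | None = None,
) -> CohortTable:
    """Flag rows missing-at-random given observed covariates and blank one cell.

    The flag probability is ``logistic(c + Σ missing_coefs·indicator)`` with
    the intercept ``c`` solved so the expected flagged share equals
    ``fraction``; each flagged row has one randomly chosen column from
    ``columns`` (default: the disease columns, keeping covariates complete
    for IPW) blanked.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0.0:
        return table
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    eta = _linear_predictor(df, missing_coefs)

    def gap(c: float) -> float:
        return float(np.mean(expit(c + eta))) - fraction

    c = brentq(gap, -30.0, 30.0)
    flagged = rng.random(len(df)) < expit(c + eta)
    cols = columns if columns is not None else table.schema.disease_names()
    which = rng.integers(len(cols), size=len(df))
    for i in np.flatnonzero(flagged):
        df.loc[df.index[i], cols[which[i]]] = pd.NA
    return CohortTable(df, table.schema)
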