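"""Seeded generator of synthetic household-survey tables.

Each table mimics the structure the analysis pipeline expects: a latent
log-normal wealth score, weighted SES quintiles, categorical covariates
whose distributions shift with the wealth quintile, heterogeneous
probability weights and a Bernoulli "no hunger" outcome drawn from a
logistic model.  The outcome model's intercept is calibrated by bisection so
the weighted prevalence matches a configurable target, and the slope truths
are specified as odds ratios per covariate level.

``DEFAULT_WAVE_CONFIGS`` ships one configuration per emulated survey round
(``wave1`` .. ``wave5`` and ``nfnss``) whose sample sizes, prevalence
targets and odds-ratio gradients follow the published per-round estimates
the generator is meant to emulate.  The quintile-conditional covariate
tables are invented defaults (the source surveys' joint distributions are
not public) and are fully config-exposed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .survey_core import (
    CATEGORICAL_LEVELS,
    OUTCOME,
    WEIGHT,
    SurveyTable,
    weighted_quintiles,
)

__all__ = [
    "GeneratorConfig",
    "DEFAULT_WAVE_CONFIGS",
    "generate_covariates",
    "calibrate_intercept",
    "generate_wave",
    "fixture_table",
]

PROVINCES = [
    "western_cape", "eastern_cape", "northern_cape", "free_state",
    "kwazulu_natal", "north_west", "gauteng", "mpumalanga", "limpopo",
]

# Probability of each covariate level conditional on wealth quintile 1..5.
# Invented defaults: education, formal housing, services and employment all
# improve with the quintile; household size shrinks with it.
_DEFAULT_COVARIATE_MODEL: dict[str, dict[object, list[float]]] = {
    "employment": {
        "not_economically_active": [0.40, 0.35, 0.30, 0.25, 0.20],
        "unemployed": [0.35, 0.33, 0.28, 0.20, 0.10],
        "employed": [0.25, 0.32, 0.42, 0.55, 0.70],
    },
    "race": {
        "black_african": [0.92, 0.90, 0.86, 0.78, 0.55],
        "people_of_colour": [0.05, 0.06, 0.08, 0.10, 0.15],
        "asian_indian": [0.01, 0.01, 0.02, 0.04, 0.08],
        "white": [0.02, 0.03, 0.04, 0.08, 0.22],
    },
    "education": {
        "none": [0.15, 0.10, 0.06, 0.04, 0.02],
        "primary": [0.40, 0.32, 0.22, 0.12, 0.06],
        "secondary": [0.42, 0.52, 0.60, 0.62, 0.47],
        "tertiary": [0.03, 0.06, 0.12, 0.22, 0.45],
    },
    "dwelling": {
        "formal": [0.55, 0.62, 0.72, 0.85, 0.95],
        "traditional": [0.25, 0.20, 0.14, 0.07, 0.02],
        "informal": [0.20, 0.18, 0.14, 0.08, 0.03],
    },
    "electricity": {
        "no": [0.30, 0.22, 0.14, 0.07, 0.02],
        "yes": [0.70, 0.78, 0.86, 0.93, 0.98],
    },
    "piped_water": {
        "no": [0.45, 0.35, 0.22, 0.10, 0.03],
        "yes": [0.55, 0.65, 0.78, 0.90, 0.97],
    },
    "sex": {
        "male": [0.45, 0.47, 0.50, 0.53, 0.58],
        "female": [0.55, 0.53, 0.50, 0.47, 0.42],
    },
}

#: Poisson mean of (household_size - 1) per quintile.
_HH_SIZE_LAMBDA = [4.2, 3.8, 3.4, 2.9, 2.3]


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic survey round."""

    n: int
    target_no_hunger_prevalence: float
    odds_ratios: dict[str, float] = field(default_factory=dict)
    covariate_model: dict = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_COVARIATE_MODEL)
    )
    weight_model: dict = field(
        default_factory=lambda: {"dist": "gamma", "shape": 4.0, "mean": 1.0}
    )
    seed: int = 0
    wave_id: str = "wave1"
    informative_weights: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.target_no_hunger_prevalence < 1:
            raise ValueError("target prevalence must lie in (0, 1)")
        for k, v in self.odds_ratios.items():
            if not v > 0:
                raise ValueError(f"odds ratio for {k!r} must be positive")
        for cov, table in self.covariate_model.items():
            probs = np.asarray(list(table.values()), dtype=float)
            if probs.ndim != 2 or probs.shape[1] != 5:
                raise ValueError(f"covariate model for {cov!r} needs 5 quintile columns")
            if np.any(probs < 0) or not np.allclose(probs.sum(axis=0), 1.0):
                raise ValueError(
                    f"probabilities for {cov!r} must be non-negative and sum to 1"
                )

    def replace(self, **kw) -> "GeneratorConfig":
        new = copy.deepcopy(self)
        for k, v in kw.items():
            setattr(new, k, v)
        new.__post_init__()
        return new


def _wave(or_by_term: dict[str, float], n: int, target: float, wave_id: str
          ) -> GeneratorConfig:
    return GeneratorConfig(
        n=n, target_no_hunger_prevalence=target,
        odds_ratios=dict(or_by_term), wave_id=wave_id,
    )


# Per-round odds-ratio truths for the no-hunger outcome; keys name design
# columns ("term[level]" for dummies).  Rounds where a level was dropped in
# the emulated source estimates carry a neutral 1.0.
DEFAULT_WAVE_CONFIGS: dict[str, GeneratorConfig] = {
    "wave1": _wave({
        "employment[unemployed]": 0.66, "employment[employed]": 0.85,
        "race[people_of_colour]": 1.34, "race[asian_indian]": 2.12,
        "race[white]": 3.67,
        "ses_quintile[2]": 1.06, "ses_quintile[3]": 1.62,
        "ses_quintile[4]": 1.51, "ses_quintile[5]": 3.75,
        "dwelling[traditional]": 0.91, "dwelling[informal]": 0.71,
        "electricity[yes]": 1.33, "piped_water[yes]": 0.89,
        "education[primary]": 1.41, "education[secondary]": 1.94,
        "education[tertiary]": 6.62,
        "sex[female]": 1.03, "household_size": 0.97, "age": 1.01,
    }, 5652, 0.7769, "wave1"),
    "wave2": _wave({
        "employment[unemployed]": 0.65, "employment[employed]": 0.87,
        "race[people_of_colour]": 2.25, "race[asian_indian]": 1.21,
        "race[white]": 7.26,
        "ses_quintile[2]": 1.58, "ses_quintile[3]": 2.00,
        "ses_quintile[4]": 2.67, "ses_quintile[5]": 9.45,
        "dwelling[traditional]": 0.87, "dwelling[informal]": 0.69,
        "electricity[yes]": 0.75, "piped_water[yes]": 0.94,
        "education[primary]": 1.10, "education[secondary]": 1.24,
        "education[tertiary]": 11.46,
        "sex[female]": 1.04, "household_size": 0.98, "age": 0.99,
    }, 4476, 0.8401, "wave2"),
    "wave3": _wave({
        "employment[unemployed]": 1.0, "employment[employed]": 1.0,
        "race[people_of_colour]": 4.01, "race[asian_indian]": 1.0,
        "race[white]": 3.33,
        "ses_quintile[2]": 1.07, "ses_quintile[3]": 1.29,
        "ses_quintile[4]": 1.86, "ses_quintile[5]": 5.29,
        "dwelling[traditional]": 0.56, "dwelling[informal]": 0.57,
        "electricity[yes]": 1.94, "piped_water[yes]": 0.45,
        "education[primary]": 0.49, "education[secondary]": 0.71,
        "education[tertiary]": 0.45,
        "sex[female]": 1.01, "household_size": 0.97, "age": 0.99,
    }, 4429, 0.8159, "wave3"),
    "wave4": _wave({
        "employment[unemployed]": 0.74, "employment[employed]": 0.92,
        "race[people_of_colour]": 1.43, "race[asian_indian]": 2.11,
        "race[white]": 2.04,
        "ses_quintile[2]": 2.69, "ses_quintile[3]": 2.19,
        "ses_quintile[4]": 3.05, "ses_quintile[5]": 11.93,
        "dwelling[traditional]": 0.89, "dwelling[informal]": 0.69,
        "electricity[yes]": 1.08, "piped_water[yes]": 0.91,
        "education[primary]": 2.01, "education[secondary]": 1.89,
        "education[tertiary]": 5.46,
        "sex[female]": 1.00, "household_size": 0.89, "age": 0.99,
    }, 4208, 0.8330, "wave4"),
    "wave5": _wave({
        "employment[unemployed]": 1.11, "employment[employed]": 1.23,
        "race[people_of_colour]": 1.70, "race[asian_indian]": 7.42,
        "race[white]": 5.99,
        "ses_quintile[2]": 1.55, "ses_quintile[3]": 2.02,
        "ses_quintile[4]": 4.96, "ses_quintile[5]": 10.06,
        "dwelling[traditional]": 0.64, "dwelling[informal]": 0.44,
        "electricity[yes]": 1.58, "piped_water[yes]": 1.04,
        "education[primary]": 0.74, "education[secondary]": 0.65,
        "education[tertiary]": 0.90,
        "sex[female]": 1.08, "household_size": 0.91, "age": 1.00,
    }, 4341, 0.8393, "wave5"),
    "nfnss": _wave({
        "employment[unemployed]": 1.38, "employment[employed]": 0.72,
        "race[people_of_colour]": 0.46, "race[asian_indian]": 1.0,
        "race[white]": 0.84,
        "ses_quintile[2]": 2.98, "ses_quintile[3]": 3.46,
        "ses_quintile[4]": 2.90, "ses_quintile[5]": 6.80,
        "dwelling[traditional]": 1.0, "dwelling[informal]": 1.38,
        "electricity[yes]": 1.11, "piped_water[yes]": 1.58,
        "education[primary]": 2.84, "education[secondary]": 3.73,
        "education[tertiary]": 2.56,
        "sex[female]": 1.93, "household_size": 1.15, "age": 0.98,
    }, 30891, 0.9181, "nfnss"),
}

#: Default formula matching the generator's outcome model.
DEFAULT_FORMULA = (
    f"{OUTCOME} ~ employment + race + C(ses_quintile) + dwelling + "
    "electricity + piped_water + education + sex + household_size + age"
)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def generate_covariates(config: GeneratorConfig, seed: int | None = None
                        ) -> SurveyTable:
    """Draw covariates, weights and SES structure (no outcome yet).

    Latent wealth ``z ~ N(0, 1)`` gives ``ses_score = exp(z)``; quintiles
    come from :func:`~hhineq.survey_core.weighted_quintiles`.  Categorical
    covariates are drawn from the quintile-conditional probability tables;
    weights follow the (quintile-independent by default) weight model.
    """
    seed = config.seed if seed is None else seed
    n = config.n
    rng_cov = _rng(seed, 1)
    rng_w = _rng(seed, 2)

    z = rng_cov.standard_normal(n)
    ses_score = np.exp(z)

    wm = config.weight_model
    if wm.get("dist", "gamma") != "gamma":
        raise ValueError("only a gamma weight model is implemented")
    shape = float(wm.get("shape", 4.0))
    mean = float(wm.get("mean", 1.0))
    w = rng_w.gamma(shape, mean / shape, size=n)
    if config.informative_weights:
        # stress-test mode: weights rise for poorer (more rural) households
        w = w * np.exp(-0.5 * z)
        w = w / w.mean() * mean

    q = weighted_quintiles(ses_score, w)

    df = pd.DataFrame({
        "ses_score": ses_score, "ses_quintile": q, WEIGHT: w,
    })
    for cov, table in config.covariate_model.items():
        levels = list(table.keys())
        probs = np.asarray([table[lev] for lev in levels], dtype=float)  # L x 5
        p_row = probs[:, q - 1].T  # n x L
        u = rng_cov.random(n)
        cum = np.cumsum(p_row, axis=1)
        idx = (u[:, None] > cum).sum(axis=1)
        df[cov] = np.asarray(levels, dtype=object)[idx]

    df["household_size"] = 1 + rng_cov.poisson(
        np.asarray(_HH_SIZE_LAMBDA)[q - 1]
    )
    age = rng_cov.normal(45.0, 15.0, size=n)
    while True:
        bad = (age < 18) | (age > 90)
        if not bad.any():
            break
        age[bad] = rng_cov.normal(45.0, 15.0, size=int(bad.sum()))
    df["age"] = np.round(age, 1)
    df["province"] = rng_cov.choice(PROVINCES, size=n)
    df["wave_id"] = config.wave_id
    df[OUTCOME] = np.nan
    return SurveyTable(df)


def _linear_predictor(df: pd.DataFrame, odds_ratios: dict[str, float]
                      ) -> np.ndarray:
    """X @ log(OR) for the generator's design, without the intercept."""
    xb = np.zeros(len(df))
    for key, orat in odds_ratios.items():
        beta = np.log(orat)
        if beta == 0.0:
            continue
        if "[" in key:
            term, level = key[:-1].split("[", 1)
            if term == "ses_quintile":
                x = (df[term].to_numpy() == int(level)).astype(float)
            else:
                x = (df[term].to_numpy() == level).astype(float)
        else:
            x = df[key].to_numpy(dtype=float)
        xb += beta * x
    return xb


def calibrate_intercept(config: GeneratorConfig, covariates) -> float:
    """Intercept making the weighted mean outcome probability hit the target.

    Solves ``sum(w * expit(a + xb)) / sum(w) = target`` by bisection to
    1e-8; the left side is strictly increasing in ``a``.
    """
    df = covariates.data if isinstance(covariates, SurveyTable) else covariates
    xb = _linear_predictor(df, config.odds_ratios)
    w = df[WEIGHT].to_numpy(dtype=float)
    target = config.target_no_hunger_prevalence

    def mean_p(a: float) -> float:
        return float(np.sum(w * expit(a + xb)) / np.sum(w))

    lo, hi = -40.0, 40.0
    if not mean_p(lo) < target < mean_p(hi):
        raise ValueError("target prevalence unattainable for this design")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-8:
            break
    return 0.5 * (lo + hi)


def generate_wave(config: GeneratorConfig, seed: int | None = None
                  ) -> SurveyTable:
    """Full synthetic survey round: covariates, calibrated logistic outcome."""
    seed = config.seed if seed is None else seed
    table = generate_covariates(config, seed)
    a = calibrate_intercept(config, table)
    xb = _linear_predictor(table.data, config.odds_ratios)
    p = expit(a + xb)
    rng_out = _rng(seed, 3)
    table.data[OUTCOME] = (rng_out.random(config.n) < p).astype(float)
    return table


def fixture_table(seed: int = 0, n: int = 200) -> SurveyTable:
    """Small deterministic table for tests and pipeline smoke runs."""
    cfg = DEFAULT_WAVE_CONFIGS["wave1"].replace(n=n, seed=seed)
    return generate_wave(cfg, seed)
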