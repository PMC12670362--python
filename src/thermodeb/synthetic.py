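"""Synthetic factorial growth experiment emulating the *Daphnia* study design.

The design crosses two mean temperatures (20, 28 degC), two thermal-variance
regimes (constant vs. +/-5 degC square wave), two food concentrations
(3 vs. 0.4 mgC/L) and two food qualities (high vs. low), with 4 replicate
jars of 8 individuals per treatment (16 treatments, 512 individuals).

For each treatment the deterministic model prediction is the expected
phenotype; individual observations are the prediction times a multiplicative
lognormal deviation composed of a jar-level random effect and individual
noise.  Ages are rounded to the daily census.  The treatments combining the
high temperature with low food quantity AND low quality are emitted as
died-before-maturity, the only cells where mortality occurred.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from .deb import DEBError, DEBParameters
from .forcing import EnvironmentSpec, NutritionContext, ThermalRegime
from .simulate import LifeHistoryResult, simulate_individual

TEMPERATURES = (20.0, 28.0)
AMPLITUDES = (0.0, 5.0)
FOOD_LEVELS = (3.0, 0.4)
QUALITY_LEVELS = {"high": 1.0, "low": 0.0}
N_JARS = 4
N_INDIVIDUALS = 8

#: default observation-noise coefficients (multiplicative, lognormal)
NOISE_CV = 0.1
JAR_SD = 0.05

COLUMNS = ["tmean_C", "amplitude_C", "food_mgC_L", "quality",
           "jar", "individual", "mass_ug", "age_d", "growth_d", "died"]


def treatments() -> list[tuple[float, float, float, str]]:
    """The 16 factorial treatment combinations."""
    return [
        (T, A, X, q)
        for T, A, X, q in itertools.product(
            TEMPERATURES, AMPLITUDES, FOOD_LEVELS, QUALITY_LEVELS)
    ]


def is_mortality_cell(tmean: float, food: float, quality: str) -> bool:
    """True for the high-temperature, low-food, low-quality treatments."""
    return tmean == max(TEMPERATURES) and food == min(FOOD_LEVELS) and quality == "low"


def predict_treatments(params: DEBParameters) -> dict[tuple, LifeHistoryResult]:
    """Deterministic model prediction for every treatment."""
    out = {}
    for T, A, X, q in treatments():
        env = EnvironmentSpec(ThermalRegime(T, A),
                              NutritionContext(X, QUALITY_LEVELS[q]))
        out[(T, A, X, q)] = simulate_individual(params, env)
    return out


def generate_experiment(
    params: DEBParameters,
    noise_cv: float = NOISE_CV,
    jar_sd: float = JAR_SD,
    seed: int = 0,
    census_rounding: bool = True,
    predictions: dict[tuple, LifeHistoryResult] | None = None,
) -> pd.DataFrame:
    """Generate one synthetic observed-trait table.

    Parameters
    ----------
    noise_cv
        Coefficient of variation of individual multiplicative noise; the
        lognormal sigma is ``sqrt(log(1 + cv^2))`` so the geometric spread
        matches the requested CV.
    jar_sd
        Standard deviation of the jar-level lognormal random effect.
    seed
        Seed of the generator; identical seeds give identical tables.
    census_rounding
        Round ages to the nearest whole day (minimum 1), reflecting the
        daily census of the emulated protocol.
    predictions
        Optional precomputed treatment predictions (for repeated draws).

    Raises
    ------
    DEBError
        If the model fails to mature in a treatment outside the designated
        mortality cells: the parameterisation is then inconsistent with the
        emulated design.
    """
    if noise_cv < 0 or jar_sd < 0:
        raise DEBError("noise_cv and jar_sd must be non-negative")
    rng = np.random.default_rng(seed)
    if predictions is None:
        predictions = predict_treatments(params)
    sigma = math.sqrt(math.log(1.0 + noise_cv ** 2))

    rows = []
    for key in treatments():
        T, A, X, q = key
        pred = predictions[key]
        dead = is_mortality_cell(T, X, q)
        if not dead and not pred.matured:
            raise DEBError(
                f"model failed to mature in non-mortality treatment {key}: "
                f"{pred.failure_reason}"
            )
        for jar in range(1, N_JARS + 1):
            jar_eff = rng.normal(0.0, jar_sd) if jar_sd > 0 else 0.0
            for ind in range(1, N_INDIVIDUALS + 1):
                if dead:
                    rows.append((T, A, X, q, jar, ind,
                                 np.nan, np.nan, np.nan, True))
                    continue
                e_mass = rng.normal(0.0, sigma) if sigma > 0 else 0.0
                e_age = rng.normal(0.0, sigma) if sigma > 0 else 0.0
                mass = pred.mass_maturity * math.exp(jar_eff + e_mass)
                age = pred.age_maturity_observed * math.exp(jar_eff + e_age)
                if census_rounding:
                    age = max(1.0, float(round(age)))
                growth = math.log(mass / params.m0) / age
                rows.append((T, A, X, q, jar, ind, mass, age, growth, False))
    return pd.DataFrame(rows, columns=COLUMNS)
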