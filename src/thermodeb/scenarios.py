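"""Covariation scenarios: age-size phase-space trajectories under warming.

A scenario walks a window of mean temperatures while one or more context
factors (food concentration, food-quality level, diurnal thermal amplitude)
drift linearly with the accumulated warming.  Each point of the trajectory
is a full life-history simulation in a static environment; the endpoint
response type is classified from the endpoint-minus-start trait differences
using the same sign conventions as the grid classifier.

The canonical windows span the lower, middle and upper portions of the
thermal performance curve (8-12, 18-22 and 24-28 degC) with baselines
X = 1 mgC/L, median food quality and 2.5 degC amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .deb import DEBError, DEBParameters
from .forcing import (
    CovariationRule,
    EnvironmentSpec,
    NutritionContext,
    ThermalRegime,
    apply_rules,
)
from .patterns import classify_cell
from .simulate import LifeHistoryResult, simulate_individual

#: the three canonical temperature windows (degC)
WINDOWS = ((8.0, 12.0), (18.0, 22.0), (24.0, 28.0))

#: scenario baselines
BASELINE_X = 1.0
BASELINE_QUALITY = 0.5
BASELINE_AMPLITUDE = 2.5

#: default trajectory resolution: 0.5 degC spacing over a 4 degC window
DEFAULT_N_POINTS = 9


@dataclass
class ScenarioTrajectory:
    """Ordered life-history responses along a warming trajectory."""

    temperatures: np.ndarray
    environments: list[EnvironmentSpec]
    results: list[LifeHistoryResult]
    rules: list[CovariationRule]
    endpoint_label: str
    complete: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for T, env, res in zip(self.temperatures, self.environments, self.results):
            mass, age, g = res.traits
            rows.append({
                "T_mean": T,
                "X": env.nutrition.X,
                "quality": env.nutrition.quality_level,
                "amplitude": env.thermal.amplitude,
                "age_d": age,
                "mass_ug": mass,
                "growth_d": g,
                "matured": res.matured,
            })
        frame = pd.DataFrame(rows)
        frame["label"] = self.point_labels()
        return frame

    def point_labels(self) -> list[str]:
        """Local-slope classification at each trajectory point.

        Complements the endpoint label: central differences of the
        median-normalised traits along the warming axis, classified with the
        grid semantics.
        """
        traits = np.array([r.traits for r in self.results])  # (n, 3)
        med = np.nanmedian(traits, axis=0)
        labels = []
        slopes = np.full_like(traits, np.nan)
        for k in range(3):
            slopes[:, k] = np.gradient(traits[:, k], self.temperatures) / med[k]
        for i, res in enumerate(self.results):
            if not res.matured:
                labels.append("no-maturity")
            else:
                labels.append(classify_cell(*slopes[i]))
        return labels


def baseline_environment(T_mean: float) -> EnvironmentSpec:
    """Scenario baseline context at a given mean temperature."""
    return EnvironmentSpec(
        ThermalRegime(T_mean=T_mean, amplitude=BASELINE_AMPLITUDE),
        NutritionContext(X=BASELINE_X, quality_level=BASELINE_QUALITY),
    )


def run_scenario(
    params: DEBParameters,
    window: tuple[float, float],
    rules: list[CovariationRule] | None = None,
    n_points: int = DEFAULT_N_POINTS,
    baseline: EnvironmentSpec | None = None,
) -> ScenarioTrajectory:
    """Simulate a warming trajectory with covarying context factors.

    For each mean temperature T in the window, every rule's factor is set to
    ``baseline * (1 + rate * (T - T_start) / 100)`` and one individual is
    simulated in the resulting static environment.  An empty rule list is
    the no-covariation reference arrow.
    """
    T_start, T_end = window
    if not T_end > T_start:
        raise DEBError("window must satisfy T_end > T_start")
    rules = list(rules or [])
    temperatures = np.linspace(T_start, T_end, n_points)

    envs, results = [], []
    for T in temperatures:
        env0 = baseline if baseline is not None else baseline_environment(T_start)
        env = apply_rules(env0, rules, delta_T=float(T - T_start))
        env = EnvironmentSpec(replace(env.thermal, T_mean=float(T)), env.nutrition)
        envs.append(env)
        results.append(simulate_individual(params, env))

    complete = all(r.matured for r in results)
    label = "incomplete"
    if results[0].matured and results[-1].matured:
        m0, a0, g0 = results[0].traits
        m1, a1, g1 = results[-1].traits
        span = T_end - T_start
        # endpoint-to-endpoint differences on median-normalised traits
        med = [np.nanmedian([r.traits[k] for r in results if r.matured])
               for k in range(3)]
        label = classify_cell((m1 - m0) / span / med[0],
                              (a1 - a0) / span / med[1],
                              (g1 - g0) / span / med[2])
    return ScenarioTrajectory(temperatures, envs, results, rules, label, complete)


def load_scenario(path) -> dict:
    """Load a scenario description file (TOML or YAML).

    Recognised keys: ``window`` ([T_start, T_end], degC), optional baselines
    ``X``, ``quality``, ``amplitude``, and ``rules`` as a mapping of factor
    name (X | quality | amplitude) to rate in percent per degC.  Returns
    keyword arguments for :func:`run_scenario`.
    """
    from pathlib import Path

    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    if "window" not in raw:
        raise DEBError("scenario file must define a temperature window")
    window = tuple(float(x) for x in raw["window"])
    baselines = {
        "X": float(raw.get("X", BASELINE_X)),
        "quality_level": float(raw.get("quality", BASELINE_QUALITY)),
        "amplitude": float(raw.get("amplitude", BASELINE_AMPLITUDE)),
    }
    names = {"X": "X", "quality": "quality_level", "amplitude": "amplitude"}
    rules = [
        CovariationRule(names.get(k, k), float(rate), baselines[names.get(k, k)])
        for k, rate in (raw.get("rules") or {}).items()
    ]
    baseline = EnvironmentSpec(
        ThermalRegime(window[0], baselines["amplitude"]),
        NutritionContext(baselines["X"], baselines["quality_level"]),
    )
    return {"window": window, "rules": rules, "baseline": baseline}


def growth_isocline(g: float, m0: float, ages) -> np.ndarray:
    """Mass along an iso-growth-rate curve: ``m(age) = m0 * exp(g * age)``.

    The inversion of the juvenile specific growth rate definition; the point
    (age, mass) of any matured individual lies exactly on the isocline of
    its own growth rate.
    """
    if g < 0:
        raise DEBError("growth isoclines are defined for g >= 0")
    if m0 <= 0:
        raise DEBError("neonate mass must be positive")
    return m0 * np.exp(g * np.asarray(ages, dtype=float))
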