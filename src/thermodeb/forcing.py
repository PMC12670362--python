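"""Environmental forcing: thermal regimes, nutrition and covariation rules.

Temperature is forced either constant or as a diurnal square wave
``T(t) = T_mean + A * sgn(sin(2 pi t / period))`` (warm half-period first).
Food quality acts on the organism through its maintenance costs: the quality
level in [0, 1] maps linearly onto the somatic maintenance rate ``p_M``
(330-740 J cm^-3 d^-1) and the maturity maintenance coefficient ``k_j``
(0.05-0.1 d^-1), with quality 1 the low-cost high-quality endpoint.
Covariation rules couple a context factor to warming at a fixed linear rate
in percent per degC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .deb import DEBError

#: food-quality endpoints for (p_M, k_j): quality 1 -> low cost, 0 -> high cost
P_M_RANGE = (330.0, 740.0)
K_J_RANGE = (0.05, 0.1)

#: default magnitude bound on covariation rates, % per degC
MAX_COVARIATION_RATE = 6.25

COVARIABLE_FACTORS = ("X", "quality_level", "amplitude")


@dataclass(frozen=True)
class ThermalRegime:
    """Constant or diurnal square-wave temperature forcing (degC)."""

    T_mean: float
    amplitude: float = 0.0
    period: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise DEBError("amplitude must be non-negative")
        if self.period <= 0:
            raise DEBError("period must be positive")


@dataclass(frozen=True)
class NutritionContext:
    """Food concentration (mgC L^-1) and quality level in [0, 1].

    ``maintenance`` optionally pins the quality-driven costs (p_M, k_j)
    directly, taking precedence over ``quality_level``; covariation
    scenarios use it because their quality rules act on the cost scale.
    """

    X: float
    quality_level: float | None = 1.0
    maintenance: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.X < 0:
            raise DEBError("food concentration X must be non-negative")
        if self.quality_level is not None and not 0.0 <= self.quality_level <= 1.0:
            raise DEBError("quality_level must lie in [0, 1]")

    def maintenance_costs(self) -> tuple[float, float] | None:
        """Effective (p_M, k_j), or None to use the parameter set as given."""
        if self.maintenance is not None:
            return self.maintenance
        if self.quality_level is None:
            return None
        return quality_to_maintenance(self.quality_level)


@dataclass(frozen=True)
class EnvironmentSpec:
    """Full environment of one life-history run."""

    thermal: ThermalRegime
    nutrition: NutritionContext

    @classmethod
    def constant(cls, T_mean: float, X: float, quality_level: float = 1.0,
                 amplitude: float = 0.0, period: float = 1.0) -> "EnvironmentSpec":
        return cls(ThermalRegime(T_mean, amplitude, period),
                   NutritionContext(X, quality_level))


@dataclass(frozen=True)
class CovariationRule:
    """Linear coupling of one context factor to warming.

    ``rate`` is the percent change of the factor per degC of warming above
    the scenario's starting temperature; accumulation is linear, not
    compounding, so 6.25 % per degC over 4 degC is exactly 25 %.
    """

    factor: str
    rate: float
    baseline: float
    max_rate: float = MAX_COVARIATION_RATE

    def __post_init__(self) -> None:
        if self.factor not in COVARIABLE_FACTORS:
            raise DEBError(
                f"factor must be one of {COVARIABLE_FACTORS}, got {self.factor!r}"
            )
        if abs(self.rate) > self.max_rate:
            raise DEBError(
                f"|rate| = {abs(self.rate)} exceeds bound {self.max_rate} %/degC"
            )


def temperature_at(regime: ThermalRegime, t: float) -> float:
    """Instantaneous temperature (degC) of a square-wave regime at time t (d).

    The warm half-period comes first; with zero amplitude the mean is
    returned for all t.  Exact half-period multiples sit on the
    discontinuity and return the warm level by convention.
    """
    if t < 0:
        raise DEBError("time must be non-negative")
    if regime.amplitude == 0:
        return regime.T_mean
    phase = math.fmod(t / regime.period, 1.0)
    sign = 1.0 if phase < 0.5 else -1.0
    return regime.T_mean + regime.amplitude * sign


def discontinuity_times(regime: ThermalRegime, t0: float, t1: float) -> np.ndarray:
    """Square-wave switching times in (t0, t1), exposed to the ODE solver."""
    if regime.amplitude == 0:
        return np.empty(0)
    half = regime.period / 2.0
    first = math.floor(t0 / half) + 1
    last = math.ceil(t1 / half) - 1
    times = np.arange(first, last + 1) * half
    return times[(times > t0) & (times < t1)]


def covary_factor(rule: CovariationRule, delta_T: float) -> float:
    """Factor value after ``delta_T`` degC of warming under a linear rule.

    Negative projections are clamped to zero with a warning (a factor cannot
    go negative, but the linear rule can formally cross zero).
    """
    value = rule.baseline * (1.0 + rule.rate * delta_T / 100.0)
    if value < 0:
        warnings.warn(
            f"covariation drove {rule.factor} negative; clamping to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return value


def quality_to_maintenance(quality_level: float) -> tuple[float, float]:
    """Map a food-quality level in [0, 1] to maintenance costs (p_M, k_j).

    Quality 1 is the high-quality (*Cryptomonas*-like) endpoint with the low
    costs (330, 0.05); quality 0 the low-quality (*Synechococcus*-like)
    endpoint (740, 0.1); interpolation is linear.
    """
    if not 0.0 <= quality_level <= 1.0:
        raise DEBError("quality_level must lie in [0, 1]")
    p_lo, p_hi = P_M_RANGE
    k_lo, k_hi = K_J_RANGE
    p_M = p_hi - quality_level * (p_hi - p_lo)
    k_j = k_hi - quality_level * (k_hi - k_lo)
    return p_M, k_j


def apply_rules(
    env: EnvironmentSpec, rules: list[CovariationRule], delta_T: float
) -> EnvironmentSpec:
    """Environment after applying every covariation rule at ``delta_T``.

    Food quantity and thermal amplitude covary on their own scales.  The
    quality rule covaries the quality-*controlled* quantities, i.e. the
    maintenance costs: a quality decline of r percent per degC raises p_M
    and k_j by r percent per degC (clamped to the admissible quality range).
    """
    thermal, nutrition = env.thermal, env.nutrition
    for rule in rules:
        if rule.factor == "X":
            nutrition = replace(nutrition, X=covary_factor(rule, delta_T))
        elif rule.factor == "quality_level":
            costs = nutrition.maintenance_costs()
            if costs is None:
                raise DEBError("quality covariation needs a quality baseline")
            scale = 1.0 - rule.rate * delta_T / 100.0  # quality down = costs up
            p_M = min(max(costs[0] * scale, P_M_RANGE[0]), P_M_RANGE[1])
            k_j = min(max(costs[1] * scale, K_J_RANGE[0]), K_J_RANGE[1])
            nutrition = replace(nutrition, maintenance=(p_M, k_j))
        else:
            thermal = replace(thermal, amplitude=covary_factor(rule, delta_T))
    return EnvironmentSpec(thermal, nutrition)
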