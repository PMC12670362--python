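"""Core Dynamic Energy Budget (DEB) model with relaxed thermal assumptions.

The organism is described by three state variables: reserve energy ``E`` (J),
structural volume ``V`` (cm^3) and the cumulative maturity investment /
reproductive buffer ``R`` (J).  Assimilated energy enters the reserve, is
mobilised at a rate set by the energy conductance, and is split by the
allocation fraction ``kappa`` between soma (growth + somatic maintenance) and
development/reproduction (maturity maintenance + maturation).

Two departures from standard DEB theory drive the thermal life-history
patterns this package studies:

* uptake follows a unimodal Sharpe--Schoolfield temperature response
  (activation + high-temperature deactivation) while all other physiological
  rates (conductance, somatic and maturity maintenance) follow a monotone
  Arrhenius response, so the uptake/maintenance balance degrades near and
  above the deactivation temperature;
* the allocation fraction ``kappa`` is itself a decreasing sigmoid of
  temperature between ``kappa_max`` (cold) and ``kappa_min`` (warm), so warm
  animals route proportionally more mobilised energy to development.

Maturation is threshold-driven: puberty occurs at the first instant both the
cumulative maturity energy ``R >= R_p`` and a minimal structural volume
``V >= V_p`` are satisfied.  Eggs appear in the brood pouch only after a
temperature-dependent first adult-instar delay, which is what an observer
scores as maturity.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

CELSIUS_TO_KELVIN = 273.15

#: admissible intervals used by config validation (overridable per load)
P_M_ADMISSIBLE = (330.0, 740.0)
K_J_ADMISSIBLE = (0.05, 0.1)


class DEBError(ValueError):
    """Invalid parameter, state or input for a DEB computation."""


class Stage(enum.Enum):
    """Life stage, ordered; transitions are monotone forward."""

    JUVENILE = "juvenile"
    MATURE_AWAITING_CLUTCH = "mature_awaiting_clutch"
    POST_CLUTCH = "post_clutch"
    FAILED = "failed"


_STAGE_ORDER = {
    Stage.JUVENILE: 0,
    Stage.MATURE_AWAITING_CLUTCH: 1,
    Stage.POST_CLUTCH: 2,
    Stage.FAILED: 3,
}


@dataclass(frozen=True)
class DEBParameters:
    """Rate, threshold and conversion constants of the bioenergetic model.

    Rates are expressed at the reference temperature ``T_star`` and scaled at
    run time by the thermal correction factors.  Defaults are parameterised
    for *Daphnia magna* from the published DEB literature for that species.

    Attributes
    ----------
    p_AM : float
        Maximum surface-specific uptake rate, J cm^-2 d^-1 at ``T_star``.
    ks : float
        Half-saturation food concentration, mgC L^-1.
    v_dot : float
        Energy conductance, cm d^-1 at ``T_star``.
    E_G : float
        Volume-specific cost of structure, J cm^-3.
    p_M : float
        Volume-specific somatic maintenance rate at ``T_star``,
        J cm^-3 d^-1.  Food-quality dependent (high quality = low cost).
    k_j : float
        Maturity/reproduction maintenance coefficient at ``T_star``, d^-1.
        Food-quality dependent.
    kappa_min, kappa_max : float
        Bounds of the temperature-dependent allocation fraction.
    T_hat : float
        Inflexion temperature of the kappa sigmoid, degC.
    lambda_ : float
        Stiffness of the kappa sigmoid, degC^-1 (0 recovers a constant
        allocation fraction).
    R_p : float
        Cumulative maturity energy threshold for puberty, J.
    V_p : float
        Minimal structural volume threshold for puberty, cm^3.
    E_a, E_d : float
        Activation / deactivation energies, eV.
    T_d : float
        Temperature of 50% uptake deactivation, K.
    T_star : float
        Reference temperature, K (293.15 K = 20 degC).
    k_B : float
        Boltzmann constant, eV K^-1.
    delta_star : float
        First adult-instar duration at ``T_star``, d.
    d_m : float
        Structural dry-mass density, ug cm^-3.
    d_e : float
        Reserve/clutch energy density, J ug^-1.
    m0 : float
        Neonate dry mass, ug (sets the initial state and the denominator of
        the juvenile specific growth rate).
    e0_frac : float
        Fraction of neonate dry mass carried as reserve at birth.
    horizon_days : float
        Simulation horizon, d; failing to lay a clutch within it marks the
        individual as failed.
    delta_convention : str
        ``"as_printed"`` (default): the instar delay scales with the
        Arrhenius factor, ``delta_star * qM(T)``.  ``"rate_scaled"``: the
        delay shortens with warming like other physiological times,
        ``delta_star / qM(T)``.  Both equal ``delta_star`` at ``T_star``;
        only the default reproduces the cold-end reverse-TSR region (the
        delay-window growth term is the positive mass-slope contribution).
    adult_maintenance : str
        ``"buffer"`` (default): maturity maintenance keeps acting on the full
        buffer ``R`` after puberty; ``"frozen"``: it acts on the frozen
        maturity level ``R_p`` only.
    standard_deb : bool
        If True, uptake uses the Arrhenius factor too (all rates share one
        thermal scaling), recovering the classic single-scaling DEB model.
    """

    p_AM: float = 200.0
    ks: float = 0.3
    v_dot: float = 0.12
    E_G: float = 1200.0
    p_M: float = 330.0
    k_j: float = 0.05
    kappa_min: float = 0.6
    kappa_max: float = 0.7
    T_hat: float = 22.0
    lambda_: float = 2.8
    R_p: float = 1.2
    V_p: float = 1.5e-4
    E_a: float = 0.65
    E_d: float = 1.89
    T_d: float = 302.15
    T_star: float = 293.15
    k_B: float = 8.617e-5
    delta_star: float = 2.0
    d_m: float = 19e4
    d_e: float = 25e-3
    m0: float = 7.0
    e0_frac: float = 0.35
    horizon_days: float = 100.0
    delta_convention: str = "as_printed"
    adult_maintenance: str = "buffer"
    standard_deb: bool = False
    p_M_bounds: tuple = P_M_ADMISSIBLE
    k_j_bounds: tuple = K_J_ADMISSIBLE

    def __post_init__(self) -> None:
        positive = (
            "p_AM", "ks", "v_dot", "E_G", "p_M", "k_j", "R_p", "V_p",
            "E_a", "E_d", "T_d", "T_star", "k_B", "delta_star", "d_m",
            "d_e", "m0", "horizon_days",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise DEBError(f"{name} must be strictly positive")
        if not 0 < self.kappa_min <= self.kappa_max < 1:
            raise DEBError("require 0 < kappa_min <= kappa_max < 1")
        if self.lambda_ < 0:
            raise DEBError("lambda_ must be non-negative")
        if not 0 <= self.e0_frac < 1:
            raise DEBError("e0_frac must lie in [0, 1)")
        lo, hi = self.p_M_bounds
        if not lo <= self.p_M <= hi:
            raise DEBError(f"p_M={self.p_M} outside admissible [{lo}, {hi}]")
        lo, hi = self.k_j_bounds
        if not lo <= self.k_j <= hi:
            raise DEBError(f"k_j={self.k_j} outside admissible [{lo}, {hi}]")
        if self.delta_convention not in ("rate_scaled", "as_printed"):
            raise DEBError("delta_convention must be rate_scaled|as_printed")
        if self.adult_maintenance not in ("buffer", "frozen"):
            raise DEBError("adult_maintenance must be buffer|frozen")

    # -- config I/O ---------------------------------------------------------

    #: flat config keys (Table-style symbols) -> dataclass field names
    _CONFIG_KEYS = {
        "p_AM": "p_AM", "ks": "ks", "v": "v_dot", "v_dot": "v_dot",
        "E_G": "E_G", "p_M": "p_M", "k_j": "k_j",
        "kappa_min": "kappa_min", "kappa_max": "kappa_max",
        "T_hat": "T_hat", "lambda": "lambda_", "lambda_": "lambda_",
        "R_p": "R_p", "V_p": "V_p", "E_a": "E_a", "E_d": "E_d",
        "T_d": "T_d", "T_star": "T_star", "k_B": "k_B",
        "delta_star": "delta_star", "d_m": "d_m", "d_e": "d_e",
        "m0": "m0", "e0_frac": "e0_frac", "horizon_days": "horizon_days",
        "delta_convention": "delta_convention",
        "adult_maintenance": "adult_maintenance",
        "standard_deb": "standard_deb",
    }

    @classmethod
    def from_dict(cls, mapping: dict) -> "DEBParameters":
        """Build parameters from a flat key->value mapping.

        Unknown keys are rejected so typos in a config file fail loudly.
        """
        kwargs = {}
        unknown = sorted(set(mapping) - set(cls._CONFIG_KEYS))
        if unknown:
            raise DEBError(f"unknown parameter keys: {', '.join(unknown)}")
        for key, value in mapping.items():
            kwargs[cls._CONFIG_KEYS[key]] = value
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "DEBParameters":
        """Load parameters from a flat TOML or YAML file."""
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            with open(path) as fh:
                mapping = yaml.safe_load(fh) or {}
        else:
            import tomllib

            with open(path, "rb") as fh:
                mapping = tomllib.load(fh)
        return cls.from_dict(mapping)

    def with_quality(self, p_M: float, k_j: float) -> "DEBParameters":
        """Return a copy with food-quality-dependent maintenance costs."""
        return replace(self, p_M=p_M, k_j=k_j)


@dataclass
class OrganismState:
    """Instantaneous physiological state of one individual."""

    E: float
    V: float
    R: float
    stage: Stage = Stage.JUVENILE
    t_maturity: float | None = None

    def __post_init__(self) -> None:
        if self.E < 0 or self.V <= 0 or self.R < 0:
            raise DEBError("require E >= 0, V > 0, R >= 0")

    def advance_stage(self, new: Stage) -> None:
        if _STAGE_ORDER[new] < _STAGE_ORDER[self.stage]:
            raise DEBError(
                f"stage transition {self.stage.value} -> {new.value} goes backwards"
            )
        self.stage = new


def neonate_state(params: DEBParameters) -> OrganismState:
    """Initial state of a newborn.

    The neonate dry mass ``m0`` is split into structure (converted through
    the structural mass density) and reserve (fraction ``e0_frac``,
    converted through the reserve energy density); maturity starts at zero.
    """
    m_struct = params.m0 * (1.0 - params.e0_frac)
    m_res = params.m0 * params.e0_frac
    return OrganismState(E=m_res * params.d_e, V=m_struct / params.d_m, R=0.0)


# -- elementary fluxes (all at the already-thermally-corrected level) --------


def scaled_functional_response(X: float, ks: float) -> float:
    """Holling type-II scaled functional response ``X / (X + ks)``."""
    if X < 0:
        raise DEBError("food concentration X must be non-negative")
    if ks <= 0:
        raise DEBError("half-saturation ks must be positive")
    return X / (X + ks)


def assimilation_flux(params: DEBParameters, V: float, f: float, qA: float) -> float:
    """Assimilation power ``qA * p_AM * V^(2/3) * f`` (J d^-1)."""
    return qA * params.p_AM * V ** (2.0 / 3.0) * f


def maintenance_flux(params: DEBParameters, V: float, qM: float) -> float:
    """Somatic maintenance power ``qM * p_M * V`` (J d^-1)."""
    return qM * params.p_M * V


def mobilization_flux(
    params: DEBParameters, E: float, V: float, kappa: float, p_S: float, qM: float
) -> float:
    """Reserve mobilisation power (J d^-1).

    ``p_C = E * (qM * v_dot * E_G * V^(2/3) + p_S) / (E_G * V + kappa * E)``
    with the conductance thermally corrected by ``qM`` and ``p_S`` the
    already-corrected somatic maintenance flux.
    """
    num = E * (qM * params.v_dot * params.E_G * V ** (2.0 / 3.0) + p_S)
    return num / (params.E_G * V + kappa * E)


# -- thermal corrections -----------------------------------------------------


def maintenance_thermal_correction(params: DEBParameters, T: float) -> float:
    """Arrhenius factor for conductance and maintenance rates.

    ``qM = exp(E_a * (1/(k T*) - 1/(k T)))``; equals 1 at ``T = T_star`` and
    increases monotonically with temperature (kelvin input).
    """
    if T <= 0:
        raise DEBError("temperature must be positive kelvin")
    kB = params.k_B
    return math.exp(params.E_a * (1.0 / (kB * params.T_star) - 1.0 / (kB * T)))


def uptake_thermal_correction(params: DEBParameters, T: float) -> float:
    """Sharpe--Schoolfield factor for the uptake rate (kelvin input).

    Arrhenius activation divided by a high-temperature deactivation term;
    unimodal in T with 50% deactivation (relative to the Arrhenius envelope)
    at ``T = T_d``.  Not renormalised at the reference temperature, so
    ``qA(T_star)`` is slightly below 1.
    """
    if T <= 0:
        raise DEBError("temperature must be positive kelvin")
    kB = params.k_B
    arrh = maintenance_thermal_correction(params, T)
    deact = 1.0 + math.exp(params.E_d * (1.0 / (kB * params.T_d) - 1.0 / (kB * T)))
    return arrh / deact


def allocation_fraction(params: DEBParameters, T: float) -> float:
    """Temperature-dependent somatic allocation fraction kappa(T).

    Decreasing sigmoid between ``kappa_max`` (cold) and ``kappa_min`` (warm)
    with inflexion at ``T_hat``; Celsius input.  ``lambda_ = 0`` degenerates
    to the constant midpoint (standard constant-kappa DEB).
    """
    span = params.kappa_max - params.kappa_min
    z = -params.lambda_ * (T - params.T_hat)
    if z > 700.0:  # exp would overflow; sigmoid is numerically 0
        return params.kappa_max
    return params.kappa_max - span / (1.0 + math.exp(z))


def adult_instar_duration(params: DEBParameters, T: float) -> float:
    """Duration of the first adult instar (d) at temperature T (kelvin).

    This is the delay between energetic maturity (the puberty thresholds)
    and the eggs appearing in the brood pouch, i.e. between real and
    observed age-at-maturity.  Under the default ``as_printed`` convention
    the delay scales with the Arrhenius factor (``delta_star * qM``); the
    alternative ``rate_scaled`` convention divides by it, so the delay
    shortens with warming like other physiological times.  Both conventions
    equal ``delta_star`` at the reference temperature.
    """
    qM = maintenance_thermal_correction(params, T)
    if params.delta_convention == "rate_scaled":
        return params.delta_star / qM
    return params.delta_star * qM


# -- composed dynamics -------------------------------------------------------


def state_derivatives(
    params: DEBParameters,
    state: OrganismState,
    T_t: float,
    X: float,
) -> tuple[float, float, float]:
    """Time derivatives (dE/dt, dV/dt, dR/dt) at instantaneous temperature.

    ``T_t`` is in degC (converted internally to kelvin for the Arrhenius /
    Sharpe--Schoolfield factors); ``X`` is the food concentration in
    mgC L^-1.  Maturity maintenance drains the buffer (or the frozen
    maturity level, per ``adult_maintenance``) after puberty.
    """
    if state.stage is Stage.FAILED:
        raise DEBError("no dynamics for a failed individual")
    if X < 0:
        raise DEBError("food concentration X must be non-negative")
    T_K = T_t + CELSIUS_TO_KELVIN
    qM = maintenance_thermal_correction(params, T_K)
    qA = qM if params.standard_deb else uptake_thermal_correction(params, T_K)
    kappa = allocation_fraction(params, T_t)
    f = scaled_functional_response(X, params.ks)

    p_A = assimilation_flux(params, state.V, f, qA)
    p_S = maintenance_flux(params, state.V, qM)
    p_C = mobilization_flux(params, state.E, state.V, kappa, p_S, qM)

    dE = p_A - p_C
    dV = (kappa * p_C - p_S) / params.E_G
    if params.adult_maintenance == "frozen" and state.stage is not Stage.JUVENILE:
        drain = qM * params.k_j * params.R_p
    else:
        drain = qM * params.k_j * state.R
    dR = (1.0 - kappa) * p_C - drain
    return dE, dV, dR


def mass_at_maturity(
    params: DEBParameters, state_at_clutch: OrganismState, clutch_energy: float
) -> float:
    """Dry mass (ug) at observed maturity: structure + reserve + clutch.

    Structure converts through the mass density ``d_m``; reserve and clutch
    energies convert through the energy density ``d_e``.
    """
    if clutch_energy < 0:
        raise DEBError("clutch energy must be non-negative")
    s = state_at_clutch
    return params.d_m * s.V + s.E / params.d_e + clutch_energy / params.d_e
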