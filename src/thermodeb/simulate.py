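"""Event-driven life-history simulation from neonate to first clutch.

The three DEB state variables are integrated under a (possibly square-wave)
thermal regime.  Puberty is an event: the first instant at which both the
cumulative maturity energy and the minimal structural volume thresholds are
met.  Eggs are laid one first-adult-instar delay later; the three
life-history traits (observed age-at-maturity, dry mass-at-maturity and the
juvenile specific growth rate) are extracted at clutch laying.

Square-wave forcing is handled by restarting the integrator at every
half-period switch, so the solver never steps across a temperature
discontinuity and events are located within constant-temperature segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .deb import (
    CELSIUS_TO_KELVIN,
    DEBError,
    DEBParameters,
    OrganismState,
    Stage,
    adult_instar_duration,
    allocation_fraction,
    maintenance_thermal_correction,
    mass_at_maturity,
    neonate_state,
    scaled_functional_response,
    uptake_thermal_correction,
)
from .forcing import EnvironmentSpec, discontinuity_times, quality_to_maintenance, temperature_at

#: fraction of the running structural-volume peak below which the
#: individual is considered to have shrunk to death
SHRINKAGE_FRACTION = 0.1

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = (1e-10, 1e-13, 1e-10)  # (E, V, R) scales differ by orders


@dataclass
class LifeHistoryResult:
    """Life-history traits of one simulated individual.

    ``age_maturity_observed`` includes the first adult-instar delay on top
    of the real (energetic) age-at-maturity ``t_maturity_real``.
    """

    matured: bool
    age_maturity_observed: float | None = None
    t_maturity_real: float | None = None
    mass_maturity: float | None = None
    growth_rate_: float | None = None
    failure_reason: str | None = None
    trajectory: pd.DataFrame | None = None

    @property
    def traits(self) -> tuple[float, float, float]:
        """(mass ug, observed age d, growth rate d^-1); NaN if not matured."""
        if not self.matured:
            return (math.nan, math.nan, math.nan)
        return (self.mass_maturity, self.age_maturity_observed, self.growth_rate_)


def growth_rate(m0: float, mM: float, aM: float) -> float:
    """Juvenile specific growth rate ``ln(mM / m0) / aM`` (d^-1)."""
    if m0 <= 0 or mM <= 0 or aM <= 0:
        raise DEBError("growth rate requires positive masses and age")
    return math.log(mM / m0) / aM


def _raw_derivatives(params: DEBParameters, E: float, V: float, R: float,
                     T_C: float, X: float, adult: bool) -> tuple[float, float, float]:
    """Unvalidated float-level derivative core shared with the ODE solver.

    Tolerates the tiny negative E excursions an adaptive solver may probe.
    """
    T_K = T_C + CELSIUS_TO_KELVIN
    qM = maintenance_thermal_correction(params, T_K)
    qA = qM if params.standard_deb else uptake_thermal_correction(params, T_K)
    kappa = allocation_fraction(params, T_C)
    f = scaled_functional_response(X, params.ks)
    V23 = V ** (2.0 / 3.0)
    p_A = qA * params.p_AM * V23 * f
    p_S = qM * params.p_M * V
    p_C = E * (qM * params.v_dot * params.E_G * V23 + p_S) / (params.E_G * V + kappa * E)
    dE = p_A - p_C
    dV = (kappa * p_C - p_S) / params.E_G
    if adult and params.adult_maintenance == "frozen":
        drain = qM * params.k_j * params.R_p
    else:
        drain = qM * params.k_j * R
    dR = (1.0 - kappa) * p_C - drain
    return dE, dV, dR


def _instar_end_time(params: DEBParameters, regime, t_m: float) -> float:
    """Clutch time when instar development tracks instantaneous temperature.

    Development accumulates as the integral of dt / delta(T(t)) until it
    reaches 1; with square-wave forcing the integrand is piecewise constant,
    so the integral is accumulated analytically half-period by half-period.
    """
    progress, t = 0.0, t_m
    half = regime.period / 2.0
    while progress < 1.0:
        t_switch = (math.floor(t / half) + 1) * half
        T_K = temperature_at(regime, (t + min(t_switch, t + half)) / 2.0) + CELSIUS_TO_KELVIN
        rate = 1.0 / adult_instar_duration(params, T_K)
        span = t_switch - t
        if progress + rate * span >= 1.0:
            return t + (1.0 - progress) / rate
        progress += rate * span
        t = t_switch
    return t


def simulate_individual(
    params: DEBParameters,
    environment: EnvironmentSpec,
    record_trajectory: bool = False,
    rtol: float = DEFAULT_RTOL,
    atol: tuple[float, float, float] = DEFAULT_ATOL,
    instar_clock: str = "mean",
) -> LifeHistoryResult:
    """Simulate one individual from neonate to first clutch.

    Parameters
    ----------
    params
        DEB parameters; maintenance costs are overridden from the
        environment's food-quality level before integration.
    environment
        Thermal regime and nutrition context, static over the run.
    record_trajectory
        If True, attach the solver time series (t, E, V, R, T, stage).
    instar_clock
        ``"mean"`` (default): the adult-instar delay is evaluated at the
        regime's mean temperature.  ``"instantaneous"``: instar development
        accumulates at the instantaneous temperature's rate.
    """
    if instar_clock not in ("mean", "instantaneous"):
        raise DEBError("instar_clock must be mean|instantaneous")
    regime = environment.thermal
    X = environment.nutrition.X
    costs = environment.nutrition.maintenance_costs()
    if costs is not None:
        params = params.with_quality(*costs)

    state0 = neonate_state(params)
    y = np.array([state0.E, state0.V, state0.R])
    horizon = params.horizon_days
    t_cur = 0.0
    V_peak = y[1]
    rows: list[tuple] = []
    adult = False
    t_maturity: float | None = None
    t_clutch = math.inf
    failure: str | None = None

    def rhs(t, y):
        return _raw_derivatives(params, y[0], y[1], y[2], T_seg, X, adult)

    def ev_puberty(t, y):
        return min(y[2] - params.R_p, y[1] - params.V_p)

    def ev_starve(t, y):
        return y[0]

    def ev_shrink(t, y):
        return y[1] - SHRINKAGE_FRACTION * V_peak

    ev_puberty.terminal, ev_puberty.direction = True, 1
    ev_starve.terminal, ev_starve.direction = True, -1
    ev_shrink.terminal, ev_shrink.direction = True, -1

    while t_cur < horizon and failure is None:
        if adult and t_clutch <= t_cur:
            break
        t_end = min(horizon, t_clutch)
        switches = discontinuity_times(regime, t_cur, t_end)
        t_next = float(switches[0]) if switches.size else t_end
        T_seg = temperature_at(regime, (t_cur + t_next) / 2.0)
        events = [ev_starve, ev_shrink] if adult else [ev_puberty, ev_starve, ev_shrink]
        sol = solve_ivp(rhs, (t_cur, t_next), y, method="RK45",
                        rtol=rtol, atol=list(atol), events=events)
        if not sol.success:  # pragma: no cover - solver breakdown is a failure
            failure = "solver"
            break
        if record_trajectory:
            stage_label = "adult" if adult else "juvenile"
            for ti, yi in zip(sol.t, sol.y.T):
                rows.append((ti, yi[0], yi[1], yi[2], T_seg, stage_label))
        if sol.status == 1:  # an event fired
            idx = next(i for i, te in enumerate(sol.t_events) if te.size)
            t_ev = float(sol.t_events[idx][0])
            y = sol.y_events[idx][0].copy()
            if not adult and idx == 0:  # puberty
                adult = True
                t_maturity = t_ev
                if instar_clock == "mean" or regime.amplitude == 0:
                    t_clutch = t_ev + adult_instar_duration(
                        params, regime.T_mean + CELSIUS_TO_KELVIN)
                else:
                    t_clutch = _instar_end_time(params, regime, t_ev)
                t_cur = t_ev
            else:
                failure = "starvation" if events[idx] is ev_starve else "shrinkage"
                t_cur = t_ev
        else:
            y = sol.y[:, -1].copy()
            t_cur = t_next
        V_peak = max(V_peak, float(y[1]))

    trajectory = None
    if record_trajectory:
        trajectory = pd.DataFrame(
            rows, columns=["t_d", "E_J", "V_cm3", "R_J", "T_C", "stage"])

    if failure is None and adult and t_clutch <= horizon and t_cur >= t_clutch:
        state = OrganismState(E=max(float(y[0]), 0.0), V=float(y[1]),
                              R=max(float(y[2]), 0.0),
                              stage=Stage.MATURE_AWAITING_CLUTCH,
                              t_maturity=t_maturity)
        clutch = max(state.R - params.R_p, 0.0)
        mass = mass_at_maturity(params, state, clutch)
        g = growth_rate(params.m0, mass, t_clutch)
        return LifeHistoryResult(
            matured=True,
            age_maturity_observed=t_clutch,
            t_maturity_real=t_maturity,
            mass_maturity=mass,
            growth_rate_=g,
            trajectory=trajectory,
        )

    if failure is None:
        failure = "horizon"
    return LifeHistoryResult(matured=False, failure_reason=failure,
                             t_maturity_real=t_maturity, trajectory=trajectory)
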