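"""Independent brute-force oracles used by the unit and acceptance tests.

These re-derive the model's printed formulas symbol by symbol with plain
``math`` arithmetic, deliberately sharing no code with the package, so they
can serve as a dual implementation in equivalence checks.
"""

import math

K_BOLTZMANN = 8.617e-5
C2K = 273.15


def oracle_fluxes(p, E, V, R, T_C, X):
    """(dE/dt, dV/dt, dR/dt) evaluated directly from the printed equations."""
    T = T_C + C2K
    qM = math.exp(p.E_a * (1.0 / (K_BOLTZMANN * p.T_star) - 1.0 / (K_BOLTZMANN * T)))
    deact = 1.0 + math.exp(p.E_d * (1.0 / (K_BOLTZMANN * p.T_d) - 1.0 / (K_BOLTZMANN * T)))
    qA = qM / deact
    kappa = p.kappa_max - (p.kappa_max - p.kappa_min) / (
        1.0 + math.exp(-p.lambda_ * (T_C - p.T_hat)))
    f = X / (X + p.ks)
    pA = qA * p.p_AM * V ** (2.0 / 3.0) * f
    pS = qM * p.p_M * V
    pC = E * (qM * p.v_dot * p.E_G * V ** (2.0 / 3.0) + pS) / (p.E_G * V + kappa * E)
    dE = pA - pC
    dV = (kappa * pC - pS) / p.E_G
    dR = (1.0 - kappa) * pC - qM * p.k_j * R
    return dE, dV, dR


def euler_life_history(p, T_C, X, dt=1e-4):
    """Fixed-step Euler integration of the full life history.

    Returns (mass_ug, observed_age_d, growth_d) at constant temperature or
    None if the horizon elapses without a clutch.
    """
    m_struct = p.m0 * (1.0 - p.e0_frac)
    E = p.m0 * p.e0_frac * p.d_e
    V = m_struct / p.d_m
    R = 0.0
    t = 0.0
    t_m = None
    T_K = T_C + C2K
    qM = math.exp(p.E_a * (1.0 / (K_BOLTZMANN * p.T_star) - 1.0 / (K_BOLTZMANN * T_K)))
    delta = p.delta_star * qM if p.delta_convention == "as_printed" else p.delta_star / qM
    t_clutch = math.inf
    while t < p.horizon_days:
        step = dt
        if t_m is not None and t + dt > t_clutch:
            step = t_clutch - t
        dE, dV, dR = oracle_fluxes(p, E, V, R, T_C, X)
        E += step * dE
        V += step * dV
        R += step * dR
        t += step
        if t_m is None and R >= p.R_p and V >= p.V_p:
            t_m = t
            t_clutch = t_m + delta
        if t_m is not None and t >= t_clutch:
            clutch = max(R - p.R_p, 0.0)
            mass = p.d_m * V + E / p.d_e + clutch / p.d_e
            age = t_clutch
            return mass, age, math.log(mass / p.m0) / age
    return None
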