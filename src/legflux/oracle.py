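"""Independent ODE validation of the steady-state flux algebra.

The algebraic two- and three-pool estimators assume an isotopic and mass
steady state. This module checks them against a genuinely different route:
impose a set of true fluxes, numerically integrate the muscle free pool's
tracee and tracer amounts to their steady state, read off the observables
(Cv, Ev, Em) a study would measure, and feed those to the estimators. The
recovered fluxes must match the imposed ones.

System (arterial boundary fixed at Ca, Ea; venous mixing instantaneous):

    dQ/dt = F_MA + F_M0 - (k_VM + k_0M) * Q        tracee amount in muscle
    dq/dt = F_MA * Ea  - (k_VM + k_0M) * q         tracer amount (proteolysis
                                                   releases unlabeled phe)

with k_VM = F_VM/Q*, k_0M = F_0M/Q* for an arbitrary steady-state pool size
Q*. Venous outflow mixes the shunt with the muscle efflux:

    Cv = (F_VA + k_VM*Q) / PF,   Ev = (F_VA*Ea + k_VM*q) / (Cv*PF)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ValidationError


@dataclass(frozen=True)
class SteadyStateObservables:
    Ca: float
    Cv: float
    Ea: float
    Ev: float
    Em: float
    PF: float


def integrate_to_steady_state(F_MA: float, F_M0: float, F_0M: float,
                              PF: float, Ca: float, Ea: float,
                              pool_size: float = 1000.0,
                              horizon_time_constants: float = 80.0,
                              ) -> SteadyStateObservables:
    """Integrate the muscle-pool tracee/tracer ODEs and return observables.

    ``F_MA``, ``F_M0`` (breakdown) and ``F_0M`` (synthesis) are the imposed
    truth in nmol/min/100 ml; outward transport follows from mass balance,
    F_VM = F_MA + F_M0 - F_0M. The integration starts far from equilibrium
    (half-filled unlabeled pool) and runs for many pool time constants.
    """
    F_VM = F_MA + F_M0 - F_0M
    F_VA = Ca * PF - F_MA
    if F_VM <= 0:
        raise ValidationError(f"F_VM = {F_VM} must be > 0")
    if F_VA < 0:
        raise ValidationError(f"shunt flux F_VA = {F_VA} must be >= 0")
    if min(F_MA, F_M0, F_0M, PF, Ca, Ea) <= 0:
        raise ValidationError("all fluxes, PF, Ca and Ea must be > 0")

    k_out = (F_VM + F_0M) / pool_size
    k_VM = F_VM / pool_size

    def rhs(_t, y):
        Q, q = y
        return [F_MA + F_M0 - k_out * Q, F_MA * Ea - k_out * q]

    t_end = horizon_time_constants / k_out
    sol = solve_ivp(rhs, (0.0, t_end), [0.5 * pool_size, 0.0],
                    method="LSODA", rtol=1e-12, atol=1e-12)
    Q, q = sol.y[:, -1]
    Em = q / Q
    Cv = (F_VA + k_VM * Q) / PF
    Ev = (F_VA * Ea + k_VM * q) / (Cv * PF)
    return SteadyStateObservables(Ca=Ca, Cv=Cv, Ea=Ea, Ev=Ev, Em=Em, PF=PF)


def random_valid_fluxes(rng: np.random.Generator) -> dict[str, float]:
    """Draw one physiologically valid flux configuration for oracle sweeps."""
    while True:
        PF = rng.uniform(1.5, 5.0)
        Ca = rng.uniform(40.0, 90.0)
        Ea = rng.uniform(0.04, 0.12)
        F_M0 = rng.uniform(40.0, 120.0)           # breakdown
        F_0M = F_M0 + rng.uniform(-25.0, 10.0)    # synthesis (NB = F_0M-F_M0)
        F_MA = rng.uniform(0.5, 1.6) * F_M0       # inward transport
        F_VM = F_MA + F_M0 - F_0M
        if F_0M > 0 and F_VM > 0 and F_MA < Ca * PF:
            return dict(F_MA=F_MA, F_M0=F_M0, F_0M=F_0M, PF=PF, Ca=Ca, Ea=Ea)
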