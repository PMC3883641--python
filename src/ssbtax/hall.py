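"""Two-compartment energy-balance body-weight model.

Body weight is split into fat mass F and lean (fat-free) mass L with energy
densities rho_F and rho_L.  Total energy expenditure is

    E = K + gamma_F * F + gamma_L * L + delta * activity * (F + L)
        + AT + tef * EI

where K is a resting-metabolism constant, delta the physical-activity
coefficient per kg body weight, AT adaptive thermogenesis (first-order
relaxation toward at_beta * dEI with time constant at_tau_days) and tef the
thermic effect of food.  An energy imbalance EB = EI - E partitions into the
compartments along the Forbes rule dL/dF = C / F, which in energy terms is

    dF/dt = (1 - p) * EB / rho_F,     dL/dt = p * EB / rho_L,
    p = C' / (C' + F),   C' = C * rho_L / rho_F,

so a kilogram of fat change is accompanied by C/F kilograms of lean change.

Each simulated individual is initialised at energy balance (EI solved so
EB = 0 at the baseline composition), so weight responds only to the intake
*change* series, with the realistic multi-year delay that motivates a
dynamic rather than static weight model.  Integration is explicit Euler at
one-day steps, vectorised over individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .tables import HallParameters

__all__ = ["initial_fat_mass", "equilibrium_intake", "simulate_weight",
           "steady_state_weight_change", "WeightTrajectory"]

DAYS_PER_YEAR = 365


def initial_fat_mass(weight, height, age, sex) -> np.ndarray:
    """Baseline fat mass (kg) from a BMI/age/sex body-fat regression.

    Deurenberg-style prediction: body fat % = 1.2*BMI + 0.23*age
    - 10.8*1{male} - 5.4, clipped to [5%, 60%].
    """
    weight = np.asarray(weight, dtype=float)
    bmi = weight / np.asarray(height, dtype=float) ** 2
    male = (np.asarray(sex) == "male").astype(float)
    bf = 1.2 * bmi + 0.23 * np.asarray(age, dtype=float) - 10.8 * male - 5.4
    bf = np.clip(bf, 5.0, 60.0)
    return weight * bf / 100.0


def _expenditure(F, L, activity, params: HallParameters, at, intake):
    W = F + L
    return (params.rmr_constant + params.gamma_fat * F + params.gamma_lean * L
            + params.activity_coeff * np.asarray(activity) * W
            + at + params.tef_fraction * intake)


def equilibrium_intake(weight, fat, activity=1.0,
                       params: HallParameters | None = None) -> np.ndarray:
    """Intake (kcal/day) at which expenditure balances intake for the given
    body composition, i.e. the weight derivative is zero."""
    params = params or HallParameters.default()
    weight = np.asarray(weight, dtype=float)
    fat = np.asarray(fat, dtype=float)
    lean = weight - fat
    base = (params.rmr_constant + params.gamma_fat * fat
            + params.gamma_lean * lean
            + params.activity_coeff * np.asarray(activity) * weight)
    return base / (1.0 - params.tef_fraction)


@dataclass
class WeightTrajectory:
    """Yearly snapshots (year 0 = baseline) of weight, fat and lean mass,
    plus the cumulative energy imbalance for conservation checks."""

    weight: np.ndarray        # (n, n_years + 1)
    fat: np.ndarray
    lean: np.ndarray
    cumulative_flux: np.ndarray   # (n,), integral of EB dt over the horizon


def simulate_weight(weight0, fat0, delta_intake, activity=1.0,
                    params: HallParameters | None = None,
                    dt: float = 1.0) -> WeightTrajectory:
    """Integrate the fat/lean system under a yearly intake-change schedule.

    ``delta_intake`` is kcal/day added to the equilibrium intake, shape
    (n_years,) shared by all individuals or (n, n_years) per individual;
    each year's value is held constant over its days.
    """
    params = params or HallParameters.default()
    F = np.atleast_1d(np.asarray(fat0, dtype=float)).copy()
    W0 = np.atleast_1d(np.asarray(weight0, dtype=float))
    L = W0 - F
    if np.any(F <= 0) or np.any(L <= 0):
        raise ValueError("fat and lean mass must be positive")
    n = F.shape[0]
    di = np.asarray(delta_intake, dtype=float)
    if di.ndim == 1:
        di = np.broadcast_to(di, (n, di.shape[0]))
    n_years = di.shape[1]
    act = np.broadcast_to(np.asarray(activity, dtype=float), (n,))

    ei0 = equilibrium_intake(W0, F, act, params)
    at = np.zeros(n)
    steps_per_year = int(round(DAYS_PER_YEAR / dt))
    if steps_per_year < 1:
        raise ValueError("dt larger than one year")

    weight = np.empty((n, n_years + 1))
    fat = np.empty_like(weight)
    lean = np.empty_like(weight)
    weight[:, 0], fat[:, 0], lean[:, 0] = F + L, F, L
    flux = np.zeros(n)
    c_energy = params.forbes_c * params.rho_lean / params.rho_fat
    for y in range(n_years):
        intake = ei0 + di[:, y]
        for _ in range(steps_per_year):
            if params.include_adaptive_thermogenesis:
                at = at + dt * (params.at_beta * di[:, y] - at) / params.at_tau_days
            else:
                at = 0.0
            eb = intake - _expenditure(F, L, act, params, at, intake)
            p = c_energy / (c_energy + F)
            F = F + dt * (1.0 - p) * eb / params.rho_fat
            L = L + dt * p * eb / params.rho_lean
            flux += eb * dt
            if np.any(F <= 0) or np.any(L <= 0) or not np.all(np.isfinite(F)):
                raise FloatingPointError(
                    "integration failure: non-physical body composition")
        weight[:, y + 1], fat[:, y + 1], lean[:, y + 1] = F + L, F, L
    return WeightTrajectory(weight=weight, fat=fat, lean=lean,
                            cumulative_flux=flux)


def steady_state_weight_change(weight0: float, fat0: float,
                               delta_intake: float, activity: float = 1.0,
                               params: HallParameters | None = None) -> float:
    """Algebraic steady-state weight change for a sustained intake change.

    Independent of the ODE integrator: lean mass is eliminated along the
    Forbes trajectory L(F) = L0 + C * ln(F/F0) and the energy-balance
    equation EB(F, L(F)) = 0 is solved by bracketing.
    """
    params = params or HallParameters.default()
    L0 = weight0 - fat0
    ei0 = float(equilibrium_intake(weight0, fat0, activity, params))
    intake = ei0 + delta_intake
    at = params.at_beta * delta_intake if params.include_adaptive_thermogenesis else 0.0

    def lean(F):
        return L0 + params.forbes_c * np.log(F / fat0)

    def eb(F):
        return intake - _expenditure(F, lean(F), activity, params, at, intake)

    if delta_intake == 0:
        return 0.0
    lo, hi = fat0, fat0
    step = 1.0 if delta_intake > 0 else -1.0
    for _ in range(500):
        hi = hi + step
        if hi <= 0.1:
            hi = 0.1
            break
        if eb(fat0) * eb(hi) < 0:
            break
    F_star = brentq(eb, min(lo, hi), max(lo, hi), xtol=1e-10)
    return float(F_star + lean(F_star) - weight0)
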