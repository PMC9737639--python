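"""Energy-balance body-weight model (simplified Hall steady-state rule).

A sustained change in daily energy intake moves the body toward a new
steady-state weight: 100 kJ/day of sustained deficit per kilogram lost at
steady state. Approach to the new steady state is exponential in time,
calibrated so that the configured fraction of the total change (default
95%) is attained at the evaluation horizon (default 3 years). Height is
held constant, so the BMI change is the weight change divided by height
squared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field

from .population import Population

__all__ = [
    "WeightModelParams",
    "WeightOutcome",
    "steady_state_weight_change",
    "weight_change_at_horizon",
    "apply_weight_change",
    "apply_to_population",
]

KCAL_TO_KJ = 4.184


class WeightModelParams(BaseModel):
    """Parameters of the steady-state energy-balance rule.

    kj_per_kg
        Sustained daily energy change (kJ/day) per kilogram of steady-state
        weight change; the canonical rule constant is 100.
    attainment_fraction
        Fraction of the steady-state change reached at ``horizon_years``.
    min_weight_kg
        Physiologic floor applied when subtracting weight; floored
        individuals are counted, not errored.
    """

    kj_per_kg: float = Field(gt=0.0, default=100.0)
    attainment_fraction: float = Field(gt=0.0, le=1.0, default=0.95)
    horizon_years: float = Field(gt=0.0, default=3.0)
    kcal_to_kj: float = Field(gt=0.0, default=KCAL_TO_KJ)
    min_weight_kg: float = Field(gt=0.0, default=30.0)

    def tau_years(self) -> float:
        """Exponential time constant solved from the horizon anchor.

        1 - exp(-horizon/tau) = attainment_fraction, so at the horizon the
        attained change is exactly the configured fraction of steady state.
        For attainment_fraction == 1 the approach is treated as instantaneous.
        """
        if self.attainment_fraction >= 1.0:
            return 0.0
        return -self.horizon_years / math.log1p(-self.attainment_fraction)


@dataclass
class WeightOutcome:
    """Weight and BMI after applying an energy change at the horizon."""

    delta_weight_kg: np.ndarray | float
    bmi_pre: np.ndarray | float
    bmi_post: np.ndarray | float
    n_floored: int = 0


def steady_state_weight_change(
    delta_e_kcal_per_day, params: WeightModelParams | None = None
):
    """Steady-state weight change (kg) for a sustained daily energy change.

    dw_ss = dE[kJ/day] / kj_per_kg; the sign follows the energy change.
    Accepts scalars or arrays.
    """
    p = params or WeightModelParams()
    return np.multiply(delta_e_kcal_per_day, p.kcal_to_kj) / p.kj_per_kg


def weight_change_at_horizon(
    delta_w_ss, t_years: float, params: WeightModelParams | None = None
):
    """Weight change attained ``t_years`` after the intake change.

    Exponential approach dw(t) = dw_ss * (1 - exp(-t/tau)); at the default
    horizon this returns exactly attainment_fraction * dw_ss.
    """
    p = params or WeightModelParams()
    if t_years < 0:
        raise ValueError(f"t_years must be >= 0, got {t_years}")
    tau = p.tau_years()
    if tau == 0.0:
        frac = 0.0 if t_years == 0 else 1.0
    else:
        frac = 1.0 - math.exp(-t_years / tau)
    return np.multiply(delta_w_ss, frac)


def apply_weight_change(
    weight_kg, height_m, delta_w, params: WeightModelParams | None = None
) -> WeightOutcome:
    """Apply a signed weight change with height held constant.

    Post-change weight is floored at ``min_weight_kg``; the number of
    floored individuals is reported on the outcome.
    """
    p = params or WeightModelParams()
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_m = np.asarray(height_m, dtype=float)
    if np.any(height_m <= 0):
        raise ValueError("height must be positive")
    if np.any(weight_kg <= 0):
        raise ValueError("weight must be positive")

    # floor at the physiologic minimum, but never *raise* an individual who
    # already started below it (a zero change must be the identity)
    floor = np.minimum(weight_kg, p.min_weight_kg)
    new_w = weight_kg + np.asarray(delta_w, dtype=float)
    floored = new_w < floor
    n_floored = int(np.count_nonzero(floored))
    new_w = np.maximum(new_w, floor)

    h2 = height_m**2
    return WeightOutcome(
        delta_weight_kg=new_w - weight_kg,
        bmi_pre=weight_kg / h2,
        bmi_post=new_w / h2,
        n_floored=n_floored,
    )


def apply_to_population(
    pop: Population,
    delta_e_kcal_per_day: np.ndarray,
    params: WeightModelParams | None = None,
    t_years: float | None = None,
) -> WeightOutcome:
    """Energy change → horizon weight change → BMI, for a whole population."""
    p = params or WeightModelParams()
    t = p.horizon_years if t_years is None else t_years
    dw_ss = steady_state_weight_change(delta_e_kcal_per_day, p)
    dw = weight_change_at_horizon(dw_ss, t, p)
    return apply_weight_change(
        pop.df["weight_kg"].to_numpy(dtype=float),
        pop.df["height_m"].to_numpy(dtype=float),
        dw,
        p,
    )
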