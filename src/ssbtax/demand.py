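"""Tax scenario → price shock → elasticity-driven consumption and energy change.

The demand response is first-order in prices: the percentage change in
demand for category j is sum_i eps[j, i] * pct_dprice[i], with eps the
own/cross price-elasticity matrix. A multiplicative (log) form,
q' = q * prod_i (1 + dp_i)^eps[j, i], is available behind a switch.
Shifted volumes are floored at zero — a price response cannot drive
consumption negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .catalogue import BeverageCategory, catalogue_names
from .population import Population

__all__ = [
    "ElasticityMatrix",
    "TaxScenario",
    "EnergyChange",
    "default_elasticity_matrix",
    "price_change",
    "consumption_shift",
    "energy_change",
]


class ElasticityMatrix:
    """Own- and cross-price demand elasticities over beverage categories.

    ``values[j, i]`` is the % change in demand for category j per 1% price
    change of category i; the diagonal holds own-price elasticities
    (expected negative — a warning, not an error, if not).
    """

    def __init__(self, categories: Sequence[str], values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"elasticity matrix must be square, got shape {values.shape}")
        if len(categories) != values.shape[0]:
            raise ValueError(
                f"{len(categories)} categories but matrix of shape {values.shape}"
            )
        if np.any(np.diag(values) > 0):
            bad = [c for c, v in zip(categories, np.diag(values)) if v > 0]
            warnings.warn(
                f"positive own-price elasticity for {bad}; Giffen-like demand is unusual",
                stacklevel=2,
            )
        self.categories = list(categories)
        self.values = values

    def aligned_to(self, catalogue: Sequence[BeverageCategory]) -> "ElasticityMatrix":
        """Reorder to match a catalogue exactly; error on any mismatch."""
        names = catalogue_names(list(catalogue))
        if set(names) != set(self.categories):
            raise ValueError(
                f"elasticity categories {sorted(self.categories)} do not match "
                f"catalogue {sorted(names)}"
            )
        idx = [self.categories.index(n) for n in names]
        return ElasticityMatrix(names, self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.categories, columns=self.categories)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ElasticityMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("elasticity table must have identical row and column labels")
        return cls(list(df.index), df.to_numpy(dtype=float))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ElasticityMatrix":
        return cls.from_dataframe(pd.read_csv(path, index_col=0))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ElasticityMatrix":
        raw = yaml.safe_load(Path(path).read_text())
        cats = list(raw["categories"])
        values = np.array([[raw["values"][j][i] for i in cats] for j in cats], dtype=float)
        return cls(cats, values)


class TaxScenario(BaseModel):
    """An excise-tax scenario on a subset of beverage categories."""

    tax_rate: float = Field(ge=0.0, description="ad-valorem tax as a fraction, e.g. 0.20")
    pass_through: float = Field(ge=0.0, le=1.0, default=1.0)
    taxed_categories: list[str]
    horizon_years: float = Field(gt=0.0, default=3.0)
    name: str = ""

    @field_validator("name", mode="before")
    @classmethod
    def _default_name(cls, v, info):
        return v or ""

    def label(self) -> str:
        if self.name:
            return self.name
        return f"tax{round(self.tax_rate * 100)}_pt{round(self.pass_through * 100)}"


@dataclass
class EnergyChange:
    """Per-individual demand response: volume shifts and net energy change.

    ``delta_volume`` is (n, K) signed mL/day; ``delta_kcal`` is the signed
    per-person energy change, identically equal to delta_volume @ density.
    """

    delta_volume: np.ndarray
    delta_kcal: np.ndarray


# Illustrative elasticity matrix. The demand study underlying the source
# estimates is not redistributable, so these values are documented
# placeholders with the canonical qualitative structure: unit-elastic
# own-price response for the taxed SSB classes and positive cross-price
# substitution toward milk, juice, coffee/tea and water. Replication against
# real data requires supplying the estimated matrix.
_ILLUSTRATIVE = {
    "soda": {"soda": -1.0},
    "milk_sweetened": {"milk_sweetened": -1.0},
    "sports_energy": {"sports_energy": -1.0},
    "other_ssb": {"other_ssb": -1.0},
    "milk": {"milk": -0.5, "soda": 0.70, "milk_sweetened": 0.15, "sports_energy": 0.05, "other_ssb": 0.20},
    "fruit_juice": {"fruit_juice": -0.5, "soda": 0.45, "milk_sweetened": 0.05, "sports_energy": 0.02, "other_ssb": 0.18},
    "coffee_tea": {"coffee_tea": -0.3, "soda": 0.35, "milk_sweetened": 0.05, "sports_energy": 0.02, "other_ssb": 0.13},
    "water": {"water": -0.1, "soda": 0.20, "milk_sweetened": 0.03, "sports_energy": 0.02, "other_ssb": 0.05},
}


def default_elasticity_matrix(catalogue: Sequence[BeverageCategory]) -> ElasticityMatrix:
    """Illustrative own/cross elasticity matrix for the default catalogue."""
    names = catalogue_names(list(catalogue))
    K = len(names)
    values = np.zeros((K, K))
    for j, nj in enumerate(names):
        row = _ILLUSTRATIVE.get(nj, {})
        for i, ni in enumerate(names):
            values[j, i] = row.get(ni, 0.0)
    return ElasticityMatrix(names, values)


def price_change(
    scenario: TaxScenario, catalogue: Sequence[BeverageCategory]
) -> np.ndarray:
    """Per-category retail price change in percent.

    Taxed categories rise by tax_rate * pass_through * 100 percent; all
    others are unchanged.
    """
    names = catalogue_names(list(catalogue))
    unknown = set(scenario.taxed_categories) - set(names)
    if unknown:
        raise ValueError(
            f"unknown taxed categories {sorted(unknown)}; valid names: {names}"
        )
    pct = np.zeros(len(names))
    shock = scenario.tax_rate * scenario.pass_through * 100.0
    for i, n in enumerate(names):
        if n in scenario.taxed_categories:
            pct[i] = shock
    return pct


def consumption_shift(
    elasticities: ElasticityMatrix,
    price_pct: np.ndarray,
    consumption: np.ndarray,
    form: Literal["linear", "log"] = "linear",
) -> np.ndarray:
    """Shifted consumption under a percentage price shock.

    The same percentage demand change applies to every individual
    irrespective of sex or age; heterogeneity in the absolute response
    comes entirely from baseline consumption levels. ``consumption`` may be
    a (K,) vector or an (n, K) matrix.
    """
    q = np.asarray(consumption, dtype=float)
    price_pct = np.asarray(price_pct, dtype=float)
    K = elasticities.values.shape[0]
    if price_pct.shape != (K,):
        raise ValueError(f"price vector shape {price_pct.shape} != ({K},)")
    if q.shape[-1] != K:
        raise ValueError(f"consumption has {q.shape[-1]} categories, expected {K}")
    if np.any(q < 0):
        raise ValueError("baseline consumption must be nonnegative")

    if form == "linear":
        pct_dq = elasticities.values @ price_pct  # (K,)
        shifted = q * (1.0 + pct_dq / 100.0)
    elif form == "log":
        log_factor = elasticities.values @ np.log1p(price_pct / 100.0)
        shifted = q * np.exp(log_factor)
    else:
        raise ValueError(f"unknown demand form {form!r}")
    return np.maximum(shifted, 0.0)


def energy_change(
    pop: Population, shifted: np.ndarray, baseline: np.ndarray | None = None
) -> EnergyChange:
    """Net per-person energy-intake change implied by shifted volumes.

    Substitution toward untaxed caloric beverages can make the net change
    positive even though taxed volumes fall.
    """
    q0 = pop.consumption() if baseline is None else np.asarray(baseline, dtype=float)
    shifted = np.asarray(shifted, dtype=float)
    if shifted.shape != q0.shape:
        raise ValueError(f"shifted shape {shifted.shape} != baseline shape {q0.shape}")
    dv = shifted - q0
    return EnergyChange(delta_volume=dv, delta_kcal=dv @ pop.energy_density())
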