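"""Beverage categories and the default catalogue.

The demand system distinguishes four classes of sugar-sweetened beverages
(SSBs) — the taxed goods — and four non-taxed substitutes (milk, fruit
juice, coffee/tea, water). Each category carries an energy density in
kcal/mL used to convert consumption volumes into daily energy intake.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BeverageCategory", "default_catalogue", "catalogue_names"]


@dataclass(frozen=True)
class BeverageCategory:
    """A beverage class in the demand system.

    Parameters
    ----------
    name : str
        Short unique label, also used as a column prefix in population files.
    energy_density : float
        kcal per mL, >= 0. Water-like categories have 0.
    taxed : bool
        Whether the category is subject to the excise tax by default.
    """

    name: str
    energy_density: float
    taxed: bool

    def __post_init__(self) -> None:
        if self.energy_density < 0:
            raise ValueError(
                f"energy_density must be >= 0, got {self.energy_density!r} "
                f"for category {self.name!r}"
            )


# Default energy densities (kcal/mL) are calibrated so that the default
# baseline volumes reproduce the published energy means: 176 mL/day of SSB
# carrying ~67 kcal/day (mix average ~0.381 kcal/mL) and 576 mL/day of
# non-sweetened caloric beverages carrying ~153 kcal/day (~0.266 kcal/mL).
# Coffee/tea is modelled as lightly sweetened at the table, hence its low
# but nonzero density. All densities are config-overridable.
_DEFAULT_CATEGORIES = (
    BeverageCategory("soda", 0.382, True),
    BeverageCategory("milk_sweetened", 0.60, True),
    BeverageCategory("sports_energy", 0.25, True),
    BeverageCategory("other_ssb", 0.30, True),
    BeverageCategory("milk", 0.60, False),
    BeverageCategory("fruit_juice", 0.45, False),
    BeverageCategory("coffee_tea", 0.1125, False),
    BeverageCategory("water", 0.0, False),
)


def default_catalogue() -> list[BeverageCategory]:
    """Return the default 8-category beverage catalogue.

    Four SSB classes (soda, sweetened milk drinks, sports/energy drinks,
    other sugary drinks) flagged taxed, plus milk, fruit juice, coffee/tea
    and water as non-taxed substitutes. Order is stable across calls.
    """
    return list(_DEFAULT_CATEGORIES)


def catalogue_names(catalogue: list[BeverageCategory]) -> list[str]:
    """Ordered unique category names; raises if names collide."""
    names = [c.name for c in catalogue]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate category names in catalogue: {names}")
    return names
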