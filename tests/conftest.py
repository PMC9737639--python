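import numpy as np
import pandas as pd
import pytest

from ssbtax import (
    Population,
    default_catalogue,
    default_population_config,
    generate_population,
)

TAXED = ["soda", "milk_sweetened", "sports_energy", "other_ssb"]


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture(scope="session")
def pop_small():
    """Mid-size synthetic population for fast pipeline tests."""
    return generate_population(default_population_config(3_000), seed=11)


@pytest.fixture(scope="session")
def pop_default():
    """Default-size calibrated population (the study-scale baseline)."""
    return generate_population(default_population_config(50_000), seed=1)


@pytest.fixture(scope="session")
def tiny_pop(catalogue):
    """Hand-written 10-person population with round numbers.

    Consumption columns follow catalogue order: soda, milk_sweetened,
    sports_energy, other_ssb, milk, fruit_juice, coffee_tea, water.
    """
    rows = [
        # id, sex, age, h, w, sw, soda, mswt, sport, ossb, milk, juice, coffee, water
        (0, "male", "20-29", 1.75, 80.0, 2.0, 500, 0, 0, 100, 0, 0, 100, 500),
        (1, "male", "20-29", 1.80, 95.0, 1.0, 300, 50, 50, 0, 0, 200, 0, 800),
        (2, "female", "20-29", 1.60, 55.0, 1.5, 250, 0, 0, 50, 100, 0, 200, 400),
        (3, "male", "30-39", 1.70, 74.0, 1.0, 150, 0, 0, 50, 200, 300, 300, 600),
        (4, "female", "30-39", 1.65, 68.2, 2.5, 100, 20, 0, 30, 250, 250, 400, 700),
        (5, "male", "50-59", 1.68, 85.0, 1.0, 80, 0, 0, 20, 300, 200, 500, 500),
        (6, "female", "50-59", 1.58, 62.0, 2.0, 50, 0, 0, 0, 300, 300, 450, 600),
        (7, "male", "70+", 1.66, 72.0, 0.5, 40, 0, 0, 10, 400, 250, 500, 400),
        (8, "female", "70+", 1.55, 58.0, 1.0, 30, 0, 0, 0, 350, 300, 400, 500),
        (9, "female", "70+", 1.52, 70.0, 1.5, 0, 0, 0, 0, 0, 0, 0, 0),
    ]
    cols = ["id", "sex", "age_group", "height_m", "weight_kg", "survey_weight"] + [
        f"cons_{c.name}" for c in catalogue
    ]
    df = pd.DataFrame(rows, columns=cols).astype(
        {c: float for c in cols if c not in ("id", "sex", "age_group")}
    )
    return Population(df=df, catalogue=catalogue, provenance={"fixture": "tiny"})
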