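"""Synthetic adult population generator and baseline summaries.

Stands in for the Brazilian POF 2017–2018 consumption and PNS 2019
anthropometry microdata. The generator draws, per individual: sex, age
group, height, a BMI-derived weight, a survey expansion weight, and a
daily consumption volume (mL/day) per beverage category, such that the
survey-weighted stratum means reproduce the published baseline profile:

* mean SSB intake ~176 mL/day and ~67 kcal/day overall;
* soft drinks ~65% of SSB volume;
* a monotone age gradient from 268.6 mL/day (ages 20–29) down to
  105.5 mL/day (ages 70+), men 208 vs women 153 mL/day;
* non-sweetened caloric beverages (milk, fruit juice, coffee/tea)
  ~576 mL/day and ~153 kcal/day.

Consumption is zero-inflated gamma per category (dietary-recall intakes
are right-skewed with many zero consumers); BMI is lognormal per sex with
parameters solved from target overweight/obesity prevalences.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy.optimize import brentq
from scipy.stats import norm

from .catalogue import BeverageCategory, catalogue_names, default_catalogue

__all__ = [
    "AGE_GROUPS",
    "SEXES",
    "PopulationConfig",
    "Population",
    "default_population_config",
    "generate_population",
    "baseline_summary",
    "write_population",
    "read_population",
    "bmi_lognormal_params",
]

AGE_GROUPS: tuple[str, ...] = ("20-29", "30-39", "40-49", "50-59", "60-69", "70+")
SEXES: tuple[str, ...] = ("male", "female")

# Adult age structure used to weight the age gradient (approximate Brazilian
# adult distribution; a generator default, not a survey fact).
_DEFAULT_AGE_SHARES = {
    "20-29": 0.23,
    "30-39": 0.22,
    "40-49": 0.19,
    "50-59": 0.16,
    "60-69": 0.12,
    "70+": 0.08,
}

# Printed baseline anchors the defaults are calibrated to.
_SSB_MEAN_OVERALL = 176.0  # mL/day
_SSB_MEAN_MALE = 208.0
_SSB_MEAN_FEMALE = 153.0
_SSB_MEAN_20_29 = 268.6
_SSB_MEAN_70P = 105.5
_NONSWEET_MEAN_OVERALL = 576.0  # mL/day, excluding water

# The three printed sex/overall means are jointly consistent only for a male
# share of 23/55; using it makes all three anchors hold in expectation.
_DEFAULT_MALE_SHARE = 23.0 / 55.0

_SSB_SHARES = {"soda": 0.65, "milk_sweetened": 0.10, "sports_energy": 0.05, "other_ssb": 0.20}
_NONSWEET_SHARES = {"milk": 0.06, "fruit_juice": 0.367, "coffee_tea": 0.573}

# Non-sweetened consumption rises with age (substitute beverages, milk in
# particular, are consumed more by older adults); ramp is rescaled so the
# overall weighted mean hits the 576 mL/day target exactly in expectation.
_NONSWEET_AGE_RAMP = {
    "20-29": 400.0,
    "30-39": 520.0,
    "40-49": 590.0,
    "50-59": 650.0,
    "60-69": 700.0,
    "70+": 740.0,
}

_DEFAULT_ZERO_PROB = {
    "soda": 0.40,
    "milk_sweetened": 0.80,
    "sports_energy": 0.90,
    "other_ssb": 0.60,
    "milk": 0.60,
    "fruit_juice": 0.50,
    "coffee_tea": 0.20,
    "water": 0.05,
}


class PopulationConfig(BaseModel):
    """Generator configuration; all stratum targets are mL/day.

    ``stratum_means[category][sex][age_group]`` gives the target
    survey-weighted mean consumption of that category in that stratum.
    ``gamma_shape`` controls within-consumer dispersion (CV = shape**-0.5);
    ``zero_prob`` is the probability of zero consumption. BMI targets are
    prevalences (fractions) of overweight (25 <= BMI < 30) and obesity
    (BMI >= 30) per sex.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    n_individuals: int = Field(gt=0)
    catalogue: list[BeverageCategory]
    stratum_means: dict[str, dict[str, dict[str, float]]]
    zero_prob: dict[str, float]
    gamma_shape: dict[str, float]
    bmi_prevalence_targets: dict[str, dict[str, float]]
    height_mean_m: dict[str, float]
    height_sd_m: dict[str, float]
    male_share: float = Field(ge=0.0, le=1.0, default=_DEFAULT_MALE_SHARE)
    age_shares: dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_AGE_SHARES))
    total_population_scale: float = Field(gt=0, default=159_000_000.0)
    survey_weight_sigma: float = Field(ge=0.0, default=0.3)
    bmi_consumption_rho: float = Field(ge=-1.0, le=1.0, default=0.0)

    @field_validator("zero_prob")
    @classmethod
    def _probs_in_unit_interval(cls, v: dict[str, float]) -> dict[str, float]:
        for name, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"zero_prob[{name!r}] must be in [0, 1], got {p}")
        return v

    @field_validator("gamma_shape")
    @classmethod
    def _shapes_positive(cls, v: dict[str, float]) -> dict[str, float]:
        for name, k in v.items():
            if k <= 0:
                raise ValueError(f"gamma_shape[{name!r}] must be > 0, got {k}")
        return v

    @field_validator("stratum_means")
    @classmethod
    def _means_nonnegative(cls, v):
        for cat, by_sex in v.items():
            for sex, by_age in by_sex.items():
                for age, m in by_age.items():
                    if m < 0:
                        raise ValueError(
                            f"stratum_means[{cat!r}][{sex!r}][{age!r}] must be >= 0, got {m}"
                        )
        return v

    @model_validator(mode="after")
    def _check_structure(self) -> "PopulationConfig":
        names = catalogue_names(self.catalogue)
        missing = set(names) - set(self.stratum_means)
        if missing:
            raise ValueError(f"stratum_means missing categories: {sorted(missing)}")
        total = sum(self.age_shares.get(a, 0.0) for a in AGE_GROUPS)
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError(f"age_shares must sum to 1, got {total}")
        for sex in SEXES:
            t = self.bmi_prevalence_targets[sex]
            p_ow, p_ob = t["overweight"], t["obese"]
            if not (0.0 < p_ob < 1.0 and 0.0 < p_ow < 1.0 and p_ow + p_ob < 1.0):
                raise ValueError(
                    f"bmi_prevalence_targets[{sex!r}]: need 0 < overweight, obese and "
                    f"overweight + obese < 1, got {t}"
                )
            if self.height_mean_m[sex] <= 0 or self.height_sd_m[sex] < 0:
                raise ValueError(f"height parameters for {sex!r} must be positive")
        return self


@dataclass
class Population:
    """Individual-level table plus its catalogue and provenance.

    ``df`` has one row per adult with columns id, sex, age_group, height_m,
    weight_kg, survey_weight and one ``cons_<category>`` column (mL/day)
    per catalogue entry, in catalogue order.
    """

    df: pd.DataFrame
    catalogue: list[BeverageCategory]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def consumption_columns(self) -> list[str]:
        return [f"cons_{c.name}" for c in self.catalogue]

    def consumption(self) -> np.ndarray:
        """(n, K) consumption matrix in catalogue order, mL/day."""
        return self.df[self.consumption_columns].to_numpy(dtype=float)

    def energy_density(self) -> np.ndarray:
        return np.array([c.energy_density for c in self.catalogue])

    def taxed_mask(self) -> np.ndarray:
        return np.array([c.taxed for c in self.catalogue])


def _solve_age_curve(
    anchor_young: float, anchor_old: float, overall: float, age_shares: Mapping[str, float]
) -> dict[str, float]:
    """Monotone geometric age gradient hitting both anchors and the overall mean.

    mu_a = c + b * rho**a with mu_0 = anchor_young, mu_5 = anchor_old; rho is
    solved so the age-share-weighted mean equals ``overall``.
    """
    w = np.array([age_shares[a] for a in AGE_GROUPS])
    idx = np.arange(len(AGE_GROUPS))

    def curve(rho: float) -> np.ndarray:
        b = (anchor_young - anchor_old) / (1.0 - rho ** idx[-1])
        c = anchor_young - b
        return c + b * rho**idx

    def objective(rho: float) -> float:
        return float(w @ curve(rho)) - overall

    lo, hi = 1e-9, 1.0 - 1e-9
    if objective(lo) * objective(hi) > 0:
        raise ValueError(
            "overall mean not attainable with a monotone geometric age gradient "
            "between the given anchors"
        )
    rho = brentq(objective, lo, hi, xtol=1e-12)
    return dict(zip(AGE_GROUPS, curve(rho)))


def bmi_lognormal_params(p_overweight: float, p_obese: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) with P(25 <= X < 30) and P(X >= 30) as targeted.

    Closed form: the two tail constraints at the 25 and 30 kg/m^2 cut-offs
    pin both parameters.
    """
    z1 = norm.ppf(1.0 - p_overweight - p_obese)  # standardised ln(25)
    z2 = norm.ppf(1.0 - p_obese)  # standardised ln(30)
    sigma = (math.log(30.0) - math.log(25.0)) / (z2 - z1)
    mu = math.log(25.0) - sigma * z1
    return mu, sigma


def default_population_config(n_individuals: int = 50_000) -> PopulationConfig:
    """Default generator configuration calibrated to the published baselines."""
    catalogue = default_catalogue()
    age_shares = dict(_DEFAULT_AGE_SHARES)

    ssb_age = _solve_age_curve(_SSB_MEAN_20_29, _SSB_MEAN_70P, _SSB_MEAN_OVERALL, age_shares)
    sex_mult = {
        "male": _SSB_MEAN_MALE / _SSB_MEAN_OVERALL,
        "female": _SSB_MEAN_FEMALE / _SSB_MEAN_OVERALL,
    }

    w = np.array([age_shares[a] for a in AGE_GROUPS])
    ramp = np.array([_NONSWEET_AGE_RAMP[a] for a in AGE_GROUPS])
    nonsweet_age = dict(zip(AGE_GROUPS, ramp * (_NONSWEET_MEAN_OVERALL / float(w @ ramp))))

    stratum_means: dict[str, dict[str, dict[str, float]]] = {}
    for cat in catalogue:
        if cat.name in _SSB_SHARES:
            share = _SSB_SHARES[cat.name]
            stratum_means[cat.name] = {
                sex: {a: share * ssb_age[a] * sex_mult[sex] for a in AGE_GROUPS}
                for sex in SEXES
            }
        elif cat.name in _NONSWEET_SHARES:
            share = _NONSWEET_SHARES[cat.name]
            stratum_means[cat.name] = {
                sex: {a: share * nonsweet_age[a] for a in AGE_GROUPS} for sex in SEXES
            }
        else:  # water: flat, calorie-free
            stratum_means[cat.name] = {
                sex: {a: 500.0 for a in AGE_GROUPS} for sex in SEXES
            }

    return PopulationConfig(
        n_individuals=n_individuals,
        catalogue=catalogue,
        stratum_means=stratum_means,
        zero_prob=dict(_DEFAULT_ZERO_PROB),
        gamma_shape={c.name: 1.2 for c in catalogue},
        bmi_prevalence_targets={
            # PNS-like defaults (assumptions, not printed in the source study)
            "male": {"overweight": 0.36, "obese": 0.218},
            "female": {"overweight": 0.33, "obese": 0.295},
        },
        height_mean_m={"male": 1.73, "female": 1.61},
        height_sd_m={"male": 0.07, "female": 0.065},
    )


def generate_population(config: PopulationConfig, seed: int) -> Population:
    """Draw a synthetic population; bit-reproducible given (config, seed)."""
    rng = np.random.default_rng(seed)
    n = config.n_individuals
    names = catalogue_names(config.catalogue)

    sex = np.where(rng.random(n) < config.male_share, "male", "female")
    ages = np.array(AGE_GROUPS)
    age_p = np.array([config.age_shares[a] for a in AGE_GROUPS])
    age_group = rng.choice(ages, size=n, p=age_p / age_p.sum())

    cols: dict[str, np.ndarray] = {
        "id": np.arange(n, dtype=np.int64),
        "sex": sex,
        "age_group": age_group,
    }

    # heights: truncated-normal-ish (normal clipped at a physiologic floor)
    h_mean = np.where(sex == "male", config.height_mean_m["male"], config.height_mean_m["female"])
    h_sd = np.where(sex == "male", config.height_sd_m["male"], config.height_sd_m["female"])
    height = np.maximum(rng.normal(h_mean, h_sd), 1.30)
    cols["height_m"] = height

    # BMI: lognormal per sex, parameters solved from prevalence targets
    bmi = np.empty(n)
    bmi_z = rng.standard_normal(n)
    for s in SEXES:
        t = config.bmi_prevalence_targets[s]
        mu, sg = bmi_lognormal_params(t["overweight"], t["obese"])
        m = sex == s
        bmi[m] = np.exp(mu + sg * bmi_z[m])
    cols["weight_kg"] = bmi * height**2

    # survey weights: mildly heterogeneous, normalized to the expansion total
    if config.survey_weight_sigma > 0:
        sw = rng.lognormal(0.0, config.survey_weight_sigma, n)
    else:
        sw = np.ones(n)
    cols["survey_weight"] = sw * (config.total_population_scale / sw.sum())

    # optional rank correlation between a latent consumption propensity and BMI
    rho = config.bmi_consumption_rho
    propensity = rho * bmi_z + math.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(n)
    u_consume = norm.cdf(propensity)

    for name in names:
        by_sex = config.stratum_means[name]
        mean = np.empty(n)
        for s in SEXES:
            for a in AGE_GROUPS:
                m = (sex == s) & (age_group == a)
                mean[m] = by_sex[s][a]
        p0 = config.zero_prob[name]
        k = config.gamma_shape[name]
        consumes = u_consume >= p0 if rho != 0.0 else rng.random(n) >= p0
        # zero-inflated gamma: mean among consumers inflated so the stratum
        # mean equals the target
        mean_pos = np.where(mean > 0, mean / max(1.0 - p0, 1e-12), 0.0)
        draw = rng.gamma(k, 1.0, n) * (mean_pos / k)
        cols[f"cons_{name}"] = np.where(consumes & (mean > 0), draw, 0.0)

    df = pd.DataFrame(cols)
    provenance = {
        "generator": "ssbtax.population.generate_population",
        "seed": int(seed),
        "config": json.loads(config.model_dump_json()),
    }
    return Population(df=df, catalogue=list(config.catalogue), provenance=provenance)


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    return float(np.average(values, weights=weights))


def baseline_summary(pop: Population) -> pd.DataFrame:
    """Survey-weighted mean volume and energy per category by stratum.

    Returns a tidy frame with one row per sex x age stratum, per-sex rows
    and an overall row. Besides per-category ``vol_*``/``kcal_*`` columns it
    reports SSB and non-sweetened (water excluded) aggregates and the soft
    drink share of SSB volume.
    """
    if len(pop) == 0:
        raise ValueError("cannot summarise an empty population")

    df = pop.df
    dens = pop.energy_density()
    taxed = pop.taxed_mask()
    names = [c.name for c in pop.catalogue]
    caloric_untaxed = ~taxed & (dens > 0)

    cons = pop.consumption()
    kcal = cons * dens
    w = df["survey_weight"].to_numpy(dtype=float)

    def stratum_row(mask: np.ndarray, sex: str, age: str) -> dict:
        ws = w[mask]
        row: dict = {"sex": sex, "age_group": age, "n": int(mask.sum()), "weight_total": ws.sum()}
        for j, name in enumerate(names):
            row[f"vol_{name}"] = _weighted_mean(cons[mask, j], ws)
            row[f"kcal_{name}"] = _weighted_mean(kcal[mask, j], ws)
        ssb_vol = cons[mask][:, taxed].sum(axis=1)
        row["ssb_volume"] = _weighted_mean(ssb_vol, ws)
        row["ssb_kcal"] = _weighted_mean(kcal[mask][:, taxed].sum(axis=1), ws)
        row["nonsweet_volume"] = _weighted_mean(cons[mask][:, caloric_untaxed].sum(axis=1), ws)
        row["nonsweet_kcal"] = _weighted_mean(kcal[mask][:, caloric_untaxed].sum(axis=1), ws)
        if "soda" in names and row["ssb_volume"] > 0:
            row["soda_share_of_ssb"] = 100.0 * row["vol_soda"] / row["ssb_volume"]
        return row

    sexes = df["sex"].to_numpy()
    ages = df["age_group"].to_numpy()
    rows = []
    for s in SEXES:
        for a in AGE_GROUPS:
            mask = (sexes == s) & (ages == a)
            if mask.any():
                rows.append(stratum_row(mask, s, a))
    for s in SEXES:
        mask = sexes == s
        if mask.any():
            rows.append(stratum_row(mask, s, "all"))
    for a in AGE_GROUPS:
        mask = ages == a
        if mask.any():
            rows.append(stratum_row(mask, "all", a))
    rows.append(stratum_row(np.ones(len(df), dtype=bool), "all", "all"))
    return pd.DataFrame(rows)


def write_population(pop: Population, path: str | Path) -> None:
    """Write the individual table as CSV with a JSON sidecar for metadata."""
    path = Path(path)
    pop.df.to_csv(path, index=False)
    meta = {
        "catalogue": [
            {"name": c.name, "energy_density": c.energy_density, "taxed": c.taxed}
            for c in pop.catalogue
        ],
        "provenance": pop.provenance,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_population(path: str | Path) -> Population:
    """Read a population CSV written by :func:`write_population`."""
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text())
    catalogue = [BeverageCategory(**c) for c in meta["catalogue"]]
    return Population(df=df, catalogue=catalogue, provenance=meta.get("provenance", {}))
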