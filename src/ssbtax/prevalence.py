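"""BMI classification, survey-weighted prevalence, and bootstrap CIs.

Overweight is 25 <= BMI < 30 kg/m^2 and obesity BMI >= 30. Prevalence is
the survey-weight share of a class; the tax effect is reported as the
relative change in prevalence (percent of the baseline prevalence, not
percentage points) plus the implied change in expansion-weighted person
counts. Confidence intervals are nonparametric percentile bootstrap over
individuals, resampled within sex x age strata.
"""

from __future__ import annotations

import warnings
from typing import Callable, Literal

import numpy as np
import pandas as pd

from .population import AGE_GROUPS, SEXES, Population

__all__ = [
    "classify_bmi",
    "weighted_prevalence",
    "prevalence_change",
    "bootstrap_ci",
]

BMI_OVERWEIGHT = 25.0
BMI_OBESE = 30.0

_CLASSES = ("normal", "overweight", "obese")


def classify_bmi(bmi):
    """Classify BMI into normal / overweight / obese.

    Boundaries: overweight at exactly 25, obese at exactly 30. Scalars
    return a string; arrays return an object array of class labels.
    NaN or nonpositive values are rejected.
    """
    arr = np.asarray(bmi, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("BMI values must be finite and positive")
    out = np.where(arr >= BMI_OBESE, "obese", np.where(arr >= BMI_OVERWEIGHT, "overweight", "normal"))
    if np.isscalar(bmi) or arr.ndim == 0:
        return str(out)
    return out


def weighted_prevalence(
    bmi: np.ndarray,
    weights: np.ndarray,
    which: Literal["normal", "overweight", "obese"],
) -> float:
    """Survey-weighted prevalence (%) of a BMI class."""
    if which not in _CLASSES:
        raise ValueError(f"unknown class {which!r}; expected one of {_CLASSES}")
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("survey weights must be nonnegative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("survey weights must not be all zero")
    labels = classify_bmi(bmi)
    return float(weights[labels == which].sum() / total * 100.0)


def _strata_masks(df: pd.DataFrame):
    """Yield (sex, age_group, mask) for populated strata, per-sex and overall."""
    sexes = df["sex"].to_numpy()
    ages = df["age_group"].to_numpy()
    for s in SEXES:
        for a in AGE_GROUPS:
            mask = (sexes == s) & (ages == a)
            if mask.any():
                yield s, a, mask
    for s in SEXES:
        mask = sexes == s
        if mask.any():
            yield s, "all", mask
    for a in AGE_GROUPS:
        mask = ages == a
        if mask.any():
            yield "all", a, mask
    yield "all", "all", np.ones(len(df), dtype=bool)


def _prevalence_records(
    bmi_pre: np.ndarray,
    bmi_post: np.ndarray,
    weights: np.ndarray,
    df: pd.DataFrame,
    restrict_to_baseline_class: bool,
) -> pd.DataFrame:
    rows = []
    for s, a, mask in _strata_masks(df):
        w = weights[mask]
        pre_b, post_b = bmi_pre[mask], bmi_post[mask]
        for which in ("overweight", "obese"):
            pre = weighted_prevalence(pre_b, w, which)
            if restrict_to_baseline_class:
                in_class = classify_bmi(pre_b) == which
                post = float(
                    w[in_class & (classify_bmi(post_b) == which)].sum() / w.sum() * 100.0
                )
            else:
                post = weighted_prevalence(post_b, w, which)
            if pre == 0.0:
                warnings.warn(
                    f"baseline {which} prevalence is zero in stratum ({s}, {a}); "
                    "relative change undefined",
                    stacklevel=2,
                )
                rel = np.nan
            else:
                rel = 100.0 * (post - pre) / pre
            rows.append(
                {
                    "sex": s,
                    "age_group": a,
                    "measure": which,
                    "prevalence_pre": pre,
                    "prevalence_post": post,
                    "relative_change_pct": rel,
                    "count_change": (post - pre) / 100.0 * w.sum(),
                }
            )
    return pd.DataFrame(rows)


def prevalence_change(
    pop: Population,
    bmi_pre: np.ndarray,
    bmi_post: np.ndarray,
    restrict_to_baseline_class: bool = False,
) -> pd.DataFrame:
    """Per-stratum overweight/obesity prevalence before and after the tax.

    Positive ``relative_change_pct`` means prevalence rose. The default
    classifies the full population on both sides of the tax so individuals
    may enter or leave each class; ``restrict_to_baseline_class=True``
    instead follows only individuals in the class at baseline (who can then
    only leave), a strictly one-sided variant.
    """
    weights = pop.df["survey_weight"].to_numpy(dtype=float)
    return _prevalence_records(
        np.asarray(bmi_pre, dtype=float),
        np.asarray(bmi_post, dtype=float),
        weights,
        pop.df,
        restrict_to_baseline_class,
    )


def bootstrap_ci(
    statistic: Callable[[pd.DataFrame], float],
    df: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for a statistic of an individual-level table.

    Resamples rows with replacement ``B`` times; reproducible given seed.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    rng = np.random.default_rng(seed)
    n = len(df)
    stats = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, n)
        stats[b] = statistic(df.iloc[idx])
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)
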