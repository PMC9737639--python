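"""End-to-end scenario orchestration and report rendering.

Composes the pipeline population → demand response → energy change →
weight/BMI change → prevalence change, per tax scenario, with stratified
bootstrap confidence intervals, and writes tidy CSV/JSON reports (one
energy, one BMI and one prevalence table per scenario — the shapes of the
source study's Tables 1, 2 and Figure 2).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .demand import (
    ElasticityMatrix,
    TaxScenario,
    consumption_shift,
    default_elasticity_matrix,
    energy_change,
    price_change,
)
from .population import (
    Population,
    PopulationConfig,
    default_population_config,
    generate_population,
    read_population,
)
from .prevalence import _strata_masks, classify_bmi, prevalence_change
from .weight import WeightModelParams, apply_to_population

log = logging.getLogger("ssbtax")

__all__ = [
    "RunConfig",
    "ScenarioResult",
    "simulate_scenario",
    "run_scenario",
    "run_sensitivity",
    "render_reports",
]

# fixed offsets give each stage an independent, reproducible substream
_BOOTSTRAP_SEED_OFFSET = 10_007


class RunConfig(BaseModel):
    """Configuration of a full simulation run."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    population_file: str | None = None
    population_config: PopulationConfig | None = None
    n_individuals: int = Field(gt=0, default=50_000)
    elasticities_file: str | None = None
    scenarios: list[TaxScenario]
    weight_model: WeightModelParams = Field(default_factory=WeightModelParams)
    demand_form: str = "linear"
    bootstrap_replicates: int = Field(ge=0, default=1000)
    restrict_to_baseline_class: bool = False
    output_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.model_validate(raw)

    def load_population(self) -> Population:
        if self.population_file:
            return read_population(self.population_file)
        cfg = self.population_config or default_population_config(self.n_individuals)
        return generate_population(cfg, self.seed)

    def load_elasticities(self, pop: Population) -> ElasticityMatrix:
        if self.elasticities_file:
            path = Path(self.elasticities_file)
            if path.suffix in (".yaml", ".yml"):
                em = ElasticityMatrix.from_yaml(path)
            else:
                em = ElasticityMatrix.from_csv(path)
        else:
            em = default_elasticity_matrix(pop.catalogue)
        return em.aligned_to(pop.catalogue)


@dataclass
class ScenarioResult:
    """Stratified outcome tables for one tax scenario.

    energy_table: survey-weighted mean energy change (kcal/person/day) per
    stratum; bmi_table: mean BMI change (kg/m^2); prevalence_table:
    overweight/obesity prevalence pre/post with relative changes and
    expansion-weighted count changes. Each carries percentile-bootstrap
    ci_low/ci_high columns when replicates > 0.
    """

    scenario: TaxScenario
    energy_table: pd.DataFrame
    bmi_table: pd.DataFrame
    prevalence_table: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)


def _stratified_cis(
    df: pd.DataFrame,
    weights: np.ndarray,
    delta_e: np.ndarray,
    delta_bmi: np.ndarray,
    pre_labels: np.ndarray,
    post_labels: np.ndarray,
    B: int,
    seed: int,
    chunk: int = 50,
) -> dict[tuple[str, str], dict[str, tuple[float, float]]]:
    """Percentile bootstrap CIs per stratum for all reported measures.

    One shared resample per replicate per stratum feeds every statistic, so
    the CI set is internally coherent.
    """
    rng = np.random.default_rng(seed)
    ind = {
        ("pre", "overweight"): (pre_labels == "overweight").astype(float),
        ("pre", "obese"): (pre_labels == "obese").astype(float),
        ("post", "overweight"): (post_labels == "overweight").astype(float),
        ("post", "obese"): (post_labels == "obese").astype(float),
    }
    out: dict[tuple[str, str], dict[str, tuple[float, float]]] = {}
    for s, a, mask in _strata_masks(df):
        w = weights[mask]
        de, db = delta_e[mask], delta_bmi[mask]
        loc = {k: v[mask] for k, v in ind.items()}
        n = len(w)
        reps: dict[str, list[np.ndarray]] = {
            "mean_delta_e": [],
            "mean_delta_bmi": [],
            "rel_overweight": [],
            "rel_obese": [],
        }
        done = 0
        while done < B:
            b = min(chunk, B - done)
            idx = rng.integers(0, n, (b, n))
            W = w[idx]
            Ws = W.sum(axis=1)
            reps["mean_delta_e"].append((W * de[idx]).sum(axis=1) / Ws)
            reps["mean_delta_bmi"].append((W * db[idx]).sum(axis=1) / Ws)
            for which in ("overweight", "obese"):
                pre = (W * loc[("pre", which)][idx]).sum(axis=1) / Ws
                post = (W * loc[("post", which)][idx]).sum(axis=1) / Ws
                with np.errstate(divide="ignore", invalid="ignore"):
                    reps[f"rel_{which}"].append(100.0 * (post - pre) / pre)
            done += b
        out[(s, a)] = {
            k: tuple(np.quantile(np.concatenate(v), [0.025, 0.975]))
            for k, v in reps.items()
        }
    return out


def simulate_scenario(
    pop: Population,
    elasticities: ElasticityMatrix,
    scenario: TaxScenario,
    weight_params: WeightModelParams | None = None,
    bootstrap_replicates: int = 1000,
    seed: int = 0,
    demand_form: str = "linear",
    restrict_to_baseline_class: bool = False,
) -> ScenarioResult:
    """Run the full pipeline for one scenario on an in-memory population."""
    params = weight_params or WeightModelParams()

    price_pct = price_change(scenario, pop.catalogue)
    baseline = pop.consumption()
    shifted = consumption_shift(elasticities, price_pct, baseline, form=demand_form)
    ec = energy_change(pop, shifted, baseline)
    outcome = apply_to_population(pop, ec.delta_kcal, params)

    weights = pop.df["survey_weight"].to_numpy(dtype=float)
    bmi_pre = np.asarray(outcome.bmi_pre, dtype=float)
    bmi_post = np.asarray(outcome.bmi_post, dtype=float)
    delta_bmi = bmi_post - bmi_pre

    log.info(
        "scenario %s: price shock %s%%; mean dE %.3f kcal/day; mean dBMI %.4f; "
        "%d weights floored; %d volumes clipped to zero",
        scenario.label(),
        np.unique(price_pct[price_pct != 0]),
        np.average(ec.delta_kcal, weights=weights),
        np.average(delta_bmi, weights=weights),
        outcome.n_floored,
        int(np.count_nonzero((shifted == 0.0) & (baseline > 0.0))),
    )

    rows_e, rows_b = [], []
    for s, a, mask in _strata_masks(pop.df):
        ws = weights[mask]
        rows_e.append(
            {
                "sex": s,
                "age_group": a,
                "n": int(mask.sum()),
                "mean_delta_kcal": float(np.average(ec.delta_kcal[mask], weights=ws)),
            }
        )
        rows_b.append(
            {
                "sex": s,
                "age_group": a,
                "n": int(mask.sum()),
                "mean_delta_bmi": float(np.average(delta_bmi[mask], weights=ws)),
            }
        )
    energy_table = pd.DataFrame(rows_e)
    bmi_table = pd.DataFrame(rows_b)
    prev_table = prevalence_change(
        pop, bmi_pre, bmi_post, restrict_to_baseline_class=restrict_to_baseline_class
    )

    if bootstrap_replicates > 0:
        cis = _stratified_cis(
            pop.df,
            weights,
            ec.delta_kcal,
            delta_bmi,
            classify_bmi(bmi_pre),
            classify_bmi(bmi_post),
            bootstrap_replicates,
            seed + _BOOTSTRAP_SEED_OFFSET,
        )
        energy_table["ci_low"] = [cis[(r.sex, r.age_group)]["mean_delta_e"][0] for r in energy_table.itertuples()]
        energy_table["ci_high"] = [cis[(r.sex, r.age_group)]["mean_delta_e"][1] for r in energy_table.itertuples()]
        bmi_table["ci_low"] = [cis[(r.sex, r.age_group)]["mean_delta_bmi"][0] for r in bmi_table.itertuples()]
        bmi_table["ci_high"] = [cis[(r.sex, r.age_group)]["mean_delta_bmi"][1] for r in bmi_table.itertuples()]
        prev_table["ci_low"] = [
            cis[(r.sex, r.age_group)][f"rel_{r.measure}"][0] for r in prev_table.itertuples()
        ]
        prev_table["ci_high"] = [
            cis[(r.sex, r.age_group)][f"rel_{r.measure}"][1] for r in prev_table.itertuples()
        ]

    for table in (energy_table, bmi_table, prev_table):
        table.insert(0, "scenario", scenario.label())

    return ScenarioResult(
        scenario=scenario,
        energy_table=energy_table,
        bmi_table=bmi_table,
        prevalence_table=prev_table,
        diagnostics={
            "n_floored_weights": outcome.n_floored,
            "n_clipped_volumes": int(np.count_nonzero((shifted == 0.0) & (baseline > 0.0))),
        },
    )


def run_scenario(config: RunConfig, scenario: TaxScenario) -> ScenarioResult:
    """Load (or generate) inputs per ``config`` and simulate one scenario."""
    pop = config.load_population()
    em = config.load_elasticities(pop)
    return simulate_scenario(
        pop,
        em,
        scenario,
        weight_params=config.weight_model,
        bootstrap_replicates=config.bootstrap_replicates,
        seed=config.seed,
        demand_form=config.demand_form,
        restrict_to_baseline_class=config.restrict_to_baseline_class,
    )


def run(config: RunConfig) -> list[ScenarioResult]:
    """Simulate every scenario in the config on a shared population."""
    pop = config.load_population()
    em = config.load_elasticities(pop)
    results = []
    for sc in config.scenarios:
        results.append(
            simulate_scenario(
                pop,
                em,
                sc,
                weight_params=config.weight_model,
                bootstrap_replicates=config.bootstrap_replicates,
                seed=config.seed,
                demand_form=config.demand_form,
                restrict_to_baseline_class=config.restrict_to_baseline_class,
            )
        )
    return results


def run_sensitivity(
    config: RunConfig, pass_through_values: Sequence[float]
) -> tuple[dict[float, list[ScenarioResult]], pd.DataFrame]:
    """Re-run every scenario at each pass-through rate.

    Returns the full results per pass-through value plus a comparison table
    of overall mean energy and BMI change against the 100% reference.
    """
    for v in pass_through_values:
        if not 0.0 < v <= 1.0:
            raise ValueError(f"pass-through values must be in (0, 1], got {v}")

    pop = config.load_population()
    em = config.load_elasticities(pop)
    all_results: dict[float, list[ScenarioResult]] = {}
    rows = []
    values = list(pass_through_values)
    if 1.0 not in values:
        values = [1.0] + values
    reference: dict[str, dict[str, float]] = {}
    for v in values:
        results = []
        for sc in config.scenarios:
            sc_v = sc.model_copy(update={"pass_through": v, "name": ""})
            res = simulate_scenario(
                pop,
                em,
                sc_v,
                weight_params=config.weight_model,
                bootstrap_replicates=config.bootstrap_replicates,
                seed=config.seed,
                demand_form=config.demand_form,
                restrict_to_baseline_class=config.restrict_to_baseline_class,
            )
            results.append(res)
            overall_e = res.energy_table.query("sex == 'all' and age_group == 'all'")[
                "mean_delta_kcal"
            ].iloc[0]
            overall_b = res.bmi_table.query("sex == 'all' and age_group == 'all'")[
                "mean_delta_bmi"
            ].iloc[0]
            key = f"tax{round(sc.tax_rate * 100)}"
            if v == 1.0:
                reference[key] = {"delta_kcal": overall_e, "delta_bmi": overall_b}
            rows.append(
                {
                    "pass_through": v,
                    "tax_rate": sc.tax_rate,
                    "mean_delta_kcal": overall_e,
                    "mean_delta_bmi": overall_b,
                }
            )
        all_results[v] = results
    comparison = pd.DataFrame(rows)
    comparison["delta_kcal_vs_full_pass"] = [
        r.mean_delta_kcal - reference[f"tax{round(r.tax_rate * 100)}"]["delta_kcal"]
        for r in comparison.itertuples()
    ]
    comparison["delta_bmi_vs_full_pass"] = [
        r.mean_delta_bmi - reference[f"tax{round(r.tax_rate * 100)}"]["delta_bmi"]
        for r in comparison.itertuples()
    ]
    return all_results, comparison


def render_reports(
    results: Sequence[ScenarioResult],
    outdir: str | Path,
    force: bool = False,
    figure: bool = False,
) -> list[Path]:
    """Write one energy/BMI/prevalence CSV per scenario plus a JSON summary.

    Refuses to write into an existing non-empty directory unless ``force``.
    """
    if not results:
        raise ValueError("no results to render")
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {outdir} exists and is not empty; pass force=True"
        )
    outdir.mkdir(parents=True, exist_ok=True)

    written = []
    summary = {}
    for res in results:
        label = res.scenario.label()
        for kind, table in (
            ("energy", res.energy_table),
            ("bmi", res.bmi_table),
            ("prevalence", res.prevalence_table),
        ):
            path = outdir / f"{kind}_{label}.csv"
            table.to_csv(path, index=False)
            written.append(path)
        overall_prev = res.prevalence_table.query("sex == 'all' and age_group == 'all'")
        summary[label] = {
            "tax_rate": res.scenario.tax_rate,
            "pass_through": res.scenario.pass_through,
            "mean_delta_kcal_overall": float(
                res.energy_table.query("sex == 'all' and age_group == 'all'")[
                    "mean_delta_kcal"
                ].iloc[0]
            ),
            "mean_delta_bmi_overall": float(
                res.bmi_table.query("sex == 'all' and age_group == 'all'")[
                    "mean_delta_bmi"
                ].iloc[0]
            ),
            "relative_prevalence_change_pct": {
                row.measure: float(row.relative_change_pct)
                for row in overall_prev.itertuples()
            },
            "diagnostics": res.diagnostics,
        }
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    written.append(summary_path)

    if figure:
        written.append(_prevalence_figure(results, outdir / "prevalence_change.png"))
    return written


def _prevalence_figure(results: Sequence[ScenarioResult], path: Path) -> Path:
    """Bar chart of relative prevalence change by sex x age x scenario."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(11, 7), sharex=True)
    for col, sex in enumerate(("male", "female")):
        for row, measure in enumerate(("overweight", "obese")):
            ax = axes[row][col]
            for res in results:
                t = res.prevalence_table
                t = t[(t.sex == sex) & (t.measure == measure) & (t.age_group != "all")]
                ax.plot(
                    t.age_group, t.relative_change_pct, marker="o", label=res.scenario.label()
                )
            ax.axhline(0.0, color="grey", lw=0.8)
            ax.set_title(f"{sex}, {measure}")
            ax.set_ylabel("relative change (%)")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
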