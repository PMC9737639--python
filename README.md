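# ssbtax

Ex-ante micro-simulation of a sugar-sweetened-beverage (SSB) excise tax and
its impact on population overweight and obesity, in the style of the fiscal
health-policy models applied in Brazil, Mexico, South Africa and the UK.

The package is aimed at nutrition epidemiologists and health economists who
want to simulate, *before* a tax exists, how a price shock propagates from
beverage demand to body weight at population scale:

```
tax scenario ──► retail price change ──► consumption shift (own- & cross-price
elasticity, substitution) ──► Δ energy intake per person ──► Δ weight and BMI
(energy balance) ──► Δ overweight/obesity prevalence by sex × age stratum
```

## The model

**Price shock.** An ad-valorem tax `t` with pass-through `ϕ` raises the
retail price of every taxed category by `Δp = 100·t·ϕ` percent; untaxed
substitutes are unaffected.

**Demand response.** With own-/cross-price elasticity matrix `ε` (entry
`ε_ji` = % change in demand for beverage *j* per 1% price change of *i*),
the first-order demand response is

    %Δq_j = Σ_i ε_ji · %Δp_i ,   q'_j = max(q_j · (1 + %Δq_j/100), 0)

applied with the same percentage change to every individual; absolute
heterogeneity comes from baseline consumption. A multiplicative form
`q'_j = q_j · Π_i (1+Δp_i)^ε_ji` is available via `form="log"`.

**Energy intake.** `ΔE_i = Σ_j (q'_ij − q_ij) · d_j` with `d_j` the energy
density (kcal/mL). Substitution toward caloric untaxed beverages (milk,
juice, coffee/tea) can make `ΔE` *positive* even while taxed volumes fall.

**Body weight.** The simplified steady-state energy-balance rule: a
sustained 100 kJ/day change moves steady-state weight by 1 kg,
`Δw_ss = ΔE·4.184/100`, approached exponentially in time and calibrated so
95% of the change is attained at the 3-year evaluation horizon. Height is
constant, so `ΔBMI = Δw/h²`.

**Outcomes.** Survey-weighted prevalence of overweight (25 ≤ BMI < 30) and
obesity (BMI ≥ 30) before and after tax, reported as *relative* change in
percent and expansion-weighted person counts, with stratified percentile
bootstrap CIs.

Because the elasticity estimates of the original demand study are not
redistributable, the package ships a clearly labelled **illustrative**
matrix (unit own-price elasticity for SSBs, positive cross-price terms to
substitutes); supply your own matrix (CSV/YAML) for real analyses. A
seeded synthetic-population generator calibrated to the published Brazilian
baseline consumption profile (176 mL ≈ 67 kcal SSB per person-day, 65%
soft drinks, 576 mL ≈ 153 kcal non-sweetened, a 268.6 → 105.5 mL/day age
gradient, men 208 vs women 153 mL/day) stands in for survey microdata.

## Worked example

```python
from ssbtax import (TaxScenario, default_elasticity_matrix,
                    default_population_config, generate_population,
                    simulate_scenario)

pop = generate_population(default_population_config(50_000), seed=1)
em = default_elasticity_matrix(pop.catalogue)
scenario = TaxScenario(
    tax_rate=0.20,
    taxed_categories=["soda", "milk_sweetened", "sports_energy", "other_ssb"],
)
res = simulate_scenario(pop, em, scenario, bootstrap_replicates=200, seed=1)

overall = res.energy_table.query("sex == 'all' and age_group == 'all'")
print(overall[["mean_delta_kcal", "ci_low", "ci_high"]].round(2).to_string(index=False))
by_age = res.bmi_table.query("sex == 'all' and age_group != 'all'")
print(by_age[["age_group", "mean_delta_bmi"]].round(3).to_string(index=False))
prev = res.prevalence_table.query("sex == 'all' and age_group == 'all'")
print(prev[["measure", "prevalence_pre", "prevalence_post", "relative_change_pct"]]
      .round(3).to_string(index=False))
```

prints

```
 mean_delta_kcal  ci_low  ci_high
            8.32    8.04      8.6
age_group  mean_delta_bmi
    20-29          -0.069
    30-39           0.072
    40-49           0.167
    50-59           0.218
    60-69           0.278
      70+           0.292
   measure  prevalence_pre  prevalence_post  relative_change_pct
overweight          34.466           34.677                0.612
     obese          26.240           26.951                2.711
```

Read: under a 20% tax fully passed to prices, mean energy intake *rises* by
8.3 kcal/person/day overall — young adults (20–29), the heaviest SSB
consumers, cut calories, while older adults gain through substitution
toward caloric untaxed beverages — so mean BMI and the prevalence of
overweight (+0.6% relative) and obesity (+2.7% relative) increase at the
3-year horizon. Restricting `taxed_categories=["soda"]` expresses the
soft-drinks-only sub-analysis purely via configuration.

The same pipeline is scriptable from the shell:

```bash
ssb-tax synth-pop --seed 1 --n 50000 --out pop.csv
ssb-tax run --config run.yaml --out results/
ssb-tax sensitivity --config run.yaml --pass-through 1.0,0.8
```

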