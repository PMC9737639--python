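import numpy as np
import pandas as pd
import pytest

from ssbtax import (
    RunConfig,
    TaxScenario,
    WeightModelParams,
    consumption_shift,
    default_elasticity_matrix,
    energy_change,
    prevalence_change,
    price_change,
    render_reports,
    run_scenario,
    run_sensitivity,
    simulate_scenario,
)
from ssbtax.weight import apply_to_population
from tests.conftest import TAXED


@pytest.fixture(scope="module")
def em(catalogue):
    return default_elasticity_matrix(catalogue)


def scenario(rate=0.20, pt=1.0):
    return TaxScenario(tax_rate=rate, pass_through=pt, taxed_categories=TAXED)


class TestNullScenario:
    def test_null_tax_is_exact_identity(self, pop_small, em):
        res = simulate_scenario(pop_small, em, scenario(rate=0.0), bootstrap_replicates=0)
        assert (res.energy_table["mean_delta_kcal"] == 0.0).all()
        assert (res.bmi_table["mean_delta_bmi"] == 0.0).all()
        prev = res.prevalence_table
        assert (prev["prevalence_post"] == prev["prevalence_pre"]).all()

    def test_zero_pass_through_is_exact_identity(self, pop_small, em):
        res = simulate_scenario(pop_small, em, scenario(pt=0.0), bootstrap_replicates=0)
        assert (res.energy_table["mean_delta_kcal"] == 0.0).all()
        assert (res.bmi_table["mean_delta_bmi"] == 0.0).all()


class TestStageComposition:
    def test_manual_stages_equal_runner(self, tiny_pop, em):
        """Composing the stages by hand reproduces simulate_scenario exactly."""
        sc = scenario()
        pct = price_change(sc, tiny_pop.catalogue)
        shifted = consumption_shift(em, pct, tiny_pop.consumption())
        ec = energy_change(tiny_pop, shifted)
        outcome = apply_to_population(tiny_pop, ec.delta_kcal)
        manual_prev = prevalence_change(
            tiny_pop, np.asarray(outcome.bmi_pre), np.asarray(outcome.bmi_post)
        )

        res = simulate_scenario(tiny_pop, em, sc, bootstrap_replicates=0)
        w = tiny_pop.df["survey_weight"].to_numpy()
        overall = res.energy_table.query("sex == 'all' and age_group == 'all'")
        assert overall["mean_delta_kcal"].iloc[0] == np.average(ec.delta_kcal, weights=w)
        pd.testing.assert_frame_equal(
            res.prevalence_table.drop(columns="scenario"), manual_prev
        )

    def test_every_stratum_reported_once(self, pop_small, em):
        res = simulate_scenario(pop_small, em, scenario(), bootstrap_replicates=0)
        keys = list(zip(res.energy_table["sex"], res.energy_table["age_group"]))
        assert len(keys) == len(set(keys))
        assert ("all", "all") in keys
        # 12 sex x age + 2 sex + 6 age + 1 overall
        assert len(keys) == 21


class TestDeterminismAndMonotonicity:
    def test_same_seed_identical_results(self, pop_small, em):
        a = simulate_scenario(pop_small, em, scenario(), bootstrap_replicates=50, seed=3)
        b = simulate_scenario(pop_small, em, scenario(), bootstrap_replicates=50, seed=3)
        pd.testing.assert_frame_equal(a.energy_table, b.energy_table)
        pd.testing.assert_frame_equal(a.prevalence_table, b.prevalence_table)

    def test_higher_tax_larger_consumption_drop(self, pop_small, em):
        """Taxed-category volume falls strictly more at 30% than at 20%."""
        q = pop_small.consumption()
        taxed = pop_small.taxed_mask()
        drops = []
        for rate in (0.20, 0.30):
            pct = price_change(scenario(rate=rate), pop_small.catalogue)
            shifted = consumption_shift(em, pct, q)
            drops.append((q - shifted)[:, taxed].sum())
        assert drops[1] > drops[0] > 0


class TestSensitivity:
    def test_pass_through_linearity_per_individual(self, pop_small, em):
        sc_full, sc_part = scenario(pt=1.0), scenario(pt=0.8)
        de = {}
        for key, sc in (("full", sc_full), ("part", sc_part)):
            pct = price_change(sc, pop_small.catalogue)
            shifted = consumption_shift(em, pct, pop_small.consumption())
            de[key] = energy_change(pop_small, shifted).delta_kcal
        np.testing.assert_allclose(de["part"], 0.8 * de["full"], rtol=1e-12, atol=1e-12)

    def test_full_pass_through_matches_main_run(self, pop_small, em, tmp_path):
        cfg = RunConfig(
            scenarios=[scenario()], n_individuals=500, bootstrap_replicates=0, seed=9
        )
        results, comparison = run_sensitivity(cfg, [1.0])
        main = run_scenario(cfg, scenario())
        pd.testing.assert_frame_equal(
            results[1.0][0].energy_table, main.energy_table
        )
        assert (comparison["delta_kcal_vs_full_pass"] == 0.0).all()

    def test_lower_pass_through_smaller_bmi_change(self, pop_small, em):
        full = simulate_scenario(pop_small, em, scenario(pt=1.0), bootstrap_replicates=0)
        part = simulate_scenario(pop_small, em, scenario(pt=0.8), bootstrap_replicates=0)
        b_full = full.bmi_table.query("sex == 'all' and age_group == 'all'")[
            "mean_delta_bmi"
        ].iloc[0]
        b_part = part.bmi_table.query("sex == 'all' and age_group == 'all'")[
            "mean_delta_bmi"
        ].iloc[0]
        assert abs(b_part) < abs(b_full)

    def test_invalid_pass_through_rejected(self):
        cfg = RunConfig(scenarios=[scenario()], n_individuals=100, bootstrap_replicates=0)
        with pytest.raises(ValueError, match="pass-through"):
            run_sensitivity(cfg, [0.0])
        with pytest.raises(ValueError, match="pass-through"):
            run_sensitivity(cfg, [1.2])


class TestSodaOnlyTaxViaConfig:
    def test_taxing_soda_only_is_pure_config(self, pop_small, em):
        sc = TaxScenario(tax_rate=0.20, taxed_categories=["soda"])
        pct = price_change(sc, pop_small.catalogue)
        nonzero = [c.name for c, p in zip(pop_small.catalogue, pct) if p != 0]
        assert nonzero == ["soda"]
        res = simulate_scenario(pop_small, em, sc, bootstrap_replicates=0)
        full = simulate_scenario(pop_small, em, scenario(), bootstrap_replicates=0)
        e_soda = res.energy_table.query("sex == 'all' and age_group == 'all'")[
            "mean_delta_kcal"
        ].iloc[0]
        e_full = full.energy_table.query("sex == 'all' and age_group == 'all'")[
            "mean_delta_kcal"
        ].iloc[0]
        assert e_soda != e_full


class TestRenderReports:
    def test_one_scenario_three_csvs(self, tiny_pop, em, tmp_path):
        res = simulate_scenario(tiny_pop, em, scenario(), bootstrap_replicates=0)
        written = render_reports([res], tmp_path / "out")
        names = sorted(p.name for p in written)
        assert sum(n.endswith(".csv") for n in names) == 3
        assert "summary.json" in names

    def test_scenario_labels_in_filenames(self, tiny_pop, em, tmp_path):
        results = [
            simulate_scenario(tiny_pop, em, scenario(rate=r), bootstrap_replicates=0)
            for r in (0.20, 0.25, 0.30)
        ]
        written = render_reports(results, tmp_path / "out")
        joined = " ".join(p.name for p in written)
        for label in ("tax20", "tax25", "tax30"):
            assert label in joined

    def test_refuses_existing_dir_without_force(self, tiny_pop, em, tmp_path):
        res = simulate_scenario(tiny_pop, em, scenario(), bootstrap_replicates=0)
        out = tmp_path / "out"
        render_reports([res], out)
        with pytest.raises(FileExistsError):
            render_reports([res], out)
        render_reports([res], out, force=True)  # succeeds


def test_run_config_yaml_roundtrip(tmp_path):
    cfg_path = tmp_path / "run.yaml"
    cfg_path.write_text(
        """
n_individuals: 200
seed: 4
bootstrap_replicates: 0
scenarios:
  - tax_rate: 0.20
    pass_through: 1.0
    taxed_categories: [soda, milk_sweetened, sports_energy, other_ssb]
"""
    )
    cfg = RunConfig.from_yaml(cfg_path)
    assert cfg.scenarios[0].tax_rate == 0.20
    res = run_scenario(cfg, cfg.scenarios[0])
    assert len(res.energy_table) == 21
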