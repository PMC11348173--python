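"""Full-model orchestration: dose labeling, ledgers, metrics, populations."""

import dataclasses
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import scpbpk as s
from scpbpk.simulation_engine import (DOSE, ENDO, PLASMA, SYS, ConfigError,
                                      apply_overrides, default_parameters,
                                      pk_metrics, population_sample,
                                      sensitivity_sweep)


class TestDoseLabeling:
    def test_zero_dose_leaves_drug_states_zero(self):
        res = s.simulate(s.ScenarioSpec(drug=s.DrugProperties(dose=0.0)))
        L = res.model.layout
        for sp in (DOSE, SYS):
            assert np.abs(res.states[:, L.species_slice(sp)]).max() == 0.0
        assert res.bioavailability is None

    def test_dose_label_never_occupies_plasma(self, base_result):
        assert np.abs(base_result.amounts(DOSE, PLASMA)).max() == 0.0

    def test_ledger_entries_non_decreasing(self, base_result):
        L = base_result.model.layout
        ledger_block = base_result.states[:, L.n_state:]
        assert (np.diff(ledger_block, axis=0) >= -1e-9).all()

    def test_dose_label_closure(self, base_result):
        """F + pre-systemic catabolism + residual accounts for the dose."""
        L = base_result.model.layout
        dose = base_result.dose
        f = base_result.bioavailability
        presys = sum(base_result.states[-1, led + DOSE] for led in L.ledgers)
        residual = base_result.residual_dose_label
        assert f + presys / dose + residual / dose == pytest.approx(1.0, abs=1e-3)

    def test_whole_system_mass_balance(self, base_result):
        """synthesis + dose = change in total mass + total eliminated."""
        L = base_result.model.layout
        synth = base_result.parameters.systemic.synthesis_rate
        t_end = base_result.times[-1]
        initial = base_result.baseline[:L.n_state].sum() + base_result.dose
        final = base_result.states[-1, :L.n_state].sum()
        eliminated = base_result.states[-1, L.n_state:L.led_arrival].sum()
        lhs = initial + synth * t_end
        rhs = final + eliminated
        assert rhs == pytest.approx(lhs, rel=1e-6)

    def test_fcrn_conservation_along_trajectory(self, base_result):
        """Free receptor (total minus bound) never leaves [0, total]."""
        from scpbpk.simulation_engine import APCC
        pool = base_result.lymph_pool
        cols = [base_result.model.layout.idx(sp, APCC) for sp in (DOSE, SYS, ENDO)]
        occupancy = base_result.states[:, cols] @ pool.mg_to_um
        assert occupancy.min() >= -1e-9 * pool.fcrn_total
        assert occupancy.max() <= pool.fcrn_total * (1 + 1e-9)


class TestNumerics:
    def test_tolerance_halving_stability(self, base_scenario, base_result):
        tight = dataclasses.replace(base_scenario, rtol=base_scenario.rtol / 2,
                                    atol=base_scenario.atol / 2)
        res2 = s.simulate(tight)
        assert res2.bioavailability == pytest.approx(
            base_result.bioavailability, abs=1e-4
        )
        assert res2.metrics["tmax_h"] == pytest.approx(
            base_result.metrics["tmax_h"], rel=1e-3
        )

    def test_tracer_dose_superposition(self):
        r1 = s.simulate(s.ScenarioSpec(drug=s.DrugProperties(dose=0.01)))
        r2 = s.simulate(s.ScenarioSpec(drug=s.DrugProperties(dose=0.02)))
        c1, c2 = r1.plasma_concentration, r2.plasma_concentration
        mask = c1 > c1.max() * 1e-3
        np.testing.assert_allclose(c2[mask], 2.0 * c1[mask], rtol=1e-3)


class TestPkMetrics:
    def test_recovers_analytic_double_exponential_peak(self):
        """Bateman-type curve with a known closed-form peak."""
        k1, k2 = 0.01, 0.05
        t = np.arange(0.0, 400.0, 0.1)
        conc = np.exp(-k1 * t) - np.exp(-k2 * t)
        fake = SimpleNamespace(times=t, plasma_concentration=conc, dose=0.0)
        tmax_true = np.log(k2 / k1) / (k2 - k1)
        cmax_true = np.exp(-k1 * tmax_true) - np.exp(-k2 * tmax_true)
        m = pk_metrics(fake, s.BodyPhysiology())
        assert m["tmax_h"] == pytest.approx(tmax_true, rel=1e-3)
        assert m["cmax_mg_per_l"] == pytest.approx(cmax_true, rel=1e-4)

    def test_flat_trajectory_rejected(self):
        fake = SimpleNamespace(times=np.arange(10.0),
                               plasma_concentration=np.zeros(10), dose=1.0)
        with pytest.raises(ValueError):
            pk_metrics(fake, s.BodyPhysiology())

    def test_cmax_percent_uses_vascular_amount(self, base_result):
        m = base_result.metrics
        expected = 100.0 * m["cmax_mg_per_l"] * 2.9 / base_result.dose
        assert m["cmax_percent_dose"] == pytest.approx(expected)


class TestScenarioConfig:
    def test_unknown_override_path_rejected(self):
        with pytest.raises(ConfigError):
            s.simulate(s.ScenarioSpec(overrides={"apc.k_down": 1.0}))

    def test_group_path_rejected(self):
        with pytest.raises(ConfigError):
            apply_overrides(default_parameters("arm"), {"apc": 1.0})

    def test_override_changes_parameter(self):
        p = apply_overrides(default_parameters("arm"), {"apc.k_up": 0.5})
        assert p.apc.k_up == 0.5

    def test_invalid_horizon(self):
        with pytest.raises(ConfigError):
            s.ScenarioSpec(horizon_days=0.0)


class TestSweepAndSites:
    def test_sweep_is_monotone_in_uptake(self):
        table = sensitivity_sweep(s.ScenarioSpec(), "apc.k_up",
                                  [0.05, 0.25, 1.0])
        f = table["bioavailability"].to_numpy()
        assert (np.diff(f) < 0).all()

    def test_identity_site_ratios(self, base_result):
        from scpbpk.simulation_engine import site_comparison
        with pytest.raises(ValueError):
            site_comparison(s.DrugProperties(), ["arm"])

    def test_free_flow_limit_recovers_full_dose(self):
        """With APC uptake off and endothelial machinery off, no loss path
        remains and the full dose reaches plasma."""
        scenario = s.ScenarioSpec(
            drug=s.DrugProperties(k_up_multiplier=0.0),
            overrides={"systemic.k_endothelial_uptake": 0.0,
                       "systemic.cl_up_tissue": 0.0,
                       "systemic.synthesis_rate": 0.0},
        )
        res = s.simulate(scenario)
        assert res.bioavailability == pytest.approx(1.0, abs=1e-3)


class TestPopulation:
    def test_same_seed_identical_draws(self):
        sc = s.ScenarioSpec(seed=42)
        p1 = population_sample(sc, n=2)
        p2 = population_sample(sc, n=2)
        pd.testing.assert_frame_equal(p1.multipliers, p2.multipliers)
        np.testing.assert_array_equal(p1.bioavailabilities,
                                      p2.bioavailabilities)

    def test_zero_cv_collapses_to_representative(self, base_result):
        pop = population_sample(s.ScenarioSpec(), n=2,
                                cv_map={"apc.k_up": 0.0})
        assert pop.bioavailabilities[0] == pytest.approx(
            base_result.bioavailability, rel=1e-6
        )
        np.testing.assert_allclose(pop.plasma_lo, pop.plasma_hi, rtol=1e-9)
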