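"""MIRD dose assembly, colony growth, scenarios, error propagation."""
import numpy as np
import pandas as pd
import pytest

from celldose import reference
from celldose.dosimetry import (
    DoseError,
    colony_schedule,
    compute_absorbed_dose,
    propagate_uncertainty,
    scenario_compare,
)
from celldose.kinetics import INTERNALIZED, MEDIUM, MEMBRANE


def single_interval_cumulated(medium=0.0, membrane=0.0, internalized=0.0):
    return pd.DataFrame(
        {MEDIUM: [medium], MEMBRANE: [membrane], INTERNALIZED: [internalized]},
        index=["day1"],
    )


class TestColonySchedule:
    def test_doubling_every_day(self):
        assert colony_schedule(24.0, 6) == [1, 4, 8, 16, 32, 64]

    def test_infinite_doubling_time_stays_isolated(self):
        assert colony_schedule(1e12, 6) == [1] * 6

    def test_rounding_rule(self):
        assert colony_schedule(36.0, 3)[2] == 4  # round(2^(72/36))

    def test_sizes_nondecreasing(self):
        for td in (27.0, 35.0, 44.0):
            sizes = colony_schedule(td, 6)
            assert sizes[0] == 1
            assert all(b >= a for a, b in zip(sizes, sizes[1:]))


class TestComputeDose:
    def test_single_term_returns_s_value(self):
        s = reference.monolayer_s_per_day()
        cum = single_interval_cumulated(medium=1.0)
        res = compute_absorbed_dose(cum, s, scenario="pm_cy")
        assert res.total_dose_gy == pytest.approx(s.loc["day1", "s_medium"])

    def test_dose_linear_in_added_activity(self):
        s = reference.monolayer_s_per_day()
        cum = single_interval_cumulated(medium=2.0, membrane=3.0, internalized=5.0)
        res1 = compute_absorbed_dose(cum, s, scenario="pm_cy")
        res2 = compute_absorbed_dose(cum * 2.0, s, scenario="pm_cy")
        assert res2.total_dose_gy == pytest.approx(2.0 * res1.total_dose_gy)

    def test_components_sum_to_total(self):
        s = reference.monolayer_s_per_day()
        cum = single_interval_cumulated(medium=2.0, membrane=3.0, internalized=5.0)
        res = compute_absorbed_dose(cum, s, scenario="pm_cy")
        parts = res.table.loc["day1", [MEDIUM, MEMBRANE, INTERNALIZED]].sum()
        assert parts == pytest.approx(res.table.loc["day1", "total"], rel=1e-12)

    def test_golgi_scenario_scales_internal_term(self):
        """Identical kinetics, Cy -> G: term grows by the published S ratio."""
        s = reference.monolayer_s_per_day()
        cum = single_interval_cumulated(internalized=1.0)
        cy = compute_absorbed_dose(cum, s, scenario="pm_cy", internalized_in="cytoplasm")
        g = compute_absorbed_dose(cum, s, scenario="pm_g", internalized_in="golgi")
        assert g.total_dose_gy / cy.total_dose_gy == pytest.approx(
            9.35e-5 / 5.84e-5, rel=1e-9
        )

    def test_missing_s_value_named(self):
        s = reference.monolayer_s_per_day().drop(index="day1")
        cum = single_interval_cumulated(internalized=1.0)
        with pytest.raises(DoseError, match="day1"):
            compute_absorbed_dose(cum, s, scenario="pm_cy")

    def test_medium_term_dropped_when_undefined(self):
        s = reference.monolayer_s_per_day()
        cum = pd.DataFrame(
            {MEDIUM: [5.0], MEMBRANE: [0.0], INTERNALIZED: [0.0]}, index=["day3"]
        )
        res = compute_absorbed_dose(cum, s, scenario="pm_cy")
        assert res.total_dose_gy == 0.0


class TestScenarioCompare:
    def test_identical_scenarios_ratio_one(self):
        s = reference.monolayer_s_per_day()
        cum = single_interval_cumulated(internalized=1.0)
        a = compute_absorbed_dose(cum, s, scenario="a", added_activity_mbq_ml=0.5)
        b = compute_absorbed_dose(cum, s, scenario="b", added_activity_mbq_ml=0.5)
        table = scenario_compare([a, b])
        assert table.loc["a", "b"] == pytest.approx(1.0)

    def test_published_sphere_to_mesh_ratios(self):
        """Ratios recomputed from the published cumulative-dose table."""
        doses = reference.cumulative_dose_per_activity()
        ratios = (doses["sphere"] / doses["pm_cy"]).to_numpy()
        np.testing.assert_allclose(
            ratios, [3.00, 3.086, 3.011, 2.859, 2.765], atol=0.005
        )

    def test_published_golgi_to_cytoplasm_at_half_mbq(self):
        doses = reference.cumulative_dose_per_activity()
        assert doses.loc[0.5, "pm_g"] / doses.loc[0.5, "pm_cy"] == pytest.approx(
            1.478, abs=0.01
        )

    def test_mismatched_kinetics_rejected(self):
        s = reference.monolayer_s_per_day()
        cum = single_interval_cumulated(internalized=1.0)
        a = compute_absorbed_dose(cum, s, scenario="a", added_activity_mbq_ml=0.5)
        b = compute_absorbed_dose(cum, s, scenario="b", added_activity_mbq_ml=1.0)
        with pytest.raises(DoseError, match="identical"):
            scenario_compare([a, b])


class TestMonteCarloSTable:
    def test_day_one_is_pure_self_dose(self, engine, reference_cell):
        """Isolated day-1 cells: monolayer total equals the self S value."""
        from celldose.dosimetry import ColonyModel, monte_carlo_s_table

        table = monte_carlo_s_table(
            engine, reference_cell, ColonyModel(35.0), sources=("Cy",),
            n_histories=4000, seed=3,
        )
        self_s = engine.self_s_value(reference_cell, "Cy", 4000, seed=3)
        assert table.loc["day1", "s_cy"] == pytest.approx(self_s.value, rel=1e-12)
        # growing clusters add cross-dose on the later days
        assert table.loc["day6", "s_cy"] > table.loc["day1", "s_cy"]
        assert "cross_geometry" in table.attrs


class TestPropagateUncertainty:
    def test_single_component(self):
        assert propagate_uncertainty([0.07]) == pytest.approx(0.07)

    def test_three_four_five(self):
        assert propagate_uncertainty([0.03, 0.04]) == pytest.approx(0.05)

    def test_all_zero(self):
        assert propagate_uncertainty([0.0, 0.0, 0.0]) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(DoseError):
            propagate_uncertainty([-0.1])
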