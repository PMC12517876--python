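"""Isocaloric substitution: formulas, linearity, item-level oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from upfsim.records import NovaGroup, NutrientTotals, ParticipantIntake, aggregate_intake
from upfsim.substitution import (
    DEFAULT_SCENARIOS,
    ScenarioSpec,
    apply_scenario,
    run_scenarios,
)
from .conftest import random_classified_foods


def make_intake(upf_sodium=0.0, upf_sugar=0.0, upf_fiber=0.0, upf_energy=100.0):
    total = NutrientTotals(
        energy=upf_energy + 1000.0,
        sodium=upf_sodium + 500.0,
        added_sugar=upf_sugar + 20.0,
        fiber=upf_fiber + 5.0,
    )
    upf = NutrientTotals(upf_energy, upf_sodium, upf_sugar, upf_fiber)
    return ParticipantIntake("P1", total=total, upf=upf)


class TestApplyScenario:
    def test_zero_fraction_is_identity(self):
        intake = make_intake(upf_sodium=800, upf_sugar=30, upf_fiber=2)
        new, delta = apply_scenario(intake, ScenarioSpec("null", 0.0))
        assert new.as_dict() == intake.total.as_dict()
        assert (delta.d_sodium, delta.d_sugar, delta.d_fiber, delta.d_energy) == (0, 0, 0, 0)

    def test_full_replacement_halves_upf_sodium(self):
        intake = make_intake(upf_sodium=1000.0)
        _, delta = apply_scenario(intake, ScenarioSpec("C", 1.0))
        assert delta.d_sodium == pytest.approx(500.0)

    def test_full_replacement_sugar_cut_is_eighty_percent(self):
        # inverting the published full-replacement SNAP sugar result:
        # a 38.375 g UPF sugar pool under the 0.8 cut gives 30.7 g/d
        intake = make_intake(upf_sugar=38.375)
        _, delta = apply_scenario(intake, ScenarioSpec("C", 1.0))
        assert delta.d_sugar == pytest.approx(30.7)

    def test_fiber_gain_is_half_the_upf_pool(self):
        intake = make_intake(upf_fiber=2.26)
        new, delta = apply_scenario(intake, ScenarioSpec("C", 1.0))
        assert delta.d_fiber == pytest.approx(1.13)
        assert new.fiber == pytest.approx(intake.total.fiber + 1.13)

    def test_energy_conserved_exactly(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            intake = make_intake(
                upf_sodium=rng.uniform(0, 2000),
                upf_sugar=rng.uniform(0, 80),
                upf_fiber=rng.uniform(0, 10),
                upf_energy=rng.uniform(0, 1500),
            )
            for spec in DEFAULT_SCENARIOS:
                new, delta = apply_scenario(intake, spec)
                assert new.energy == intake.total.energy
                assert delta.d_energy == 0.0

    def test_zero_upf_participant_passes_through(self):
        intake = make_intake(upf_energy=0.0)
        new, delta = apply_scenario(intake, ScenarioSpec("C", 1.0))
        assert new.as_dict() == intake.total.as_dict()
        assert delta.d_sodium == 0.0

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec("bad", 1.5)

    @settings(max_examples=100, deadline=None)
    @given(
        f=st.floats(min_value=0, max_value=1, allow_nan=False),
        upf_na=st.floats(min_value=0, max_value=3000, allow_nan=False),
        upf_su=st.floats(min_value=0, max_value=100, allow_nan=False),
        upf_fi=st.floats(min_value=0, max_value=15, allow_nan=False),
    )
    def test_linearity_in_f(self, f, upf_na, upf_su, upf_fi):
        intake = make_intake(upf_sodium=upf_na, upf_sugar=upf_su, upf_fiber=upf_fi)
        _, d_f = apply_scenario(intake, ScenarioSpec("x", f))
        _, d_1 = apply_scenario(intake, ScenarioSpec("one", 1.0))
        assert d_f.d_sodium == pytest.approx(f * d_1.d_sodium, abs=1e-9)
        assert d_f.d_sugar == pytest.approx(f * d_1.d_sugar, abs=1e-9)
        assert d_f.d_fiber == pytest.approx(f * d_1.d_fiber, abs=1e-9)


class TestItemLevelOracle:
    def test_aggregate_formula_equals_item_level_substitution(self):
        """Replacing each NOVA-4 item by an isocaloric substitute with
        m-scaled per-energy densities and re-summing must equal the
        aggregate-pool formula exactly."""
        rng = np.random.default_rng(17)
        spec = ScenarioSpec("C", 1.0)
        for trial in range(100):
            foods = random_classified_foods(rng, n_participants=3, max_items=10)
            intakes = aggregate_intake(foods)
            f = float(rng.uniform(0, 1))
            spec = ScenarioSpec("t", f)
            # oracle: per-item substitution then re-sum
            for intake in intakes:
                na = su = fi = en = 0.0
                for item in foods:
                    if item.participant_id != intake.participant_id:
                        continue
                    if item.nova_group is NovaGroup.ULTRA_PROCESSED:
                        # keep (1-f) of the item, replace fraction f by the
                        # isocaloric substitute with scaled densities
                        na += (1 - f) * item.sodium + f * spec.m_sodium * item.sodium
                        su += (1 - f) * item.added_sugar + f * spec.m_sugar * item.added_sugar
                        fi += (1 - f) * item.fiber + f * spec.m_fiber * item.fiber
                        en += item.energy
                    else:
                        na, su, fi, en = na + item.sodium, su + item.added_sugar, fi + item.fiber, en + item.energy
                new, _ = apply_scenario(intake, spec)
                assert new.sodium == pytest.approx(na, rel=1e-12)
                assert new.added_sugar == pytest.approx(su, rel=1e-12)
                assert new.fiber == pytest.approx(fi, rel=1e-12)
                assert new.energy == pytest.approx(en, rel=1e-12)


class TestRunScenarios:
    def test_quarter_replacement_prints_published_scenario_a(self):
        # full-replacement sodium delta 256.7 -> quarter replacement 64.175
        intake = make_intake(upf_sodium=2 * 256.7)
        table = run_scenarios([intake], DEFAULT_SCENARIOS)
        a = table[table["scenario"] == "A"].iloc[0]
        c = table[table["scenario"] == "C"].iloc[0]
        assert c["d_sodium"] == pytest.approx(256.7)
        assert a["d_sodium"] == pytest.approx(64.175)
        assert round(a["d_sodium"], 1) == 64.2

    def test_half_replacement_of_nonparticipant_sodium(self):
        intake = make_intake(upf_sodium=2 * 294.1)
        table = run_scenarios([intake], DEFAULT_SCENARIOS)
        b = table[table["scenario"] == "B"].iloc[0]
        assert b["d_sodium"] == pytest.approx(147.05)
        assert round(float(b["d_sodium"]) + 1e-9, 1) == 147.1

    def test_one_row_per_participant_scenario(self):
        rng = np.random.default_rng(1)
        intakes = aggregate_intake(random_classified_foods(rng, n_participants=4))
        table = run_scenarios(intakes, DEFAULT_SCENARIOS)
        assert len(table) == 3 * len(intakes)

    def test_duplicate_scenario_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            run_scenarios([make_intake()], [ScenarioSpec("A", 0.2), ScenarioSpec("A", 0.3)])

    def test_group_mean_delta_equals_delta_of_group_mean(self):
        """Linearity bridge: the mean of per-participant deltas equals the
        delta computed from mean UPF pools (what lets group-level targets
        reproduce published group results)."""
        rng = np.random.default_rng(23)
        intakes = [
            make_intake(
                upf_sodium=rng.uniform(0, 1000),
                upf_sugar=rng.uniform(0, 50),
                upf_fiber=rng.uniform(0, 5),
            )
            for _ in range(50)
        ]
        spec = ScenarioSpec("B", 0.5)
        deltas = [apply_scenario(i, spec)[1] for i in intakes]
        mean_delta = np.mean([d.d_sodium for d in deltas])
        mean_pool = np.mean([i.upf.sodium for i in intakes])
        assert mean_delta == pytest.approx((1 - spec.m_sodium) * spec.f * mean_pool)
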