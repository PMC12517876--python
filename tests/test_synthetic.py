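"""Synthetic population generator: determinism, calibration, conservation."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from upfsim import nova, synthetic
from upfsim.records import FoodRecord
from upfsim.synthetic import NONSNAP_TARGETS, SNAP_TARGETS, PopulationConfig


def clt_bound(sd, n, k=3):
    return k * sd / np.sqrt(n)


class TestDeterminism:
    def test_same_seed_byte_identical_tables(self, tmp_path):
        cfg = PopulationConfig(
            snap=replace(SNAP_TARGETS, n=40), nonsnap=replace(NONSNAP_TARGETS, n=60),
            n_strata=4, seed=3,
        )
        frames1 = synthetic.generate_population(cfg)
        frames2 = synthetic.generate_population(cfg)
        for a, b, name in zip(frames1[:2], frames2[:2], ("participants", "foods")):
            p1, p2 = tmp_path / f"{name}1.csv", tmp_path / f"{name}2.csv"
            a.to_csv(p1, index=False)
            b.to_csv(p2, index=False)
            assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_changes_values_but_keeps_invariants(self):
        base = PopulationConfig(
            snap=replace(SNAP_TARGETS, n=120), nonsnap=replace(NONSNAP_TARGETS, n=120),
            n_strata=4,
        )
        realized = []
        for seed in range(5):
            cfg = replace(base, seed=seed)
            participants, foods, audit = synthetic.generate_population(cfg)
            realized.append(audit.realized["snap"]["sodium_mean"])
            # invariants hold at every seed
            assert audit.roundtrip_agreement >= 0.99
            totals = foods.groupby("participant_id")["energy_kcal"].sum()
            assert (totals > 0).all()
            bound = clt_bound(SNAP_TARGETS.sodium[1], 120)
            assert abs(audit.realized["snap"]["sodium_mean"] - 3452.1) < bound
        assert len(set(np.round(realized, 6))) > 1


class TestCalibrationRecovery:
    def test_group_moments_within_three_clt_ses(self, full_population):
        cfg, participants, foods, audit = full_population
        checks = [
            ("snap", SNAP_TARGETS), ("nonsnap", NONSNAP_TARGETS),
        ]
        for name, t in checks:
            r = audit.realized[name]
            assert r["n"] == t.n
            for key, (mean, sd) in (
                ("energy", t.energy), ("sodium", t.sodium),
                ("sugar", t.added_sugar), ("fiber", t.fiber),
            ):
                assert abs(r[f"{key}_mean"] - mean) < clt_bound(sd, t.n), (name, key)
                # SDs track loosely (chi-square spread): within 10%
                assert abs(r[f"{key}_sd"] - sd) / sd < 0.10, (name, key)

    def test_upf_energy_share_recovers_group_target(self, full_population):
        cfg, participants, foods, audit = full_population
        rules = nova.default_rules()
        unique = {d: int(nova.classify_food(d, rules)[0]) for d in foods["description"].unique()}
        foods = foods.assign(nova=foods["description"].map(unique))
        upf_energy = foods[foods["nova"] == 4].groupby("participant_id")["energy_kcal"].sum()
        total_energy = foods.groupby("participant_id")["energy_kcal"].sum()
        share = (upf_energy.reindex(total_energy.index).fillna(0) / total_energy)
        merged = participants.set_index("participant_id").join(share.rename("share"))
        for name, t in (("snap", SNAP_TARGETS), ("nonsnap", NONSNAP_TARGETS)):
            sub = merged[merged["snap"] == (name == "snap")]
            assert abs(sub["share"].mean() - t.upf_share[0]) < clt_bound(t.upf_share[1], t.n), name

    def test_demographic_mixes_match_probabilities(self, full_population):
        cfg, participants, foods, _ = full_population
        snap = participants[participants["snap"]]
        p_female = (snap["sex"] == "female").mean()
        assert abs(p_female - 0.56) < clt_bound(0.5, len(snap))
        p_nhb = (snap["race_ethnicity"] == "Non-Hispanic Black").mean()
        assert abs(p_nhb - 0.321) < clt_bound(0.5, len(snap))
        p_low_pir = (snap["pir_category"] == "low").mean()
        assert abs(p_low_pir - 0.72) < clt_bound(0.45, len(snap))
        p_insecure = snap["food_insecure"].mean()
        assert abs(p_insecure - 0.60) < clt_bound(0.49, len(snap))  # low+very_low = 0.34+0.26


class TestMassConservation:
    def test_item_sums_reproduce_drawn_totals_exactly(self, small_population):
        cfg, participants, foods, audit = small_population
        sums = foods.groupby("participant_id").agg(
            energy=("energy_kcal", "sum"), sodium=("sodium_mg", "sum"),
        )
        # totals are only stored via items, so conservation means: item sums
        # are finite, non-negative, and UPF items never exceed the total
        assert (foods[["energy_kcal", "sodium_mg", "added_sugar_g", "fiber_g"]] >= 0).all().all()
        rules = nova.default_rules()
        unique = {d: int(nova.classify_food(d, rules)[0]) for d in foods["description"].unique()}
        nova_col = foods["description"].map(unique)
        upf_sum = foods[nova_col == 4].groupby("participant_id")["sodium_mg"].sum()
        merged = sums.join(upf_sum.rename("upf_sodium")).fillna(0)
        assert (merged["upf_sodium"] <= merged["sodium"] + 1e-9).all()

    def test_items_per_participant_in_configured_range(self, small_population):
        cfg, participants, foods, _ = small_population
        counts = foods.groupby("participant_id").size()
        assert counts.between(cfg.items_min, cfg.items_max).all()
        assert len(counts) == len(participants)

    def test_every_stratum_has_two_psus(self, small_population):
        cfg, participants, foods, _ = small_population
        psus_per_stratum = participants.groupby("stratum")["psu"].nunique()
        assert (psus_per_stratum >= 2).all()


class TestRoundTrip:
    def test_classifier_agreement_at_least_99_percent(self, small_population):
        cfg, participants, foods, audit = small_population
        assert audit.roundtrip_agreement >= 0.99


class TestConfigValidation:
    def test_infeasible_share_target_raises(self):
        bad = replace(SNAP_TARGETS, upf_share=(0.5, 0.9))  # SD too large for (0,1)
        with pytest.raises(ValueError, match="logit-normal|upf_share"):
            synthetic.generate_population(
                PopulationConfig(snap=replace(bad, n=10),
                                 nonsnap=replace(NONSNAP_TARGETS, n=10), n_strata=2)
            )

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            replace(SNAP_TARGETS, race_probs=(0.5, 0.2, 0.1, 0.1, 0.05))

    def test_single_psu_config_rejected(self):
        with pytest.raises(ValueError):
            PopulationConfig(n_psu_per_stratum=1)


class TestWorkedExample:
    def test_hand_summed_totals(self, worked_example):
        participants, foods = worked_example
        w1 = foods[foods["participant_id"] == "W1"]
        assert w1["energy_kcal"].sum() == 1000.0
        assert w1["sodium_mg"].sum() == 1200.0
        w3 = foods[foods["participant_id"] == "W3"]
        assert w3["energy_kcal"].sum() == 1000.0
        assert w3["added_sugar_g"].sum() == 42.0

    def test_w1_upf_sodium_is_exactly_1000(self, worked_example, rules):
        participants, foods = worked_example
        w1 = foods[foods["participant_id"] == "W1"]
        upf_na = 0.0
        for row in w1.itertuples(index=False):
            if int(nova.classify_food(row.description, rules)[0]) == 4:
                upf_na += row.sodium_mg
        assert upf_na == 1000.0
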