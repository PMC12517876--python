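"""Model/Results interface tying the microsimulation pipeline together.

:class:`UPFRestrictionModel` is built from the two input tables (or a
synthetic-population config), holds the analysis configuration — NOVA rule
set, restriction scenarios, usual-intake Monte Carlo settings, effect
coefficients — and its :meth:`~UPFRestrictionModel.fit` runs the stages in
order: classify -> aggregate -> substitution scenarios -> usual-intake
simulation -> health-impact simulation -> survey-weighted summaries.  The
returned :class:`UPFRestrictionResults` carries every stage's table, the
seeds and config hashes that produced them, and a text ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import nova, records, substitution, survey, synthetic, usual_intake
from .health import EffectCoefficients, HealthImpactResult, point_impacts, simulate_impacts
from .records import FoodRecord, NutrientTotals, ParticipantIntake
from .substitution import DEFAULT_SCENARIOS, NutrientDelta, ScenarioSpec
from .usual_intake import UsualIntakeConfig

__all__ = ["UPFRestrictionModel", "UPFRestrictionResults"]


def _intake_frame(intakes: Sequence[ParticipantIntake]) -> pd.DataFrame:
    rows = []
    for it in intakes:
        rows.append(
            {
                "participant_id": it.participant_id,
                "baseline_energy": it.total.energy,
                "baseline_sodium": it.total.sodium,
                "baseline_sugar": it.total.added_sugar,
                "baseline_fiber": it.total.fiber,
                "upf_energy": it.upf.energy,
                "upf_sodium": it.upf.sodium,
                "upf_sugar": it.upf.added_sugar,
                "upf_fiber": it.upf.fiber,
                "upf_share": (
                    it.upf.energy / it.total.energy if it.total.energy > 0 else np.nan
                ),
                "zero_energy": it.zero_energy,
            }
        )
    return pd.DataFrame(rows)


class UPFRestrictionModel:
    """Microsimulation of graded UPF purchase restrictions on one population.

    Parameters
    ----------
    foods : item-level food table (dietary_records_io schema).
    participants : participant table with survey design fields.
    rules : keyword rule set; defaults to the shipped table.
    scenarios : restriction scenarios; defaults to A/B/C (25/50/100%).
    intake_config : usual-intake Monte Carlo settings.
    coefficients : dose-response slopes; the scale mode must be explicit.
    """

    def __init__(
        self,
        foods: pd.DataFrame,
        participants: pd.DataFrame,
        *,
        rules: nova.RuleSet | None = None,
        scenarios: Sequence[ScenarioSpec] = DEFAULT_SCENARIOS,
        intake_config: UsualIntakeConfig | None = None,
        coefficients: EffectCoefficients | None = None,
    ) -> None:
        self.foods = foods.reset_index(drop=True)
        self.participants = participants.reset_index(drop=True)
        self.rules = rules if rules is not None else nova.default_rules()
        self.scenarios = tuple(scenarios)
        self.intake_config = intake_config or UsualIntakeConfig()
        self.coefficients = coefficients or EffectCoefficients.as_reproduced()
        self.generation_audit: synthetic.GenerationAudit | None = None

    @classmethod
    def from_tables(
        cls, foods_path: str | Path, participants_path: str | Path, **kwargs
    ) -> "UPFRestrictionModel":
        """Build from the two CSV files (validated on read)."""
        foods = records.read_food_table(foods_path)
        parts = records.read_participant_table(participants_path)
        fdf = pd.DataFrame(
            {
                "participant_id": [f.participant_id for f in foods],
                "food_code": [f.food_code for f in foods],
                "description": [f.description for f in foods],
                "energy_kcal": [f.energy for f in foods],
                "sodium_mg": [f.sodium for f in foods],
                "added_sugar_g": [f.added_sugar for f in foods],
                "fiber_g": [f.fiber for f in foods],
            }
        )
        pdf = pd.DataFrame(
            {
                "participant_id": [p.participant_id for p in parts],
                "age": [p.age for p in parts],
                "sex": [p.sex for p in parts],
                "race_ethnicity": [p.race_ethnicity for p in parts],
                "snap": [p.snap for p in parts],
                "pir": [p.pir for p in parts],
                "food_security_score": [p.food_security_score for p in parts],
                "education": [p.education for p in parts],
                "household_size": [p.household_size for p in parts],
                "weight": [p.survey_weight for p in parts],
                "stratum": [p.stratum for p in parts],
                "psu": [p.psu for p in parts],
            }
        )
        pdf["pir_category"] = pdf["pir"].map(records.derive_pir_category)
        fs = pdf["food_security_score"].map(records.derive_food_security)
        pdf["food_security_level"] = [lv for lv, _ in fs]
        pdf["food_insecure"] = [ins for _, ins in fs]
        return cls(fdf, pdf, **kwargs)

    @classmethod
    def from_synthetic(
        cls, config: synthetic.PopulationConfig | None = None, **kwargs
    ) -> "UPFRestrictionModel":
        """Build from a freshly generated synthetic population."""
        config = config or synthetic.PopulationConfig()
        participants, foods, audit = synthetic.generate_population(config)
        model = cls(foods, participants, **kwargs)
        model.generation_audit = audit
        return model

    def _food_records(self) -> list[FoodRecord]:
        return [
            FoodRecord(
                participant_id=row.participant_id,
                food_code=int(row.food_code),
                description=row.description,
                energy=row.energy_kcal,
                sodium=row.sodium_mg,
                added_sugar=row.added_sugar_g,
                fiber=row.fiber_g,
            )
            for row in self.foods.itertuples(index=False)
        ]

    def fit(
        self,
        seed: int = 0,
        *,
        n_impact_sims: int = 10_000,
        single_psu: str = "error",
        skip_usual_intake: bool = False,
    ) -> "UPFRestrictionResults":
        """Run the full pipeline and return a results object.

        ``seed`` fans out to labeled substreams (usual intake, impact
        simulation) so one knob reproduces the entire run.
        ``skip_usual_intake`` omits the per-participant draw summaries (the
        heaviest stage) when only deterministic outputs are needed.
        """
        classified, audits = nova.classify_all(self._food_records(), self.rules)
        intakes = records.aggregate_intake(classified)
        intake_table = _intake_frame(intakes)
        delta_table = substitution.run_scenarios(intakes, self.scenarios)

        usual = None
        if not skip_usual_intake:
            cfg = UsualIntakeConfig(
                n_draws=self.intake_config.n_draws,
                cv=self.intake_config.cv,
                family=self.intake_config.family,
                seed=seed,
            )
            usual = usual_intake.simulate_population(intakes, cfg)

        # Group x scenario health impacts: survey-weighted mean deltas with
        # Monte Carlo coefficient uncertainty on top.
        merged = delta_table.merge(
            self.participants[["participant_id", "snap", "weight", "stratum", "psu"]],
            on="participant_id",
        )
        impacts: dict[tuple[str, str], HealthImpactResult] = {}
        impact_seed = int(
            np.random.SeedSequence([seed, 0x1417]).generate_state(1)[0] % (2**31)
        )
        for group in ("snap", "nonsnap"):
            sub = merged[merged["snap"].astype(bool) == (group == "snap")]
            if sub.empty:
                continue
            for scenario, chunk in sub.groupby("scenario", sort=True):
                design = survey.SurveyDesign(
                    chunk["weight"].to_numpy(),
                    chunk["stratum"].to_numpy(),
                    chunk["psu"].to_numpy(),
                )
                delta = NutrientDelta(
                    d_sodium=survey.weighted_mean(
                        chunk["d_sodium"].to_numpy(), design, single_psu=single_psu
                    ).estimate,
                    d_sugar=survey.weighted_mean(
                        chunk["d_sugar"].to_numpy(), design, single_psu=single_psu
                    ).estimate,
                    d_fiber=survey.weighted_mean(
                        chunk["d_fiber"].to_numpy(), design, single_psu=single_psu
                    ).estimate,
                )
                impacts[(group, scenario)] = simulate_impacts(
                    delta, self.coefficients, n_sims=n_impact_sims, seed=impact_seed
                )

        tables = survey.summarize_groups(
            self.participants,
            intake_table,
            delta_table,
            impacts,
            single_psu=single_psu,
        )
        return UPFRestrictionResults(
            model=self,
            seed=seed,
            intake_table=intake_table,
            delta_table=delta_table,
            usual_intake_table=usual,
            impacts=impacts,
            tables=tables,
            classification_audit=nova.audits_to_frame(audits),
        )


@dataclass
class UPFRestrictionResults:
    """Fitted results: per-stage tables, impact estimates, and provenance."""

    model: UPFRestrictionModel
    seed: int
    intake_table: pd.DataFrame
    delta_table: pd.DataFrame
    usual_intake_table: pd.DataFrame | None
    impacts: dict[tuple[str, str], HealthImpactResult]
    tables: dict[str, pd.DataFrame]
    classification_audit: pd.DataFrame

    @property
    def baseline(self) -> pd.DataFrame:
        return self.tables["baseline"]

    @property
    def demographics(self) -> pd.DataFrame:
        return self.tables["demographics"]

    @property
    def deltas(self) -> pd.DataFrame:
        return self.tables["deltas"]

    @property
    def impact_table(self) -> pd.DataFrame:
        return self.tables["impacts"]

    @property
    def provenance(self) -> dict[str, object]:
        return {
            "seed": self.seed,
            "rules_hash": self.model.rules.content_hash,
            "scale_mode": self.model.coefficients.scale_mode,
            "intake_family": self.model.intake_config.family,
            "n_draws": self.model.intake_config.n_draws,
            "cv": self.model.intake_config.cv,
        }

    def summary(self) -> str:
        """Human-readable run summary: design, baseline, deltas, impacts."""
        lines = [
            "UPF restriction microsimulation",
            "=" * 64,
            f"seed: {self.seed}   rule table: {self.model.rules.content_hash}",
            f"coefficient scale mode: {self.model.coefficients.scale_mode}",
            f"usual-intake family: {self.model.intake_config.family} "
            f"(cv={self.model.intake_config.cv}, draws={self.model.intake_config.n_draws})",
            "",
            "Survey-weighted baseline intake (mean [95% CI]):",
        ]
        for row in self.baseline.itertuples(index=False):
            lines.append(
                f"  {row.group:>8s} {row.variable:<12s} "
                f"{row.estimate:10.2f} [{row.ci_low:.2f}, {row.ci_high:.2f}]"
            )
        lines.append("")
        lines.append("Scenario nutrient deltas (survey-weighted means, reduction-positive):")
        for row in self.deltas.itertuples(index=False):
            lines.append(
                f"  {row.group:>8s} scenario {row.scenario}: "
                f"sodium -{row.d_sodium:.1f} mg/d, sugar -{row.d_sugar:.1f} g/d, "
                f"fiber +{row.d_fiber:.2f} g/d, energy {row.d_energy:+.1f} kcal/d"
            )
        lines.append("")
        lines.append("Projected health impacts (mean [95% percentile interval]):")
        for (group, scenario), res in sorted(self.impacts.items()):
            lines.append(
                f"  {group:>8s} scenario {scenario}: "
                f"SBP -{res.d_sbp:.2f} mm Hg [{res.d_sbp_ci[0]:.2f}, {res.d_sbp_ci[1]:.2f}], "
                f"T2D -{res.d_t2d:.2f}% [{res.d_t2d_ci[0]:.2f}, {res.d_t2d_ci[1]:.2f}], "
                f"CVD -{res.d_cvd:.2f}% [{res.d_cvd_ci[0]:.2f}, {res.d_cvd_ci[1]:.2f}]"
            )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write every table plus a provenance stamp to ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.intake_table.to_csv(outdir / "intake.csv", index=False)
        self.delta_table.to_csv(outdir / "scenario_deltas.csv", index=False)
        if self.usual_intake_table is not None:
            self.usual_intake_table.to_csv(outdir / "usual_intake.csv", index=False)
        self.classification_audit.to_csv(outdir / "classification_audit.csv", index=False)
        for name, table in self.tables.items():
            table.to_csv(outdir / f"report_{name}.csv", index=False)
        stamp = dict(self.provenance)
        if self.model.generation_audit is not None:
            stamp["generation_audit"] = self.model.generation_audit.as_dict()
        (outdir / "provenance.json").write_text(json.dumps(stamp, indent=2))
        (outdir / "summary.txt").write_text(self.summary() + "\n")

    def plot_deltas(self, ax=None):
        """Bar chart of group x scenario nutrient deltas (simple styling)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        d = self.deltas.copy()
        d["label"] = d["group"] + "/" + d["scenario"]
        x = np.arange(len(d))
        ax.bar(x - 0.2, d["d_sodium"] / 10.0, width=0.2, label="sodium (x10 mg/d)")
        ax.bar(x, d["d_sugar"], width=0.2, label="added sugar (g/d)")
        ax.bar(x + 0.2, d["d_fiber"], width=0.2, label="fiber gain (g/d)")
        ax.set_xticks(x, d["label"], rotation=45, ha="right")
        ax.set_ylabel("daily change (reduction-positive)")
        ax.legend()
        return ax

    def plot_usual_intake(self, nutrient: str = "sodium", ax=None):
        """Histogram of per-participant usual-intake means for one nutrient."""
        import matplotlib.pyplot as plt

        if self.usual_intake_table is None:
            raise ValueError("usual-intake stage was skipped for this fit")
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        sub = self.usual_intake_table[self.usual_intake_table["nutrient"] == nutrient]
        merged = sub.merge(
            self.model.participants[["participant_id", "snap"]], on="participant_id"
        )
        for group, mask in (("SNAP", merged["snap"]), ("non-SNAP", ~merged["snap"])):
            ax.hist(merged[mask]["mean"], bins=40, alpha=0.5, density=True, label=group)
        ax.set_xlabel(f"usual {nutrient} intake")
        ax.set_ylabel("density")
        ax.legend()
        return ax
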