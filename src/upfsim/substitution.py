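"""Isocaloric substitution of ultra-processed foods by minimally processed ones.

A scenario replaces a fraction ``f`` of each participant's NOVA-4 (UPF)
intake with an isocaloric minimally-processed alternative whose per-energy
nutrient densities are fixed multiples of the UPF profile: by default 50%
of the sodium density, 20% of the added-sugar density (an 80% cut) and
150% of the fiber density.  Applied to the UPF-attributable aggregate this
gives, in reduction-positive convention,

    d_sodium = (1 - m_sodium) * f * upf.sodium
    d_sugar  = (1 - m_sugar)  * f * upf.added_sugar
    d_fiber  = (m_fiber - 1)  * f * upf.fiber          (a gain)
    d_energy = 0                                        (isocaloric)

Deltas are exactly linear in ``f``, so the graded scenarios A (25%),
B (50%) and C (100%) differ only by scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .records import NutrientTotals, ParticipantIntake

__all__ = [
    "ScenarioSpec",
    "NutrientDelta",
    "DEFAULT_SCENARIOS",
    "apply_scenario",
    "run_scenarios",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One restriction scenario: replacement fraction + substitute profile.

    ``f`` is the fraction of UPF energy replaced (equivalently, of every
    UPF item — the aggregate formula and per-item replacement coincide).
    The ``m_*`` multipliers are replacement-to-UPF per-energy nutrient
    density ratios; energy is always conserved (isocaloric contract).
    """

    name: str
    f: float
    m_sodium: float = 0.5
    m_sugar: float = 0.2
    m_fiber: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"scenario {self.name!r}: f must be in [0, 1], got {self.f}")
        for nm in ("m_sodium", "m_sugar", "m_fiber"):
            if getattr(self, nm) < 0:
                raise ValueError(f"scenario {self.name!r}: {nm} must be >= 0")


#: The three graded restriction scenarios: 25%, 50% and 100% replacement.
DEFAULT_SCENARIOS: tuple[ScenarioSpec, ...] = (
    ScenarioSpec("A", 0.25),
    ScenarioSpec("B", 0.50),
    ScenarioSpec("C", 1.00),
)


@dataclass(frozen=True)
class NutrientDelta:
    """Per-day nutrient shifts in reduction-positive convention.

    ``d_sodium`` (mg) and ``d_sugar`` (g) are positive when intake falls;
    ``d_fiber`` (g) is positive when intake rises; ``d_energy`` is
    identically zero under any isocaloric scenario.
    """

    d_sodium: float = 0.0
    d_sugar: float = 0.0
    d_fiber: float = 0.0
    d_energy: float = 0.0

    def scaled(self, factor: float) -> "NutrientDelta":
        return NutrientDelta(
            self.d_sodium * factor,
            self.d_sugar * factor,
            self.d_fiber * factor,
            self.d_energy * factor,
        )


def apply_scenario(
    intake: ParticipantIntake, spec: ScenarioSpec
) -> tuple[NutrientTotals, NutrientDelta]:
    """Recompute one participant's totals under a scenario.

    A participant with zero UPF intake passes through unchanged (and stays
    in every downstream denominator).  New totals cannot go negative: each
    reduction is at most ``(1 - m) * upf_amount <= upf_amount <= total``.
    """
    if not 0.0 <= spec.f <= 1.0:
        raise ValueError(f"replacement fraction must be in [0, 1], got {spec.f}")
    u, t = intake.upf, intake.total
    d_sodium = (1.0 - spec.m_sodium) * spec.f * u.sodium
    d_sugar = (1.0 - spec.m_sugar) * spec.f * u.added_sugar
    d_fiber = (spec.m_fiber - 1.0) * spec.f * u.fiber
    new = NutrientTotals(
        energy=t.energy,
        sodium=t.sodium - d_sodium,
        added_sugar=t.added_sugar - d_sugar,
        fiber=t.fiber + d_fiber,
    )
    # NutrientTotals' own invariant re-checks non-negativity; for m <= 1 the
    # reduction is bounded by the UPF pool, which never exceeds the total.
    return new, NutrientDelta(d_sodium=d_sodium, d_sugar=d_sugar, d_fiber=d_fiber)


def run_scenarios(
    intakes: Sequence[ParticipantIntake], specs: Sequence[ScenarioSpec]
) -> pd.DataFrame:
    """Apply each scenario to each participant.

    Returns a long table with one row per (participant, scenario) carrying
    baseline totals, post-substitution totals and deltas.  Scenario names
    must be unique; deltas satisfy ``delta(f) = f * delta(1)`` exactly.
    """
    if not specs:
        raise ValueError("at least one scenario required")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate scenario names: {names}")
    rows = []
    for spec in specs:
        for intake in intakes:
            new, delta = apply_scenario(intake, spec)
            rows.append(
                {
                    "participant_id": intake.participant_id,
                    "scenario": spec.name,
                    "f": spec.f,
                    "baseline_energy": intake.total.energy,
                    "baseline_sodium": intake.total.sodium,
                    "baseline_sugar": intake.total.added_sugar,
                    "baseline_fiber": intake.total.fiber,
                    "new_energy": new.energy,
                    "new_sodium": new.sodium,
                    "new_sugar": new.added_sugar,
                    "new_fiber": new.fiber,
                    "d_sodium": delta.d_sodium,
                    "d_sugar": delta.d_sugar,
                    "d_fiber": delta.d_fiber,
                    "d_energy": delta.d_energy,
                }
            )
    return pd.DataFrame(rows)
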