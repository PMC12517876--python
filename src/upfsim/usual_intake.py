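"""Forward Monte Carlo simulation of usual nutrient intake.

A single 24-hour recall observes one realization of a person's intake;
their *usual* (long-run average) intake varies day to day.  This module
simulates that variation forward: for each participant and nutrient it
draws ``n_draws`` values around the observed amount with a fixed
within-person coefficient of variation (default 20%), by default from a
lognormal distribution moment-matched to (mean = observed, CV = cv):

    sigma^2 = ln(1 + cv^2),   mu = ln(observed) - sigma^2 / 2

so the arithmetic mean of the draws equals the observed value in
expectation and all draws are strictly positive.  A truncated-normal
family is available by config.  This is forward simulation only — it is
not a measurement-error deconvolution (NCI/ISU-style) usual-intake model.

Per-participant random substreams are derived deterministically from
(seed, participant_id), so subsetting a population never changes any
remaining participant's draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import ParticipantIntake

__all__ = [
    "UsualIntakeConfig",
    "DrawSummary",
    "participant_rng",
    "simulate_usual_intake",
    "simulate_population",
]

_PERCENTILES = (2.5, 25.0, 50.0, 75.0, 97.5)


@dataclass(frozen=True)
class UsualIntakeConfig:
    """Monte Carlo settings: draws per participant, within-person CV, family, seed."""

    n_draws: int = 10_000
    cv: float = 0.20
    family: str = "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError(f"n_draws must be >= 1, got {self.n_draws}")
        if self.cv < 0:
            raise ValueError(f"cv must be >= 0, got {self.cv}")
        if self.family not in ("lognormal", "truncated_normal"):
            raise ValueError(
                f"family must be 'lognormal' or 'truncated_normal', got {self.family!r}"
            )


@dataclass(frozen=True)
class DrawSummary:
    """Summary of one participant-nutrient draw vector."""

    mean: float
    sd: float
    cv_hat: float
    p2_5: float
    p25: float
    p50: float
    p75: float
    p97_5: float

    @classmethod
    def from_draws(cls, draws: np.ndarray) -> "DrawSummary":
        mean = float(np.mean(draws))
        sd = float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0
        pct = np.percentile(draws, _PERCENTILES)
        return cls(
            mean=mean,
            sd=sd,
            cv_hat=sd / mean if mean > 0 else 0.0,
            p2_5=float(pct[0]),
            p25=float(pct[1]),
            p50=float(pct[2]),
            p75=float(pct[3]),
            p97_5=float(pct[4]),
        )


def participant_rng(seed: int, participant_id: str) -> np.random.Generator:
    """Deterministic per-participant generator derived from (seed, id).

    The id is hashed to a stable 64-bit word and combined with the base
    seed in a :class:`numpy.random.SeedSequence`, so draws for one
    participant are invariant to who else is in the population.
    """
    digest = hashlib.sha256(str(participant_id).encode()).digest()
    word = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), word]))


def _draw(
    observed: float, config: UsualIntakeConfig, rng: np.random.Generator
) -> np.ndarray:
    if observed < 0:
        raise ValueError(f"observed intake must be >= 0, got {observed}")
    n = config.n_draws
    if observed == 0.0 or config.cv == 0.0:
        # Degenerate point mass: zero observed intake has no lognormal
        # representation, and cv = 0 means no within-person variation.
        return np.full(n, observed, dtype=float)
    if config.family == "lognormal":
        sigma2 = np.log1p(config.cv**2)
        mu = np.log(observed) - sigma2 / 2.0
        return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
    # Truncated normal at zero; truncation slightly raises the mean above
    # the observed value (negligible at cv = 0.2, where P(X<0) ~ 3e-7).
    sd = config.cv * observed
    a = (0.0 - observed) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=observed, scale=sd, size=n, random_state=rng)


def simulate_usual_intake(
    observed_value: float,
    config: UsualIntakeConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, DrawSummary]:
    """Simulate usual-intake draws for one observed nutrient amount.

    With a fixed generator state the draw vector is bit-identical across
    calls.  Returns the draws and their :class:`DrawSummary`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    draws = _draw(float(observed_value), config, rng)
    return draws, DrawSummary.from_draws(draws)


_NUTRIENTS = {"sodium": "sodium", "sugar": "added_sugar", "fiber": "fiber"}


def simulate_population(
    intakes: Sequence[ParticipantIntake], config: UsualIntakeConfig
) -> pd.DataFrame:
    """Per-participant usual-intake summaries for sodium, sugar and fiber.

    One row per (participant, nutrient) with the observed value and the
    draw summary.  Each participant uses an independent substream keyed by
    (config.seed, participant_id); full draw vectors are summarized and
    discarded to keep memory flat in population size.
    """
    rows = []
    for intake in intakes:
        rng = participant_rng(config.seed, intake.participant_id)
        for label, attr in _NUTRIENTS.items():
            observed = getattr(intake.total, attr)
            draws = _draw(observed, config, rng)
            s = DrawSummary.from_draws(draws)
            rows.append(
                {
                    "participant_id": intake.participant_id,
                    "nutrient": label,
                    "observed": observed,
                    "mean": s.mean,
                    "sd": s.sd,
                    "cv_hat": s.cv_hat,
                    "p2_5": s.p2_5,
                    "p25": s.p25,
                    "p50": s.p50,
                    "p75": s.p75,
                    "p97_5": s.p97_5,
                }
            )
    return pd.DataFrame(rows)
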