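"""Seeded synthetic survey population calibrated to published group statistics.

Generates participant and food-item tables whose group-level moments match
the published baseline profile of SNAP participants (n = 767) and
nonparticipants (n = 5563): mean/SD of daily energy, sodium, added sugar,
fiber and UPF energy share, plus the demographic, income-band,
food-security and education category mixes.  Per-participant totals are
drawn from moment-matched lognormal marginals tied together by a Gaussian
copula (a mild positive energy-nutrient correlation, default 0.5); the UPF
energy share is logit-normal, moment-matched numerically.

The UPF-attributable nutrient pools are calibrated so that full-replacement
substitution reproduces the published Scenario C group-mean deltas in
expectation (e.g. a SNAP UPF sodium pool of 513.4 mg/d yields a 256.7 mg/d
reduction under a 50% sodium cut).  These pool targets are inversions of
printed results, not measured survey facts.

Each participant's totals are then split into 8-20 food items: UPF pools
across NOVA-4 items and the remainder across NOVA-1/2/3 items, with
Dirichlet weights shared across nutrients so item sums reproduce the drawn
totals exactly.  Item descriptions are sampled from the package's labeled
vocabulary consistent with each item's intended group, which makes the
keyword classifier's round-trip agreement measurable on every generated
population.  Survey design fields are synthesized as 15 strata x 2 PSUs
with lognormal weights.  Everything is driven by one seed; identical
configs give byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from . import nova
from .records import derive_food_security, derive_pir_category

__all__ = [
    "GroupTargets",
    "PopulationConfig",
    "GenerationAudit",
    "generate_population",
    "make_worked_example",
    "SNAP_TARGETS",
    "NONSNAP_TARGETS",
]

_EDUCATION_LEVELS = (
    "Less than high school",
    "High school/GED",
    "Some college/Associate",
    "Bachelor or higher",
)
_RACE_LEVELS = (
    "Mexican American",
    "Other Hispanic",
    "Non-Hispanic White",
    "Non-Hispanic Black",
    "Other Race",
)
_FS_LEVELS = ("high", "marginal", "low", "very_low")
_PIR_LEVELS = ("low", "near_poverty", "higher")
_FS_SCORE_RANGES = {"high": (0, 0), "marginal": (1, 2), "low": (3, 5), "very_low": (6, 10)}
_PIR_RANGES = {"low": (0.0, 1.2999), "near_poverty": (1.30, 1.85), "higher": (1.8501, 5.0)}


@dataclass(frozen=True)
class GroupTargets:
    """Calibration targets for one SNAP-status group.

    Nutrient targets are (mean, SD) of daily totals; ``upf_*_pool`` are the
    target mean UPF-attributable amounts (the pools substitution acts on).
    Category probability tuples follow the level orders of the module
    constants and must each sum to one.
    """

    n: int
    energy: tuple[float, float]
    sodium: tuple[float, float]
    added_sugar: tuple[float, float]
    fiber: tuple[float, float]
    upf_share: tuple[float, float]
    upf_sodium_pool: float
    upf_sugar_pool: float
    upf_fiber_pool: float
    p_female: float
    race_probs: tuple[float, ...]
    education_probs: tuple[float, ...]
    pir_probs: tuple[float, ...]
    food_security_probs: tuple[float, ...]
    age_median: float
    age_iqr: tuple[float, float]
    household_median: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        for name in ("energy", "sodium", "added_sugar", "fiber", "upf_share"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd <= 0:
                raise ValueError(f"{name}: mean and SD must be > 0, got {(mean, sd)}")
        if not 0 < self.upf_share[0] < 1:
            raise ValueError("upf_share mean must be in (0, 1)")
        for name in ("race_probs", "education_probs", "pir_probs", "food_security_probs"):
            probs = getattr(self, name)
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {sum(probs)}")
            if any(p < 0 for p in probs):
                raise ValueError(f"{name} must be non-negative")


#: SNAP participants: published baseline moments and Scenario-C-implied pools.
SNAP_TARGETS = GroupTargets(
    n=767,
    energy=(1884.5, 542.3),
    sodium=(3452.1, 1104.2),
    added_sugar=(127.4, 45.2),
    fiber=(15.1, 5.6),
    upf_share=(0.582, 0.115),
    upf_sodium_pool=256.7 / 0.5,   # 513.4 mg/d
    upf_sugar_pool=30.7 / 0.8,     # 38.375 g/d
    upf_fiber_pool=1.13 / 0.5,     # 2.26 g/d
    p_female=0.560,
    race_probs=(0.151, 0.098, 0.367, 0.321, 0.063),
    education_probs=(0.270, 0.330, 0.300, 0.100),
    pir_probs=(0.720, 0.180, 0.100),
    food_security_probs=(0.220, 0.180, 0.340, 0.260),
    age_median=39.0,
    age_iqr=(29.0, 52.0),
    household_median=3,
)

#: Nonparticipants (unweighted n = 5563).
NONSNAP_TARGETS = GroupTargets(
    n=5563,
    energy=(1950.6, 531.9),
    sodium=(3610.2, 1010.8),
    added_sugar=(133.1, 41.8),
    fiber=(16.2, 5.4),
    upf_share=(0.556, 0.107),
    upf_sodium_pool=294.1 / 0.5,   # 588.2 mg/d
    upf_sugar_pool=31.4 / 0.8,     # 39.25 g/d
    upf_fiber_pool=1.25 / 0.5,     # 2.50 g/d
    p_female=0.527,
    race_probs=(0.067, 0.081, 0.593, 0.237, 0.022),
    education_probs=(0.101, 0.240, 0.310, 0.349),
    pir_probs=(0.160, 0.180, 0.660),
    food_security_probs=(0.590, 0.200, 0.150, 0.060),
    age_median=44.0,
    age_iqr=(31.0, 57.0),
    household_median=2,
)


@dataclass(frozen=True)
class PopulationConfig:
    """Full generator configuration; hashed into every generation audit."""

    snap: GroupTargets = SNAP_TARGETS
    nonsnap: GroupTargets = NONSNAP_TARGETS
    items_min: int = 8
    items_max: int = 20
    n_strata: int = 15
    n_psu_per_stratum: int = 2
    energy_nutrient_corr: float = 0.5
    weight_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.items_min <= self.items_max:
            raise ValueError("need 1 <= items_min <= items_max")
        if self.n_psu_per_stratum < 2:
            raise ValueError("each stratum needs >= 2 PSUs for variance estimation")
        if not 0 <= self.energy_nutrient_corr < 1:
            raise ValueError("energy_nutrient_corr must be in [0, 1)")

    @property
    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class GenerationAudit:
    """Realized-vs-target moments, classifier round-trip rate, seed, config hash."""

    targets: dict[str, dict[str, float]]
    realized: dict[str, dict[str, float]]
    roundtrip_agreement: float
    seed: int
    config_hash: str

    def as_dict(self) -> dict:
        return {
            "targets": self.targets,
            "realized": self.realized,
            "roundtrip_agreement": self.roundtrip_agreement,
            "seed": self.seed,
            "config_hash": self.config_hash,
        }


def _logit_normal_params(mean: float, sd: float) -> tuple[float, float]:
    """Solve for (mu, sigma) of a logit-normal with the given mean and SD.

    Moments are evaluated by Gauss-Hermite quadrature; infeasible targets
    (SD too large for the mean) raise a config error naming the field.
    """
    nodes, weights = np.polynomial.hermite.hermgauss(80)
    z = np.sqrt(2.0) * nodes
    w = weights / np.sqrt(np.pi)

    def moments(params: np.ndarray) -> np.ndarray:
        mu, log_sigma = params
        x = special.expit(mu + np.exp(log_sigma) * z)
        m1 = np.sum(w * x)
        m2 = np.sum(w * x**2)
        return np.array([m1 - mean, np.sqrt(max(m2 - m1**2, 1e-12)) - sd])

    guess = np.array([special.logit(mean), np.log(sd / (mean * (1 - mean)))])
    sol = optimize.root(moments, guess, method="hybr")
    if not sol.success or np.max(np.abs(moments(sol.x))) > 1e-8:
        raise ValueError(
            f"upf_share target (mean={mean}, sd={sd}) is not attainable by a "
            "logit-normal distribution"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _lognormal_from_z(z: np.ndarray, mean: float, sd: float) -> np.ndarray:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return np.exp(mu + np.sqrt(sigma2) * z)


def _sample_categories(
    rng: np.random.Generator, levels: Sequence[str], probs: Sequence[float], n: int
) -> np.ndarray:
    return rng.choice(np.array(levels, dtype=object), size=n, p=np.asarray(probs))


def _generate_group(
    rng: np.random.Generator,
    targets: GroupTargets,
    config: PopulationConfig,
    prefix: str,
    vocab: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """One group's participants, foods, and intended item labels."""
    n = targets.n
    rho = config.energy_nutrient_corr
    # Common-factor Gaussian copula: energy is the factor; each nutrient
    # correlates with energy at rho (and pairwise at rho^2); share is free.
    u = rng.standard_normal((5, n))
    z_energy = u[0]
    z_nut = rho * z_energy + np.sqrt(1 - rho**2) * u[1:4]
    z_share = u[4]

    energy = _lognormal_from_z(z_energy, *targets.energy)
    sodium = _lognormal_from_z(z_nut[0], *targets.sodium)
    sugar = _lognormal_from_z(z_nut[1], *targets.added_sugar)
    fiber = _lognormal_from_z(z_nut[2], *targets.fiber)
    mu_s, sig_s = _logit_normal_params(*targets.upf_share)
    share = special.expit(mu_s + sig_s * z_share)

    upf_energy = share * energy
    rel_share = share / targets.upf_share[0]
    pools = {}
    for nutrient, values, pool_mean, total_mean in (
        ("sodium", sodium, targets.upf_sodium_pool, targets.sodium[0]),
        ("sugar", sugar, targets.upf_sugar_pool, targets.added_sugar[0]),
        ("fiber", fiber, targets.upf_fiber_pool, targets.fiber[0]),
    ):
        frac = np.clip(pool_mean / total_mean * rel_share, 0.0, 0.98)
        pools[nutrient] = frac * values

    pids = np.array([f"{prefix}{i:05d}" for i in range(n)], dtype=object)
    sex = np.where(rng.random(n) < targets.p_female, "female", "male")
    race = _sample_categories(rng, _RACE_LEVELS, targets.race_probs, n)
    education = _sample_categories(rng, _EDUCATION_LEVELS, targets.education_probs, n)
    pir_cat = _sample_categories(rng, _PIR_LEVELS, targets.pir_probs, n)
    fs_cat = _sample_categories(rng, _FS_LEVELS, targets.food_security_probs, n)
    pir = np.array(
        [rng.uniform(*_PIR_RANGES[c]) for c in pir_cat], dtype=float
    )
    fs_score = np.array(
        [rng.integers(lo, hi + 1) for lo, hi in (_FS_SCORE_RANGES[c] for c in fs_cat)],
        dtype=int,
    )
    age_sd = (targets.age_iqr[1] - targets.age_iqr[0]) / 1.349
    age = np.clip(rng.normal(targets.age_median, age_sd, n), 18.0, 85.0).round(0)
    household = 1 + rng.poisson(targets.household_median - 1, n)
    weight = rng.lognormal(0.0, config.weight_sigma, n)

    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "age": age,
            "sex": sex,
            "race_ethnicity": race,
            "snap": prefix == "S",
            "pir": pir,
            "food_security_score": fs_score,
            "education": education,
            "household_size": household,
            "weight": weight,
            # stratum/psu assigned over the combined population by the caller
            "stratum": "",
            "psu": "",
        }
    )

    vocab_by_group = {g: sub.reset_index() for g, sub in vocab.groupby("nova_group")}
    non_upf_vocab = vocab[vocab["nova_group"] != 4].reset_index()

    food_rows: list[dict] = []
    label_rows: list[dict] = []
    n_items_all = rng.integers(config.items_min, config.items_max + 1, size=n)
    for i in range(n):
        n_items = int(n_items_all[i])
        n_upf = int(np.clip(round(share[i] * n_items), 1, n_items - 1))
        strata = (
            ("upf", n_upf, upf_energy[i], pools["sodium"][i], pools["sugar"][i], pools["fiber"][i]),
            (
                "non_upf",
                n_items - n_upf,
                energy[i] - upf_energy[i],
                sodium[i] - pools["sodium"][i],
                sugar[i] - pools["sugar"][i],
                fiber[i] - pools["fiber"][i],
            ),
        )
        for kind, count, e_pool, na_pool, su_pool, fi_pool in strata:
            w = rng.dirichlet(np.ones(count))
            if kind == "upf":
                pick = vocab_by_group[4].iloc[rng.integers(0, len(vocab_by_group[4]), count)]
            else:
                pick = non_upf_vocab.iloc[rng.integers(0, len(non_upf_vocab), count)]
            for j in range(count):
                food_rows.append(
                    {
                        "participant_id": pids[i],
                        "food_code": int(10_000_000 + 100 * int(pick["index"].iloc[j]) + j),
                        "description": pick["description"].iloc[j],
                        "energy_kcal": w[j] * e_pool,
                        "sodium_mg": w[j] * na_pool,
                        "added_sugar_g": w[j] * su_pool,
                        "fiber_g": w[j] * fi_pool,
                    }
                )
                label_rows.append(
                    {
                        "participant_id": pids[i],
                        "intended_group": int(pick["nova_group"].iloc[j]),
                    }
                )
    return participants, pd.DataFrame(food_rows), pd.DataFrame(label_rows)


def _realized_moments(
    participants: pd.DataFrame, foods: pd.DataFrame
) -> dict[str, dict[str, float]]:
    totals = foods.groupby("participant_id", sort=False).agg(
        energy=("energy_kcal", "sum"),
        sodium=("sodium_mg", "sum"),
        sugar=("added_sugar_g", "sum"),
        fiber=("fiber_g", "sum"),
    )
    merged = participants.merge(totals, on="participant_id")
    out = {}
    for name, mask in (("snap", merged["snap"]), ("nonsnap", ~merged["snap"])):
        sub = merged[mask]
        out[name] = {
            "n": int(len(sub)),
            "energy_mean": float(sub["energy"].mean()),
            "energy_sd": float(sub["energy"].std()),
            "sodium_mean": float(sub["sodium"].mean()),
            "sodium_sd": float(sub["sodium"].std()),
            "sugar_mean": float(sub["sugar"].mean()),
            "sugar_sd": float(sub["sugar"].std()),
            "fiber_mean": float(sub["fiber"].mean()),
            "fiber_sd": float(sub["fiber"].std()),
        }
    return out


def generate_population(
    config: PopulationConfig = PopulationConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame, GenerationAudit]:
    """Generate (participants, foods, audit) for the configured population.

    Deterministic in ``config.seed``; the audit reports realized group
    moments next to their targets, the keyword classifier's agreement with
    the intended item groups, and the config hash.
    """
    vocab = nova.load_vocabulary()
    rng_snap = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rng_non = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    p_snap, f_snap, l_snap = _generate_group(rng_snap, config.snap, config, "S", vocab)
    p_non, f_non, l_non = _generate_group(rng_non, config.nonsnap, config, "N", vocab)
    participants = pd.concat([p_snap, p_non], ignore_index=True)
    foods = pd.concat([f_snap, f_non], ignore_index=True)
    labels = pd.concat([l_snap, l_non], ignore_index=True)

    # Survey design: cycle participants through (stratum, psu) cells so every
    # stratum holds at least two PSUs whenever n >= n_strata * n_psu.
    cells = [
        (f"ST{s + 1:02d}", f"PSU{p + 1}")
        for s in range(config.n_strata)
        for p in range(config.n_psu_per_stratum)
    ]
    idx = np.arange(len(participants)) % len(cells)
    participants["stratum"] = [cells[i][0] for i in idx]
    participants["psu"] = [cells[i][1] for i in idx]
    participants["pir_category"] = participants["pir"].map(derive_pir_category)
    fs = participants["food_security_score"].map(derive_food_security)
    participants["food_security_level"] = [lv for lv, _ in fs]
    participants["food_insecure"] = [ins for _, ins in fs]

    # Classifier round-trip: assign groups from descriptions alone and
    # compare with the intended labels drawn during generation.
    rules = nova.default_rules()
    unique = {
        d: int(nova.classify_food(d, rules)[0]) for d in foods["description"].unique()
    }
    assigned = foods["description"].map(unique)
    agreement = float((assigned.to_numpy() == labels["intended_group"].to_numpy()).mean())

    targets = {
        name: {
            "n": grp.n,
            "energy_mean": grp.energy[0],
            "energy_sd": grp.energy[1],
            "sodium_mean": grp.sodium[0],
            "sodium_sd": grp.sodium[1],
            "sugar_mean": grp.added_sugar[0],
            "sugar_sd": grp.added_sugar[1],
            "fiber_mean": grp.fiber[0],
            "fiber_sd": grp.fiber[1],
            "upf_share_mean": grp.upf_share[0],
            "upf_share_sd": grp.upf_share[1],
        }
        for name, grp in (("snap", config.snap), ("nonsnap", config.nonsnap))
    }
    audit = GenerationAudit(
        targets=targets,
        realized=_realized_moments(participants, foods),
        roundtrip_agreement=agreement,
        seed=config.seed,
        config_hash=config.content_hash,
    )
    return participants, foods, audit


def make_worked_example() -> tuple[pd.DataFrame, pd.DataFrame]:
    """A tiny fixed population (6 participants, 17 items) with hand-checkable sums.

    Participant W1 carries exactly 1000 mg of UPF sodium, so full replacement
    cuts their sodium by 500 mg; every total below can be re-derived by hand.
    """
    food_rows = [
        # pid, code, description, kcal, na mg, sugar g, fiber g
        ("W1", 11100001, "HOT DOG FRANKFURTER BEEF", 500.0, 1000.0, 5.0, 1.0),
        ("W1", 11100002, "APPLE RAW", 500.0, 200.0, 10.0, 4.0),
        ("W2", 11100003, "CHICKEN BREAST ROASTED PLAIN", 400.0, 300.0, 0.0, 0.0),
        ("W2", 11100004, "RICE BROWN COOKED PLAIN", 600.0, 100.0, 0.0, 6.0),
        ("W2", 11100005, "MILK WHOLE PLAIN", 200.0, 100.0, 0.0, 0.0),
        ("W3", 11100006, "SOFT DRINK COLA", 150.0, 50.0, 40.0, 0.0),
        ("W3", 11100007, "POTATO CHIPS", 300.0, 400.0, 2.0, 2.0),
        ("W3", 11100008, "BEANS BLACK COOKED PLAIN", 250.0, 100.0, 0.0, 10.0),
        ("W3", 11100009, "EGG WHOLE COOKED", 300.0, 250.0, 0.0, 0.0),
        ("W4", 11100010, "FROZEN MEAL DINNER READY TO HEAT", 700.0, 1400.0, 10.0, 3.0),
        ("W4", 11100011, "SODA ORANGE", 200.0, 60.0, 50.0, 0.0),
        ("W4", 11100012, "BANANA RAW", 100.0, 0.0, 12.0, 3.0),
        ("W5", 11100013, "PIZZA PEPPERONI FROZEN", 800.0, 1600.0, 8.0, 4.0),
        ("W5", 11100014, "SPINACH FRESH COOKED", 200.0, 150.0, 0.0, 8.0),
        ("W6", 11100015, "CEREAL READY TO EAT SWEETENED", 300.0, 250.0, 30.0, 2.0),
        ("W6", 11100016, "MILK LOW FAT PLAIN", 150.0, 120.0, 0.0, 0.0),
        ("W6", 11100017, "SALMON FRESH BAKED", 450.0, 400.0, 0.0, 0.0),
    ]
    foods = pd.DataFrame(
        food_rows,
        columns=[
            "participant_id",
            "food_code",
            "description",
            "energy_kcal",
            "sodium_mg",
            "added_sugar_g",
            "fiber_g",
        ],
    )
    participant_rows = [
        # pid, age, sex, race, snap, pir, fs, educ, hh, weight, stratum, psu
        ("W1", 35, "female", "Non-Hispanic Black", True, 0.9, 4, "High school/GED", 3, 1.0, "ST1", "PSU1"),
        ("W2", 42, "male", "Mexican American", True, 1.1, 6, "Less than high school", 4, 2.0, "ST1", "PSU2"),
        ("W3", 29, "female", "Non-Hispanic White", True, 1.3, 2, "Some college/Associate", 2, 1.0, "ST1", "PSU1"),
        ("W4", 51, "male", "Other Hispanic", True, 0.7, 8, "High school/GED", 5, 2.0, "ST1", "PSU2"),
        ("W5", 44, "female", "Non-Hispanic White", False, 2.5, 0, "Bachelor or higher", 2, 1.0, "ST2", "PSU1"),
        ("W6", 38, "male", "Non-Hispanic White", False, 3.2, 1, "Some college/Associate", 1, 1.0, "ST2", "PSU2"),
    ]
    participants = pd.DataFrame(
        participant_rows,
        columns=[
            "participant_id",
            "age",
            "sex",
            "race_ethnicity",
            "snap",
            "pir",
            "food_security_score",
            "education",
            "household_size",
            "weight",
            "stratum",
            "psu",
        ],
    )
    participants["pir_category"] = participants["pir"].map(derive_pir_category)
    fs = participants["food_security_score"].map(derive_food_security)
    participants["food_security_level"] = [lv for lv, _ in fs]
    participants["food_insecure"] = [ins for _, ins in fs]
    return participants, foods
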