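import numpy as np
import pytest

from upfsim import nova, synthetic
from upfsim.records import FoodRecord, NovaGroup


@pytest.fixture(scope="session")
def rules():
    return nova.default_rules()


@pytest.fixture(scope="session")
def vocabulary():
    return nova.load_vocabulary()


@pytest.fixture(scope="session")
def worked_example():
    """Tiny fixed population with hand-checkable totals."""
    return synthetic.make_worked_example()


@pytest.fixture(scope="session")
def small_population():
    """A reduced synthetic population (fast, still classifier-complete)."""
    from dataclasses import replace

    cfg = synthetic.PopulationConfig(
        snap=replace(synthetic.SNAP_TARGETS, n=150),
        nonsnap=replace(synthetic.NONSNAP_TARGETS, n=250),
        n_strata=5,
        seed=42,
    )
    participants, foods, audit = synthetic.generate_population(cfg)
    return cfg, participants, foods, audit


@pytest.fixture(scope="session")
def full_population():
    """The default-size population (767 SNAP / 5563 non-SNAP), generated once."""
    cfg = synthetic.PopulationConfig(seed=7)
    participants, foods, audit = synthetic.generate_population(cfg)
    return cfg, participants, foods, audit


def random_classified_foods(rng: np.random.Generator, n_participants: int = 5,
                            max_items: int = 8) -> list[FoodRecord]:
    """Random already-classified items for aggregation/substitution oracles."""
    foods = []
    for p in range(n_participants):
        for j in range(int(rng.integers(1, max_items + 1))):
            foods.append(
                FoodRecord(
                    participant_id=f"P{p}",
                    food_code=int(10_000_000 + 100 * p + j),
                    description="FIXTURE ITEM",
                    energy=float(rng.uniform(10, 800)),
                    sodium=float(rng.uniform(0, 1500)),
                    added_sugar=float(rng.uniform(0, 60)),
                    fiber=float(rng.uniform(0, 12)),
                    nova_group=NovaGroup(int(rng.choice([1, 2, 3, 4]))),
                )
            )
    return foods
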