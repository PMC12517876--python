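"""Keyword-rule NOVA classification of food descriptions.

Foods are assigned to one of the four NOVA processing groups (minimally
processed; culinary ingredients; processed; ultra-processed) by a
priority-ordered table of whole-word keyword rules applied to normalized
FNDDS-style description text.  Every assignment is auditable: each item
yields a :class:`ClassificationAudit` naming the rule that fired and the
matched text span, and the rule table itself is a plain CSV whose hash is
logged with every run.

Matching semantics
------------------
* Descriptions and patterns are tokenized on word boundaries; a pattern
  (one or more words) matches only as a contiguous whole-word sequence, so
  ``HAM`` never matches ``GRAHAM CRACKERS``.
* Among all matching rules the highest priority wins; ties break toward
  the longer matched pattern, then toward the higher NOVA group (the
  conservative "more processed" call — misclassifying an ultra-processed
  item as minimally processed biases substitution deltas toward null).
* No match falls through to the rule set's ``default_group``, which is
  UNCLASSIFIED in the shipped table: silent defaults would hide
  vocabulary gaps.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .records import FoodRecord, NovaGroup, ParticipantIntake, normalize_description

__all__ = [
    "KeywordRule",
    "RuleSet",
    "ClassificationAudit",
    "classify_food",
    "classify_all",
    "upf_energy_share",
    "default_rules",
    "load_vocabulary",
]


@dataclass(frozen=True)
class KeywordRule:
    """One keyword/phrase rule: whole-word pattern -> NOVA group at a priority."""

    rule_id: str
    pattern: str
    nova_group: NovaGroup
    priority: int

    def __post_init__(self) -> None:
        pattern = normalize_description(self.pattern)
        if not pattern:
            raise ValueError(f"rule {self.rule_id!r}: empty pattern")
        object.__setattr__(self, "pattern", pattern)
        object.__setattr__(self, "nova_group", NovaGroup(self.nova_group))
        if self.nova_group is NovaGroup.UNCLASSIFIED:
            raise ValueError(f"rule {self.rule_id!r}: rules must target groups 1-4")

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(self.pattern.split())


@dataclass
class RuleSet:
    """An ordered, uniquely-identified collection of keyword rules."""

    rules: list[KeywordRule]
    default_group: NovaGroup = NovaGroup.UNCLASSIFIED
    name: str = "custom"

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.rules]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate rule_id(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.rules)

    @property
    def content_hash(self) -> str:
        """Stable hash of the rule table, logged by every analysis run."""
        canon = "\n".join(
            f"{r.rule_id}\t{r.pattern}\t{int(r.nova_group)}\t{r.priority}"
            for r in sorted(self.rules, key=lambda r: r.rule_id)
        ) + f"\ndefault={self.default_group}"
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_csv(cls, path: str | Path, default_group: NovaGroup = NovaGroup.UNCLASSIFIED) -> "RuleSet":
        df = pd.read_csv(path)
        required = {"rule_id", "pattern", "nova_group", "priority"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: rule table missing column(s) {sorted(missing)}")
        rules = [
            KeywordRule(
                rule_id=str(row.rule_id),
                pattern=str(row.pattern),
                nova_group=NovaGroup(int(row.nova_group)),
                priority=int(row.priority),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(rules=rules, default_group=default_group, name=str(path))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "rule_id": [r.rule_id for r in self.rules],
                "pattern": [r.pattern for r in self.rules],
                "nova_group": [int(r.nova_group) for r in self.rules],
                "priority": [r.priority for r in self.rules],
            }
        ).to_csv(path, index=False)


@dataclass
class ClassificationAudit:
    """Provenance for one classified item: which rule fired and where."""

    description: str
    assigned_group: NovaGroup
    matched_rule_id: str | None = None
    matched_span: str | None = None
    reason: str = "matched"
    food_code: int | None = None

    def as_dict(self) -> dict[str, object]:
        return {
            "food_code": self.food_code,
            "description": self.description,
            "nova_group": str(self.assigned_group),
            "matched_rule_id": self.matched_rule_id,
            "matched_span": self.matched_span,
            "reason": self.reason,
        }


def _phrase_in_tokens(phrase: tuple[str, ...], tokens: tuple[str, ...]) -> bool:
    n = len(phrase)
    if n == 0 or n > len(tokens):
        return False
    return any(tokens[i : i + n] == phrase for i in range(len(tokens) - n + 1))


def classify_food(
    description: str, rules: RuleSet, food_code: int | None = None
) -> tuple[NovaGroup, ClassificationAudit]:
    """Classify one normalized description, returning the group and its audit.

    The winning rule maximizes (priority, matched pattern length, NOVA
    group); an empty description is UNCLASSIFIED with reason ``"empty"``
    and a description matching no rule takes the rule set's default group.
    """
    text = normalize_description(description)
    if not text:
        return NovaGroup.UNCLASSIFIED, ClassificationAudit(
            description="",
            assigned_group=NovaGroup.UNCLASSIFIED,
            reason="empty",
            food_code=food_code,
        )
    tokens = tuple(text.split())
    best: KeywordRule | None = None
    best_key: tuple[int, int, int] | None = None
    for rule in rules.rules:
        if _phrase_in_tokens(rule.tokens, tokens):
            key = (rule.priority, len(rule.pattern), int(rule.nova_group))
            if best_key is None or key > best_key:
                best, best_key = rule, key
    if best is None:
        return rules.default_group, ClassificationAudit(
            description=text,
            assigned_group=rules.default_group,
            reason="no_match",
            food_code=food_code,
        )
    return best.nova_group, ClassificationAudit(
        description=text,
        assigned_group=best.nova_group,
        matched_rule_id=best.rule_id,
        matched_span=best.pattern,
        food_code=food_code,
    )


def classify_all(
    foods: Sequence[FoodRecord], rules: RuleSet
) -> tuple[list[FoodRecord], list[ClassificationAudit]]:
    """Classify every item, returning new records plus one audit row per item.

    Deterministic and order-invariant: an item's assignment depends only on
    its own description and the rule set.  Results are memoized per unique
    description, which makes classifying populations whose descriptions are
    drawn from a finite vocabulary effectively free.
    """
    cache: dict[str, tuple[NovaGroup, ClassificationAudit]] = {}
    out: list[FoodRecord] = []
    audits: list[ClassificationAudit] = []
    for food in foods:
        hit = cache.get(food.description)
        if hit is None:
            hit = classify_food(food.description, rules)
            cache[food.description] = hit
        group, proto = hit
        audit = replace(proto, food_code=food.food_code)
        out.append(replace(food, nova_group=group))
        audits.append(audit)
    return out, audits


def audits_to_frame(audits: Iterable[ClassificationAudit]) -> pd.DataFrame:
    """Render an audit log as a DataFrame (one row per classified item)."""
    return pd.DataFrame([a.as_dict() for a in audits])


def upf_energy_share(intake: ParticipantIntake) -> float:
    """Fraction of daily energy from NOVA-4 foods; requires positive total energy."""
    if intake.total.energy <= 0:
        raise ValueError(
            f"participant {intake.participant_id}: UPF energy share undefined "
            "at zero total energy"
        )
    return intake.upf.energy / intake.total.energy


def default_rules() -> RuleSet:
    """Load the curated default keyword rule table shipped with the package.

    The table operationalizes the NOVA exemplars commonly used for FNDDS
    descriptions (sodas, candy, chips, chicken nuggets, hot dogs,
    commercially prepared breads, ready-to-heat frozen meals as group 4;
    table sugar, oils, salt as group 2; brined/canned vegetables, cheese,
    bakery bread as group 3; raw fruit, plain milk, grains as group 1).
    It is a plain CSV — editable, versioned, hashed into every run log.
    """
    with resources.as_file(
        resources.files("upfsim.data").joinpath("default_nova_rules.csv")
    ) as path:
        ruleset = RuleSet.from_csv(path)
    ruleset.name = "default"
    return ruleset


def load_vocabulary() -> pd.DataFrame:
    """Load the labeled description vocabulary (columns description, nova_group).

    Built jointly with the default rule table: classifying each entry with
    :func:`default_rules` reproduces its label.  The synthetic-population
    generator samples item descriptions from this vocabulary.
    """
    with resources.as_file(
        resources.files("upfsim.data").joinpath("vocabulary.csv")
    ) as path:
        df = pd.read_csv(path)
    df["description"] = df["description"].map(normalize_description)
    df["nova_group"] = df["nova_group"].astype(int)
    return df
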