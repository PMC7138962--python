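"""Decision lists separating Phase 1 (early) from Phase 2 (late) amino acids.

Amino acids are commonly split into a prebiotic Phase 1 set, available before
biosynthetic pathways evolved, and a Phase 2 set of later products.  Two
features separate the sets almost perfectly: the mean buried area (MBA, A^2)
of the residue and its hydrophobicity log10 Kw>c.  The shipped rule (one
conjunctive IF, first-match semantics) is

    IF MBA > 97.8 AND log10 Kw>c(T) <= theta_T AND MBA > 113.9 THEN phase2
    ELSE phase1

with theta_25 = 2.64 and theta_100 = 2.60.  Against the reference sets it
scores 19/20 at either temperature; asparagine is the single error.  The
lists are applied and evaluated here as data — rule induction is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .codebook import AMINO_ACIDS
from .scales import get_scale, logkwc_scale

__all__ = [
    "PHASE1",
    "PHASE2",
    "Condition",
    "Rule",
    "DecisionList",
    "decision_list",
    "phase_features",
    "apply_decision_list",
    "evaluate_rules",
]

#: Reference truth sets (disjoint; together cover all 20 amino acids).
PHASE1 = frozenset("LIVSPTADEG")
PHASE2 = frozenset("FMYHQNKCWR")

assert PHASE1 | PHASE2 == set(AMINO_ACIDS) and not PHASE1 & PHASE2

_OPS = {
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
}


@dataclass(frozen=True)
class Condition:
    """One threshold test: feature <op> value."""

    feature: str
    op: str
    value: float

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown comparator {self.op!r}")

    def holds(self, features: dict[str, float]) -> bool:
        if self.feature not in features:
            raise KeyError(f"missing feature {self.feature!r}")
        return _OPS[self.op](features[self.feature], self.value)


@dataclass(frozen=True)
class Rule:
    """Conjunction of conditions firing a label."""

    conditions: tuple[Condition, ...]
    label: str

    def fires(self, features: dict[str, float]) -> bool:
        return all(c.holds(features) for c in self.conditions)


@dataclass(frozen=True)
class DecisionList:
    """Ordered first-match rules with a default label."""

    rules: tuple[Rule, ...]
    default_label: str
    name: str = ""

    def predict(self, features: dict[str, float]) -> str:
        for rule in self.rules:
            if rule.fires(features):
                return rule.label
        return self.default_label

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "default_label": self.default_label,
                "rules": [
                    {
                        "conditions": [
                            {"feature": c.feature, "op": c.op, "value": c.value}
                            for c in r.conditions
                        ],
                        "label": r.label,
                    }
                    for r in self.rules
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DecisionList":
        obj = json.loads(text)
        rules = tuple(
            Rule(
                conditions=tuple(Condition(**c) for c in r["conditions"]),
                label=r["label"],
            )
            for r in obj["rules"]
        )
        return cls(rules=rules, default_label=obj["default_label"], name=obj.get("name", ""))


_LOGK_THRESHOLD = {25: 2.64, 100: 2.60}
_MBA_LOW = 97.8
_MBA_HIGH = 113.9


def decision_list(temperature: int = 25) -> DecisionList:
    """The published phase rule for 25 C or 100 C (thresholds 2.64 / 2.60)."""
    t = int(temperature)
    if t not in _LOGK_THRESHOLD:
        raise ValueError("decision lists exist for 25 C and 100 C only")
    return DecisionList(
        rules=(
            Rule(
                conditions=(
                    Condition("mean_buried_area", ">", _MBA_LOW),
                    Condition("logkwc", "<=", _LOGK_THRESHOLD[t]),
                    Condition("mean_buried_area", ">", _MBA_HIGH),
                ),
                label="phase2",
            ),
        ),
        default_label="phase1",
        name=f"phase_rule_{t}C",
    )


def phase_features(aa: str, temperature: int = 25) -> dict[str, float]:
    """Feature dict (mean_buried_area, logkwc) for one amino acid."""
    return {
        "mean_buried_area": get_scale("mean_buried_area")[aa],
        "logkwc": logkwc_scale(temperature)[aa],
    }


def apply_decision_list(aa: str, features: dict[str, float], dlist: DecisionList) -> str:
    """First-match evaluation of the list on one amino acid's features."""
    if aa not in AMINO_ACIDS:
        raise ValueError(f"unknown amino acid {aa!r}")
    return dlist.predict(features)


@dataclass(frozen=True)
class RuleEvaluation:
    n_correct: int
    n_total: int
    misclassified: frozenset[str]
    predictions: dict[str, str] = field(hash=False)


def evaluate_rules(
    dlist: DecisionList,
    temperature: int = 25,
    truth: dict[str, str] | None = None,
) -> RuleEvaluation:
    """Score a decision list against the reference phase sets over all 20 amino acids."""
    if truth is None:
        truth = {aa: ("phase1" if aa in PHASE1 else "phase2") for aa in AMINO_ACIDS}
    preds = {aa: apply_decision_list(aa, phase_features(aa, temperature), dlist) for aa in AMINO_ACIDS}
    wrong = frozenset(aa for aa in AMINO_ACIDS if preds[aa] != truth[aa])
    return RuleEvaluation(
        n_correct=len(AMINO_ACIDS) - len(wrong),
        n_total=len(AMINO_ACIDS),
        misclassified=wrong,
        predictions=preds,
    )
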