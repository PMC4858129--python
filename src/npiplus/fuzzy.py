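"""Fuzzy rule-based assignment of the seven NPI+ biological classes.

A tumour's ten-marker profile is fuzzified against per-marker cut-offs
(trapezoidal shoulders of configurable width), rules are evaluated with
Mamdani-style semantics (min for conjunction within a rule, max across the
rules of one class), and the class with the highest activation wins.  A
tumour whose best activation falls below the activation threshold is left
Unclassified.  HER2 enters the rules as a crisp positive/negative status
resolved from the clinical IHC category, not as a fuzzified H-score.

The shipped default rule base is an editable approximation: the original
induced rules are not published, only the cut-off policy and the algorithm
family, so the defaults encode the accepted marker patterns of the seven
classes (luminal = CK7/8+/ER+/HER2-, split by PgR and HER3/HER4; basal =
CK5/6+ or EGFR+ with ER-/HER2-, split by p53; HER2+ split by ER).
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .ihc import MARKERS, CutoffTable, MarkerProfile, resolve_her2

__all__ = [
    "BiologicalClass",
    "CLASS_ORDER",
    "FuzzyRule",
    "RuleBase",
    "membership",
    "rule_activation",
    "classify",
    "classify_cohort",
    "default_rulebase",
    "rulebase_to_yaml",
    "rulebase_from_yaml",
]

logger = logging.getLogger(__name__)


class BiologicalClass(enum.Enum):
    """The seven NPI+ biological classes plus Unclassified.

    Enum definition order is the deterministic tie-break order used by
    classify(); ``index`` is the numeral used in prognostic-group labels
    ("1.1" ... "7.2").
    """

    LUMINAL_A = "Luminal A"
    LUMINAL_N = "Luminal N"
    LUMINAL_B = "Luminal B"
    BASAL_P53_ALTERED = "Basal p53 altered"
    BASAL_P53_NORMAL = "Basal p53 normal"
    HER2_ER_POS = "HER2+/ER+"
    HER2_ER_NEG = "HER2+/ER-"
    UNCLASSIFIED = "Unclassified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def index(self) -> int:
        """1-based class numeral (Unclassified has none)."""
        if self is BiologicalClass.UNCLASSIFIED:
            raise ValueError("Unclassified has no class numeral")
        return CLASS_ORDER.index(self) + 1

    @classmethod
    def from_label(cls, label: str) -> "BiologicalClass":
        for member in cls:
            if member.value == label:
                return member
        # tolerate the unicode minus variant of the ER-negative label
        if label == "HER2+/ER−":
            return cls.HER2_ER_NEG
        raise ValueError(f"unknown biological class label {label!r}")


#: Named classes in tie-break / reporting order.
CLASS_ORDER: tuple[BiologicalClass, ...] = tuple(
    c for c in BiologicalClass if c is not BiologicalClass.UNCLASSIFIED
)


@dataclass(frozen=True)
class FuzzyRule:
    """One rule: a conjunction of (marker, side) antecedents -> class."""

    consequent: BiologicalClass
    antecedents: tuple[tuple[str, str], ...]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.consequent is BiologicalClass.UNCLASSIFIED:
            raise ValueError("a rule cannot conclude Unclassified")
        if not self.antecedents:
            raise ValueError("a rule needs at least one antecedent")
        seen = set()
        for marker, side in self.antecedents:
            if marker not in MARKERS:
                raise ValueError(f"unknown marker {marker!r} in rule")
            if side not in ("low", "high"):
                raise ValueError(f"antecedent side must be low/high, got {side!r}")
            if marker in seen:
                raise ValueError(f"marker {marker} appears twice in one rule")
            seen.add(marker)
        if self.weight < 0:
            raise ValueError("rule weight must be nonnegative")


@dataclass
class RuleBase:
    """A set of fuzzy rules plus fuzzification parameters.

    ``membership_width`` is the half-width (H-score units) of the linear
    shoulder around each cut-off; ``marker_widths`` overrides it per
    marker.  ``activation_threshold`` is the minimum winning activation
    for a named class.
    """

    rules: tuple[FuzzyRule, ...]
    activation_threshold: float = 0.5
    membership_width: float = 20.0
    marker_widths: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rules = tuple(self.rules)
        if not self.rules:
            raise ValueError("rule base is empty")
        if not (0.0 <= self.activation_threshold <= 1.0):
            raise ValueError("activation_threshold must lie in [0, 1]")
        if self.membership_width <= 0:
            raise ValueError("membership_width must be positive")
        covered = {r.consequent for r in self.rules}
        missing = [c.value for c in CLASS_ORDER if c not in covered]
        if missing:
            raise ValueError(f"classes without any rule: {missing}")

    def width(self, marker: str) -> float:
        return float(self.marker_widths.get(marker, self.membership_width))


def membership(value: float, cutoff: float, width: float) -> tuple[float, float]:
    """(mu_low, mu_high) of an H-score against a cut-off.

    Trapezoidal shoulder: mu_high rises linearly from 0 at cutoff-width to
    1 at cutoff+width; mu_low = 1 - mu_high, so the pair always sums to 1
    and the value at the cut-off is exactly (0.5, 0.5).
    """
    if width <= 0:
        raise ValueError("membership width must be positive")
    if value >= cutoff + width:
        hi = 1.0
    elif value <= cutoff - width:
        hi = 0.0
    else:
        hi = (value - (cutoff - width)) / (2.0 * width)
    return 1.0 - hi, hi


def profile_memberships(
    profile: MarkerProfile,
    cutoffs: CutoffTable,
    rulebase: RuleBase,
    her2_status: str,
) -> dict[str, tuple[float, float]]:
    """Per-marker (mu_low, mu_high); HER2 is crisp from its resolved status."""
    if her2_status not in ("positive", "negative"):
        raise ValueError(f"her2_status must be positive/negative, got {her2_status!r}")
    mus: dict[str, tuple[float, float]] = {
        "HER2": (0.0, 1.0) if her2_status == "positive" else (1.0, 0.0)
    }
    for marker in MARKERS:
        if marker == "HER2":
            continue
        value = profile.value(marker)
        if value is None:
            continue  # missing markers contribute zero activation downstream
        mus[marker] = membership(value, cutoffs.value(marker), rulebase.width(marker))
    return mus


def rule_activation(
    memberships: Mapping[str, tuple[float, float]], rule: FuzzyRule
) -> float:
    """weight x min over antecedents of the matching membership side.

    A missing marker yields activation 0 (conservative missing-marker
    policy: the rule simply cannot fire).  The result is clipped to [0, 1].
    """
    act = 1.0
    for marker, side in rule.antecedents:
        mu = memberships.get(marker)
        if mu is None:
            return 0.0
        act = min(act, mu[0] if side == "low" else mu[1])
    return float(min(max(act * rule.weight, 0.0), 1.0))


def classify(
    profile: MarkerProfile,
    cutoffs: CutoffTable,
    rulebase: RuleBase,
    *,
    her2_status: str | None = None,
    her2_mode: str = "exclude_equivocal",
) -> tuple[BiologicalClass, float]:
    """Assign one tumour to a biological class.

    Returns (class, confidence) where confidence is the winning class's
    activation (max over its rules).  Unclassified with its best score is
    returned when no class reaches the activation threshold.  Exact ties
    between classes are broken by the fixed class order and logged.
    """
    if her2_status is None:
        her2_status = resolve_her2(profile, her2_mode)
    if her2_status == "excluded":
        raise ValueError(
            f"patient {profile.patient_id}: HER2-equivocal case cannot be "
            "classified (excluded); filter with resolve_her2 first"
        )
    mus = profile_memberships(profile, cutoffs, rulebase, her2_status)
    scores: dict[BiologicalClass, float] = {c: 0.0 for c in CLASS_ORDER}
    for rule in rulebase.rules:
        act = rule_activation(mus, rule)
        if act > scores[rule.consequent]:
            scores[rule.consequent] = act
    best = max(scores.values())
    if best < rulebase.activation_threshold:
        return BiologicalClass.UNCLASSIFIED, best
    winners = [c for c in CLASS_ORDER if scores[c] == best]
    if len(winners) > 1:
        logger.warning(
            "patient %s: activation tie at %.3f between %s; keeping %s",
            profile.patient_id,
            best,
            [c.value for c in winners],
            winners[0].value,
        )
    return winners[0], best


def classify_cohort(
    cohort: Sequence[MarkerProfile],
    cutoffs: CutoffTable,
    rulebase: RuleBase,
    *,
    her2_mode: str = "exclude_equivocal",
) -> tuple[list[tuple[str, str, float]], Counter]:
    """Classify every tumour in a cohort.

    Returns per-patient records ``(patient_id, label, confidence)`` --
    where label is a class label or ``"excluded"`` for HER2-equivocal
    cases -- and the label distribution (excluded counted separately).
    The distribution always sums to the cohort size.
    """
    assignments: list[tuple[str, str, float]] = []
    distribution: Counter = Counter()
    for profile in cohort:
        status = resolve_her2(profile, her2_mode)
        if status == "excluded":
            assignments.append((profile.patient_id, "excluded", float("nan")))
            distribution["excluded"] += 1
            continue
        bclass, confidence = classify(
            profile, cutoffs, rulebase, her2_status=status
        )
        assignments.append((profile.patient_id, bclass.value, confidence))
        distribution[bclass.value] += 1
    unclassified = distribution.get(BiologicalClass.UNCLASSIFIED.value, 0)
    n = max(len(cohort), 1)
    logger.info(
        "classified %d tumours: %.1f%% unclassified, %d HER2-excluded",
        len(cohort), 100.0 * unclassified / n, distribution.get("excluded", 0),
    )
    return assignments, distribution


def default_rulebase(
    *, activation_threshold: float = 0.5, membership_width: float = 20.0
) -> RuleBase:
    """The shipped default rules -- an editable approximation.

    Luminal classes require CK7/8 high, ER high and HER2 negative, split by
    the PgR/HER3/HER4 pattern (A: PgR high; N: PgR low with HER3 and HER4
    low; B: PgR low with HER3 or HER4 high).  Basal classes require CK5/6
    or EGFR high with ER low and HER2 negative, split by p53 (altered: p53
    high).  HER2+ classes require HER2 positivity, split by ER; the ER-
    negative rule also requires PgR low, which breaks the otherwise exact
    activation tie for tumours whose ER value sits at its cut-off and is
    biologically safe (ER-negative tumours are PgR-negative).
    """
    C = BiologicalClass
    rules = (
        FuzzyRule(C.LUMINAL_A, (("CK7/8", "high"), ("ER", "high"),
                                ("HER2", "low"), ("PgR", "high"))),
        FuzzyRule(C.LUMINAL_N, (("CK7/8", "high"), ("ER", "high"), ("HER2", "low"),
                                ("PgR", "low"), ("HER3", "low"), ("HER4", "low"))),
        FuzzyRule(C.LUMINAL_B, (("CK7/8", "high"), ("ER", "high"), ("HER2", "low"),
                                ("PgR", "low"), ("HER3", "high"))),
        FuzzyRule(C.LUMINAL_B, (("CK7/8", "high"), ("ER", "high"), ("HER2", "low"),
                                ("PgR", "low"), ("HER4", "high"))),
        FuzzyRule(C.BASAL_P53_ALTERED, (("CK5/6", "high"), ("ER", "low"),
                                        ("HER2", "low"), ("p53", "high"))),
        FuzzyRule(C.BASAL_P53_ALTERED, (("EGFR", "high"), ("ER", "low"),
                                        ("HER2", "low"), ("p53", "high"))),
        FuzzyRule(C.BASAL_P53_NORMAL, (("CK5/6", "high"), ("ER", "low"),
                                       ("HER2", "low"), ("p53", "low"))),
        FuzzyRule(C.BASAL_P53_NORMAL, (("EGFR", "high"), ("ER", "low"),
                                       ("HER2", "low"), ("p53", "low"))),
        FuzzyRule(C.HER2_ER_POS, (("HER2", "high"), ("ER", "high"))),
        FuzzyRule(C.HER2_ER_NEG, (("HER2", "high"), ("ER", "low"), ("PgR", "low"))),
    )
    return RuleBase(
        rules=rules,
        activation_threshold=activation_threshold,
        membership_width=membership_width,
    )


def rulebase_to_yaml(rulebase: RuleBase) -> str:
    """Lossless structured-text form of a rule base."""
    doc = {
        "activation_threshold": float(rulebase.activation_threshold),
        "membership_width": float(rulebase.membership_width),
        "marker_widths": {k: float(v) for k, v in sorted(rulebase.marker_widths.items())},
        "rules": [
            {
                "class": r.consequent.value,
                "if": [f"{marker}:{side}" for marker, side in r.antecedents],
                "weight": float(r.weight),
            }
            for r in rulebase.rules
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def rulebase_from_yaml(text: str) -> RuleBase:
    doc = yaml.safe_load(text)
    rules = []
    for r in doc["rules"]:
        antecedents = []
        for clause in r["if"]:
            marker, _, side = clause.rpartition(":")
            antecedents.append((marker, side))
        rules.append(
            FuzzyRule(
                BiologicalClass.from_label(r["class"]),
                tuple(antecedents),
                float(r.get("weight", 1.0)),
            )
        )
    return RuleBase(
        rules=tuple(rules),
        activation_threshold=float(doc.get("activation_threshold", 0.5)),
        membership_width=float(doc.get("membership_width", 20.0)),
        marker_widths={k: float(v) for k, v in (doc.get("marker_widths") or {}).items()},
    )
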