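"""Class-specific NPI+ prognostic indices and prognostic groups.

Each biological class has its own NPI-like linear index over
clinicopathological variables, with coefficients taken from Cox regression
of breast-cancer-specific survival within that class:

    Luminal A          0.8*Mitosis + 0.5*Size + 1.8*NodalRatio
    Luminal N          0.8*Tubules + 0.6*Stage
    Luminal B          0.7*Mitosis + 1.0*NodalRatio
    Basal p53 altered  1.4*NodalRatio + 0.4*Size
    Basal p53 normal   0.6*Stage + 1.8*Pleomorphism
    HER2+/ER+          0.5*Size + 0.9*Stage
    HER2+/ER-          0.9*Stage - 0.6*NodalRatio

Grade components (tubules, pleomorphism, mitosis) are 1-3 scores, stage is
the 1-3 lymph-node stage, size is the binary category (1: <1.5 cm, 2:
>=1.5 cm; continuous cm coding available behind a switch) and nodal ratio
is positive/total nodes.  The index is cut at per-class cutpoints into
prognostic groups ("1.1" ... "7.2"); a boundary value belongs to the
higher (worse) group.  The original cutpoints are unpublished -- the
shipped defaults are placeholders calibrated on the default synthetic
cohort, and derive_cutpoints() can re-derive them from data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fuzzy import CLASS_ORDER, BiologicalClass
from .survival import cox_fit, logrank_test

__all__ = [
    "ClinPath",
    "IndexFormula",
    "PrognosticGroup",
    "CANDIDATE_VARIABLES",
    "nodal_ratio",
    "compute_index",
    "assign_group",
    "default_formulae",
    "formulae_to_config",
    "formulae_from_config",
    "derive_formula",
    "derive_cutpoints",
]

#: Variables eligible for index formulae, with their ClinPath accessors.
CANDIDATE_VARIABLES = (
    "nodes_positive",
    "nodal_ratio",
    "size",
    "stage",
    "tubules",
    "pleomorphism",
    "mitosis",
)


def nodal_ratio(nodes_positive: int, nodes_total: int) -> float:
    """Number of positive nodes over total nodes examined, in [0, 1]."""
    if nodes_total < 1:
        raise ValueError("at least one node must have been examined")
    if not (0 <= nodes_positive <= nodes_total):
        raise ValueError(
            f"nodes_positive={nodes_positive} outside [0, nodes_total={nodes_total}]"
        )
    return nodes_positive / nodes_total


@dataclass(frozen=True)
class ClinPath:
    """Clinicopathological variables of one tumour.

    ``grade`` follows the component-sum convention (sum 3-5 -> 1, 6-7 ->
    2, 8-9 -> 3); ``size_cat`` dichotomises pathological size at 1.5 cm.
    """

    tubules: int
    pleomorphism: int
    mitosis: int
    size_cm: float
    stage: int
    nodes_positive: int
    nodes_total: int

    def __post_init__(self) -> None:
        for name in ("tubules", "pleomorphism", "mitosis", "stage"):
            v = getattr(self, name)
            if v not in (1, 2, 3):
                raise ValueError(f"{name} must be a 1-3 score, got {v!r}")
        if not (self.size_cm > 0 and math.isfinite(self.size_cm)):
            raise ValueError(f"size_cm must be positive, got {self.size_cm!r}")
        nodal_ratio(self.nodes_positive, self.nodes_total)  # validates counts

    @property
    def size_cat(self) -> int:
        return 1 if self.size_cm < 1.5 else 2

    @property
    def grade(self) -> int:
        total = self.tubules + self.pleomorphism + self.mitosis
        if total <= 5:
            return 1
        return 2 if total <= 7 else 3

    @property
    def nodal_ratio(self) -> float:
        return nodal_ratio(self.nodes_positive, self.nodes_total)

    def variable(self, name: str, *, size_coding: str = "category") -> float:
        """Value of a formula variable under the requested size coding."""
        if name == "size":
            if size_coding == "category":
                return float(self.size_cat)
            if size_coding == "continuous":
                return float(self.size_cm)
            raise ValueError(f"unknown size coding {size_coding!r}")
        if name in CANDIDATE_VARIABLES:
            return float(getattr(self, name))
        raise ValueError(f"unknown index variable {name!r}")


@dataclass(frozen=True)
class IndexFormula:
    """Weighted linear index for one biological class, with group cutpoints."""

    biological_class: BiologicalClass
    terms: tuple[tuple[str, float], ...]
    cutpoints: tuple[float, ...]
    group_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.biological_class is BiologicalClass.UNCLASSIFIED:
            raise ValueError("Unclassified has no index formula")
        for name, _ in self.terms:
            if name not in CANDIDATE_VARIABLES:
                raise ValueError(f"unknown formula variable {name!r}")
        if list(self.cutpoints) != sorted(set(self.cutpoints)):
            raise ValueError("cutpoints must be strictly ascending")
        if len(self.group_labels) != len(self.cutpoints) + 1:
            raise ValueError("need exactly len(cutpoints)+1 group labels")


@dataclass(frozen=True)
class PrognosticGroup:
    """A within-class risk stratum, labelled like "1.1"."""

    label: str
    biological_class: BiologicalClass


# Coefficients as published; cutpoints are placeholders (not from the
# source study, whose cutpoints are unpublished) calibrated once so that
# group proportions on the default synthetic cohort are sensible.
_DEFAULT_SPEC: dict[BiologicalClass, tuple[tuple[tuple[str, float], ...], tuple[float, ...]]] = {
    BiologicalClass.LUMINAL_A: ((("mitosis", 0.8), ("size", 0.5), ("nodal_ratio", 1.8)), (2.2, 3.4)),
    BiologicalClass.LUMINAL_N: ((("tubules", 0.8), ("stage", 0.6)), (3.5,)),
    BiologicalClass.LUMINAL_B: ((("mitosis", 0.7), ("nodal_ratio", 1.0)), (1.45,)),
    BiologicalClass.BASAL_P53_ALTERED: ((("nodal_ratio", 1.4), ("size", 0.4)), (1.3,)),
    BiologicalClass.BASAL_P53_NORMAL: ((("stage", 0.6), ("pleomorphism", 1.8)), (6.1,)),
    BiologicalClass.HER2_ER_POS: ((("size", 0.5), ("stage", 0.9)), (2.5,)),
    BiologicalClass.HER2_ER_NEG: ((("stage", 0.9), ("nodal_ratio", -0.6)), (2.0,)),
}


def default_formulae() -> dict[BiologicalClass, IndexFormula]:
    """The shipped per-class index formulae (Luminal A: 3 groups, others: 2)."""
    out: dict[BiologicalClass, IndexFormula] = {}
    for bclass in CLASS_ORDER:
        terms, cutpoints = _DEFAULT_SPEC[bclass]
        labels = tuple(
            f"{bclass.index}.{k}" for k in range(1, len(cutpoints) + 2)
        )
        out[bclass] = IndexFormula(bclass, terms, cutpoints, labels)
    return out


def compute_index(
    bclass: BiologicalClass,
    cp: ClinPath,
    formulae: Mapping[BiologicalClass, IndexFormula] | None = None,
    *,
    size_coding: str = "category",
) -> float:
    """Evaluate the class-specific prognostic index for one tumour."""
    if bclass is BiologicalClass.UNCLASSIFIED:
        raise ValueError("no prognostic index is defined for Unclassified tumours")
    formulae = formulae if formulae is not None else default_formulae()
    formula = formulae[bclass]
    return float(
        sum(coef * cp.variable(name, size_coding=size_coding) for name, coef in formula.terms)
    )


def assign_group(
    bclass: BiologicalClass,
    index_value: float,
    formula: IndexFormula | None = None,
) -> PrognosticGroup:
    """Map an index value to its prognostic group.

    The cutpoints partition the real line into half-open intervals; an
    index exactly at a cutpoint falls in the higher (worse) group.
    """
    if formula is None:
        formula = default_formulae()[bclass]
    if formula.biological_class is not bclass:
        raise ValueError("formula does not belong to this biological class")
    if not formula.cutpoints:
        raise ValueError(
            f"no cutpoints configured for {bclass.value}; configure them or "
            "run derive_cutpoints"
        )
    k = int(np.searchsorted(np.asarray(formula.cutpoints), index_value, side="right"))
    return PrognosticGroup(formula.group_labels[k], bclass)


def formulae_to_config(formulae: Mapping[BiologicalClass, IndexFormula]) -> list[dict]:
    return [
        {
            "class": f.biological_class.value,
            "terms": [f"{name}*{coef:g}" for name, coef in f.terms],
            "cutpoints": [float(c) for c in f.cutpoints],
            "group_labels": list(f.group_labels),
        }
        for f in (formulae[c] for c in CLASS_ORDER if c in formulae)
    ]


def formulae_from_config(records: Sequence[Mapping]) -> dict[BiologicalClass, IndexFormula]:
    out: dict[BiologicalClass, IndexFormula] = {}
    for r in records:
        bclass = BiologicalClass.from_label(r["class"])
        terms = []
        for entry in r["terms"]:
            name, _, coef = entry.partition("*")
            terms.append((name, float(coef)))
        out[bclass] = IndexFormula(
            bclass,
            tuple(terms),
            tuple(float(c) for c in r["cutpoints"]),
            tuple(r["group_labels"]),
        )
    return out


@dataclass
class DerivedFormula:
    """Result of a data-driven formula derivation."""

    terms: tuple[tuple[str, float], ...]
    raw_betas: pd.Series
    p_values: pd.Series
    retained: tuple[str, ...]


def derive_formula(
    clinpath: Sequence[ClinPath],
    durations: Sequence[float],
    events: Sequence[int],
    candidates: Sequence[str] = CANDIDATE_VARIABLES,
    *,
    alpha: float = 0.05,
    min_events: int = 10,
    size_coding: str = "category",
) -> DerivedFormula:
    """Re-derive an index formula from a class subset with survival.

    Fits a Cox proportional-hazards model of BCSS on the candidate
    variables, retains those significant at ``alpha`` (per-variable Wald),
    refits on the retained set, and reports coefficients rounded to one
    decimal (the precision of the published formulae) alongside the raw
    betas.
    """
    for name in candidates:
        if name not in CANDIDATE_VARIABLES:
            raise ValueError(f"unknown candidate variable {name!r}")
    design = pd.DataFrame(
        {name: [cp.variable(name, size_coding=size_coding) for cp in clinpath]
         for name in candidates}
    )
    result = cox_fit(design, durations, events, min_events=min_events)
    retained = tuple(name for name in candidates if result.p_values[name] < alpha)
    if not retained:
        raise ValueError(
            f"no candidate variable significant at alpha={alpha}; "
            f"smallest p={result.p_values.min():.3g}"
        )
    if set(retained) != set(candidates):
        refit = cox_fit(design[list(retained)], durations, events, min_events=min_events)
    else:
        refit = result
    terms = tuple((name, round(float(refit.betas[name]), 1)) for name in retained)
    return DerivedFormula(
        terms=terms,
        raw_betas=refit.betas,
        p_values=result.p_values,
        retained=retained,
    )


def derive_cutpoints(
    index_values: Sequence[float],
    durations: Sequence[float],
    events: Sequence[int],
    n_groups: int = 2,
    *,
    min_group_fraction: float = 0.1,
    max_candidates: int = 40,
) -> tuple[float, ...]:
    """Data-driven group cutpoints maximising outcome separation.

    Candidate cutpoints are midpoints between adjacent distinct index
    values (thinned to ``max_candidates`` quantile-spaced points for large
    inputs).  Every admissible combination of ``n_groups - 1`` candidates
    keeping each group above ``min_group_fraction`` of the sample is
    scored by the log-rank statistic between the resulting groups; the
    best combination wins, with exact score ties resolved toward the
    median candidate combination (deterministic).
    """
    index_values = np.asarray(index_values, dtype=float)
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    if n_groups < 2:
        raise ValueError("need at least two groups")
    distinct = np.unique(index_values)
    if distinct.size < n_groups:
        raise ValueError(
            f"only {distinct.size} distinct index values for {n_groups} groups"
        )
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    # thin the candidate grid only when the combination budget demands it
    n_combos = math.comb(mids.size, n_groups - 1)
    if n_combos > 5000 and mids.size > max_candidates:
        q = np.linspace(0, 1, max_candidates + 2)[1:-1]
        mids = np.unique(np.quantile(mids, q))
    n = index_values.size
    best_stat = -np.inf
    best: list[tuple[float, ...]] = []
    for combo in combinations(mids, n_groups - 1):
        cuts = np.asarray(combo)
        labels = np.searchsorted(cuts, index_values, side="right")
        counts = np.bincount(labels, minlength=n_groups)
        if counts.min() < max(1, math.ceil(min_group_fraction * n)):
            continue
        groups = [
            (durations[labels == g], events[labels == g]) for g in range(n_groups)
        ]
        if events.sum() == 0:
            stat = 0.0
        else:
            stat, _, _ = logrank_test(groups)
        if stat > best_stat + 1e-12:
            best_stat = stat
            best = [tuple(combo)]
        elif abs(stat - best_stat) <= 1e-12:
            best.append(tuple(combo))
    if not best:
        raise ValueError(
            "no admissible cutpoint combination satisfies the minimum group size"
        )
    return best[len(best) // 2]
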