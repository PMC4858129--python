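"""Semi-quantitative immunohistochemistry (IHC) scoring for the NPI+ panel.

The NPI+ biological classification rests on ten biomarkers scored with the
modified Histochemical score (H-score): for each tumour the percentage of
cells staining at each intensity (0-3) is recorded and the H-score is the
intensity-weighted sum, giving a value between 0 and 300.

Each marker is dichotomised at a cut-off before (fuzzy) classification.  Six
markers (ER, PgR, CK7/8, HER3, HER4, MUC1) use the cohort median as the
cut-off; the remaining four (CK5/6, EGFR, p53, HER2) use expert-chosen
values.  HER2 positivity is not determined from an H-score at all but from
the clinical IHC category (0/1+/2+/3+), with equivocal 2+ cases either
excluded or resolved by in-situ hybridisation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MARKERS",
    "MEDIAN_POLICY_MARKERS",
    "EXPERT_POLICY_MARKERS",
    "DEFAULT_EXPERT_CUTOFFS",
    "HScore",
    "MarkerProfile",
    "Cutoff",
    "CutoffTable",
    "DegenerateDistributionWarning",
    "compute_hscore",
    "compute_median_cutoffs",
    "build_cutoff_table",
    "resolve_her2",
    "dichotomize",
]

#: The ten NPI+ panel markers, in canonical order.
MARKERS: tuple[str, ...] = (
    "ER", "PgR", "CK5/6", "CK7/8", "EGFR", "HER2", "HER3", "HER4", "p53", "MUC1",
)

#: Markers dichotomised at the cohort median under the default policy.
MEDIAN_POLICY_MARKERS: frozenset[str] = frozenset(
    {"ER", "PgR", "CK7/8", "HER3", "HER4", "MUC1"}
)

#: Markers dichotomised at expert-chosen cut-offs under the default policy.
EXPERT_POLICY_MARKERS: frozenset[str] = frozenset({"CK5/6", "EGFR", "p53", "HER2"})

# Defaults, not from the source study (which does not publish its expert
# values): CK5/6 and EGFR call any convincing staining positive, p53
# "altered" requires accumulation beyond weak physiological staining.  The
# HER2 entry is a nominal placeholder -- HER2 status comes from the IHC
# category via resolve_her2(), never from an H-score.
DEFAULT_EXPERT_CUTOFFS: dict[str, float] = {
    "CK5/6": 10.0,
    "EGFR": 10.0,
    "p53": 20.0,
    "HER2": 10.0,
}

#: Expert fallback applied when a median-policy marker has cohort median 0
#: (a median of zero cannot separate negative from positive tumours).
ZERO_MEDIAN_FALLBACK: float = 20.0

HER2_IHC_CATEGORIES = ("0", "1+", "2+", "3+", "unknown")
HER2_ISH_VALUES = ("amplified", "not_amplified", "not_done")


class DegenerateDistributionWarning(UserWarning):
    """A marker's cohort distribution is degenerate (constant or median 0)."""


@dataclass(frozen=True)
class HScore:
    """A single marker H-score, dimensionless, in [0, 300]."""

    marker: str
    value: float

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}; expected one of {MARKERS}")
        if not (0.0 <= self.value <= 300.0) or not math.isfinite(self.value):
            raise ValueError(f"H-score for {self.marker} out of [0, 300]: {self.value}")


@dataclass
class MarkerProfile:
    """The ten-marker IHC readout of one tumour.

    Missing H-scores are simply absent from ``hscores`` (or stored as NaN,
    which is normalised to absent).  ``her2_ihc`` is the clinical IHC
    category; ``her2_ish`` the in-situ hybridisation result used to resolve
    equivocal (2+) cases when available.
    """

    patient_id: str
    hscores: dict[str, float] = field(default_factory=dict)
    her2_ihc: str = "unknown"
    her2_ish: str | None = None

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for marker, value in self.hscores.items():
            if value is None or (isinstance(value, float) and math.isnan(value)):
                continue
            hs = HScore(marker, float(value))  # validates marker name and range
            clean[hs.marker] = hs.value
        self.hscores = clean
        if self.her2_ihc not in HER2_IHC_CATEGORIES:
            raise ValueError(
                f"patient {self.patient_id}: HER2 IHC category {self.her2_ihc!r} "
                f"not in {HER2_IHC_CATEGORIES}"
            )
        if self.her2_ish is not None and self.her2_ish not in HER2_ISH_VALUES:
            raise ValueError(
                f"patient {self.patient_id}: HER2 ISH value {self.her2_ish!r} "
                f"not in {HER2_ISH_VALUES}"
            )

    def value(self, marker: str) -> float | None:
        """H-score for *marker*, or None if missing."""
        return self.hscores.get(marker)

    @property
    def missing_markers(self) -> tuple[str, ...]:
        return tuple(m for m in MARKERS if m != "HER2" and m not in self.hscores)


@dataclass(frozen=True)
class Cutoff:
    marker: str
    cutoff: float
    policy: str  # "cohort_median" | "expert"

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}")
        if not (0.0 <= self.cutoff <= 300.0):
            raise ValueError(f"cutoff for {self.marker} out of [0, 300]: {self.cutoff}")
        if self.policy not in ("cohort_median", "expert"):
            raise ValueError(f"unknown cutoff policy {self.policy!r}")


@dataclass
class CutoffTable:
    """Per-marker dichotomisation cut-offs with their provenance policy."""

    cutoffs: dict[str, Cutoff]

    def __getitem__(self, marker: str) -> Cutoff:
        return self.cutoffs[marker]

    def __contains__(self, marker: str) -> bool:
        return marker in self.cutoffs

    def value(self, marker: str) -> float:
        return self.cutoffs[marker].cutoff

    @property
    def is_complete(self) -> bool:
        return all(m in self.cutoffs for m in MARKERS)

    def to_config(self) -> list[dict]:
        """Serialisable form (list of marker/cutoff/policy records)."""
        return [
            {"marker": c.marker, "cutoff": float(c.cutoff), "policy": c.policy}
            for c in (self.cutoffs[m] for m in MARKERS if m in self.cutoffs)
        ]

    @classmethod
    def from_config(cls, records: Iterable[Mapping]) -> "CutoffTable":
        cutoffs = {
            r["marker"]: Cutoff(r["marker"], float(r["cutoff"]), r["policy"])
            for r in records
        }
        return cls(cutoffs)


def compute_hscore(
    intensity_fractions: Mapping[int, float], *, percent_tolerance: float = 0.5
) -> float:
    """H-score from the percentage of cells at each staining intensity.

    Parameters
    ----------
    intensity_fractions
        Mapping of staining intensity (0-3) to percent of cells (0-100).
        Omitted intensities count as 0%.
    percent_tolerance
        Absolute slack allowed on the percentages summing to 100, to
        tolerate rounded per-intensity readings.
    """
    percents = {0: 0.0, 1: 0.0, 2: 0.0, 3: 0.0}
    for intensity, percent in intensity_fractions.items():
        if intensity not in percents:
            raise ValueError(f"staining intensity must be 0-3, got {intensity!r}")
        p = float(percent)
        if p < 0.0:
            raise ValueError(f"negative percentage for intensity {intensity}: {p}")
        percents[intensity] = p
    total = sum(percents.values())
    if abs(total - 100.0) > percent_tolerance:
        raise ValueError(
            f"intensity percentages sum to {total:g}, not 100 "
            f"(tolerance ±{percent_tolerance:g})"
        )
    score = sum(i * p for i, p in percents.items())
    return float(min(score, 300.0))


def compute_median_cutoffs(
    cohort: Sequence[MarkerProfile],
    markers: Iterable[str] = MEDIAN_POLICY_MARKERS,
) -> CutoffTable:
    """Cohort-median cut-offs for the requested markers.

    The cut-off for each marker is the sample median of its non-missing
    H-scores.  A marker whose values are all missing raises; a constant
    marker or one with median 0 triggers a DegenerateDistributionWarning
    (a zero median cannot separate negatives from positives -- callers
    should substitute an expert value, as build_cutoff_table does).
    """
    out: dict[str, Cutoff] = {}
    for marker in markers:
        if marker not in MARKERS:
            raise ValueError(f"unknown marker {marker!r}")
        values = np.array(
            [p.value(marker) for p in cohort if p.value(marker) is not None], dtype=float
        )
        if values.size == 0:
            raise ValueError(f"marker {marker}: no non-missing values in cohort")
        med = float(np.median(values))
        if values.size > 1 and np.ptp(values) == 0.0:
            warnings.warn(
                f"marker {marker}: constant cohort distribution (all {med:g})",
                DegenerateDistributionWarning,
                stacklevel=2,
            )
        if med == 0.0:
            warnings.warn(
                f"marker {marker}: cohort median is 0; an expert cut-off should "
                "be substituted",
                DegenerateDistributionWarning,
                stacklevel=2,
            )
        out[marker] = Cutoff(marker, med, "cohort_median")
    return CutoffTable(out)


def build_cutoff_table(
    cohort: Sequence[MarkerProfile],
    *,
    expert_cutoffs: Mapping[str, float] | None = None,
    zero_median_fallback: float = ZERO_MEDIAN_FALLBACK,
) -> CutoffTable:
    """Full ten-marker cut-off table under the default policy.

    Median-policy markers get the cohort median; a median of exactly 0 is
    replaced by ``zero_median_fallback`` (tagged expert).  Expert-policy
    markers take the supplied (or default) expert values.
    """
    expert = dict(DEFAULT_EXPERT_CUTOFFS)
    if expert_cutoffs:
        expert.update(expert_cutoffs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateDistributionWarning)
        table = compute_median_cutoffs(cohort, MEDIAN_POLICY_MARKERS)
    cutoffs = dict(table.cutoffs)
    for marker, cut in list(cutoffs.items()):
        if cut.cutoff == 0.0:
            cutoffs[marker] = Cutoff(marker, float(zero_median_fallback), "expert")
    for marker in EXPERT_POLICY_MARKERS:
        cutoffs[marker] = Cutoff(marker, float(expert[marker]), "expert")
    return CutoffTable(cutoffs)


def resolve_her2(
    profile: MarkerProfile, mode: str = "exclude_equivocal"
) -> str:
    """Resolve HER2 status from the IHC category.

    3+ is positive and 0/1+ negative in either mode.  Equivocal 2+ cases
    are excluded under ``exclude_equivocal``; under ``ish_resolve`` they
    are positive iff in-situ hybridisation shows amplification, and
    excluded when ISH was not done.
    """
    if mode not in ("exclude_equivocal", "ish_resolve"):
        raise ValueError(f"unknown HER2 resolution mode {mode!r}")
    cat = profile.her2_ihc
    if cat == "unknown":
        raise ValueError(f"patient {profile.patient_id}: HER2 IHC category is unknown")
    if cat == "3+":
        return "positive"
    if cat in ("0", "1+"):
        return "negative"
    # equivocal 2+
    if mode == "exclude_equivocal":
        return "excluded"
    ish = profile.her2_ish or "not_done"
    if ish == "not_done":
        return "excluded"
    return "positive" if ish == "amplified" else "negative"


def dichotomize(
    profile: MarkerProfile,
    cutoffs: CutoffTable,
    *,
    inclusive: bool = True,
) -> dict[str, str | None]:
    """Crisp low/high call per marker (HER2 excluded; see resolve_her2).

    A value equal to the cut-off counts as high when ``inclusive`` (the
    default boundary convention, ties toward positivity).  Missing markers
    map to None.
    """
    out: dict[str, str | None] = {}
    for marker in MARKERS:
        if marker == "HER2":
            continue
        value = profile.value(marker)
        if value is None:
            out[marker] = None
            continue
        if marker not in cutoffs:
            raise KeyError(f"no cutoff configured for non-missing marker {marker}")
        c = cutoffs.value(marker)
        high = value >= c if inclusive else value > c
        out[marker] = "high" if high else "low"
    return out
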