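"""End-to-end NPI+ validation workflow on a cohort file.

``run_validation`` executes the full two-tier evaluation -- HER2
resolution, cut-off determination, fuzzy biological classification,
class-specific index and prognostic-group assignment, Kaplan-Meier /
log-rank survival comparison per class and per group, and class-by-
clinicopathology association tables -- and emits the report artefacts as
plain CSV/JSON files.  Every patient is accounted for exactly once across
{classified, unclassified, HER2-excluded}, and a rerun with identical
inputs produces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import AssociationResult, ContingencyTable, associate
from .fuzzy import (
    CLASS_ORDER,
    BiologicalClass,
    RuleBase,
    classify,
    default_rulebase,
    rulebase_from_yaml,
)
from .ihc import CutoffTable, MarkerProfile, build_cutoff_table, resolve_her2
from .prognostic import ClinPath, IndexFormula, assign_group, compute_index, default_formulae, formulae_from_config
from .survival import KMCurve, SurvivalRecord, bonferroni_adjust, encode_records, km_estimate, logrank_test
from .synthetic import MARKER_COLUMNS

__all__ = [
    "RunConfig",
    "ValidationReport",
    "read_cohort",
    "run_validation",
    "write_report",
]

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = (
    "patient_id", "er_h", "pgr_h", "ck56_h", "ck78_h", "egfr_h",
    "her2_ihc", "her3_h", "her4_h", "p53_h", "muc1_h",
)
CLINPATH_COLUMNS = (
    "tubules", "pleomorphism", "mitosis", "size_cm", "stage",
    "nodes_positive", "nodes_total",
)
SURVIVAL_COLUMNS = ("time_years", "event")
KNOWN_COLUMNS = MANDATORY_COLUMNS + ("her2_ish",) + CLINPATH_COLUMNS + SURVIVAL_COLUMNS

_NUMERIC_COLUMNS = (
    "er_h", "pgr_h", "ck56_h", "ck78_h", "egfr_h", "her3_h", "her4_h",
    "p53_h", "muc1_h", "size_cm", "time_years",
)
_INT_COLUMNS = ("tubules", "pleomorphism", "mitosis", "stage", "nodes_positive", "nodes_total")


@dataclass
class RunConfig:
    """Paths and switches of one validation run."""

    cohort_path: str | Path
    out_dir: str | Path
    rulebase: RuleBase = field(default_factory=default_rulebase)
    formulae: dict[BiologicalClass, IndexFormula] = field(default_factory=default_formulae)
    expert_cutoffs: dict[str, float] | None = None
    her2_mode: str = "exclude_equivocal"
    alpha: float = 0.01
    bonferroni: bool = True
    km_horizon_years: float = 10.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        kwargs: dict = {
            "cohort_path": doc["cohort_path"],
            "out_dir": doc.get("out_dir", "npiplus_report"),
        }
        if "rulebase" in doc:
            kwargs["rulebase"] = rulebase_from_yaml(yaml.safe_dump(doc["rulebase"]))
        if "formulae" in doc:
            kwargs["formulae"] = formulae_from_config(doc["formulae"])
        for key in ("expert_cutoffs", "her2_mode", "alpha", "bonferroni",
                    "km_horizon_years", "seed"):
            if key in doc:
                kwargs[key] = doc[key]
        return cls(**kwargs)


@dataclass
class ValidationReport:
    """All artefacts of one validation run."""

    class_distribution: pd.DataFrame
    associations: pd.DataFrame
    group_distribution: pd.DataFrame
    km_curves: pd.DataFrame
    logrank: pd.DataFrame
    assignments: pd.DataFrame
    excluded: pd.DataFrame
    meta: dict

    def reconcile(self, n_input: int) -> None:
        """Assert the patient-conservation invariant."""
        n = len(self.assignments) + len(self.excluded)
        if n != n_input:
            raise AssertionError(
                f"patient conservation violated: {n} accounted for, {n_input} read"
            )


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Strict numeric parsing (a decimal comma is an error naming the cell),
    BOM/CRLF tolerated, empty cells preserved as missing, unknown columns
    kept with a warning.
    """
    df = pd.read_csv(path, dtype=str, encoding="utf-8-sig", skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path}: missing mandatory columns {missing}")
    unknown = [c for c in df.columns if c not in KNOWN_COLUMNS]
    if unknown:
        warnings.warn(f"cohort file {path}: unknown columns {unknown} ignored")
    problems = []
    for col in _NUMERIC_COLUMNS + _INT_COLUMNS:
        if col not in df.columns:
            continue
        raw = df[col]
        converted = pd.to_numeric(raw, errors="coerce")
        bad = raw.notna() & (raw.str.strip() != "") & converted.isna()
        for idx in df.index[bad][:5]:
            problems.append(f"row {idx + 2}, column {col}: cannot parse {raw[idx]!r}")
        df[col] = converted
    if problems:
        raise ValueError("cohort parse errors: " + "; ".join(problems))
    for col in _INT_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    return df


def _profiles(df: pd.DataFrame) -> list[MarkerProfile]:
    profiles = []
    for _, row in df.iterrows():
        hscores = {}
        for marker, col in MARKER_COLUMNS.items():
            v = row.get(col)
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                hscores[marker] = float(v)
        ish = row.get("her2_ish")
        if isinstance(ish, str):
            ish = ish.strip() or None
        elif ish is not None and (not isinstance(ish, str)) and pd.isna(ish):
            ish = None
        profiles.append(
            MarkerProfile(
                patient_id=str(row["patient_id"]),
                hscores=hscores,
                her2_ihc=str(row["her2_ihc"]).strip(),
                her2_ish=ish,
            )
        )
    return profiles


def _clinpath(row: pd.Series) -> ClinPath | None:
    try:
        return ClinPath(
            tubules=int(row["tubules"]), pleomorphism=int(row["pleomorphism"]),
            mitosis=int(row["mitosis"]), size_cm=float(row["size_cm"]),
            stage=int(row["stage"]), nodes_positive=int(row["nodes_positive"]),
            nodes_total=int(row["nodes_total"]),
        )
    except (KeyError, TypeError, ValueError):
        return None


def _survival(row: pd.Series) -> SurvivalRecord | None:
    try:
        t = float(row["time_years"])
        e = str(row["event"]).strip()
        return SurvivalRecord(time=t, event=e)
    except (KeyError, TypeError, ValueError):
        return None


def _km_frame(groups: dict[str, tuple[np.ndarray, np.ndarray]]) -> pd.DataFrame:
    frames = []
    for name, (t, e) in groups.items():
        if len(t) == 0:
            continue
        curve = km_estimate(t, e)
        frames.append(curve.to_frame(group=name))
    if not frames:
        return pd.DataFrame(columns=["group", "time", "survival", "at_risk", "events"])
    return pd.concat(frames, ignore_index=True)


def _logrank_frame(
    grouped: dict[str, tuple[np.ndarray, np.ndarray]],
    comparison: str,
    alpha: float,
    bonferroni_m: int,
) -> dict | None:
    usable = {k: v for k, v in grouped.items() if len(v[0]) > 0}
    if len(usable) < 2:
        return None
    total_events = sum(int(np.sum(e)) for _, e in usable.values())
    if total_events == 0:
        return None
    stat, dof, p = logrank_test(list(usable.values()))
    return {
        "comparison": comparison,
        "groups": ";".join(usable),
        "statistic": stat,
        "dof": dof,
        "p": p,
        "n_groups": len(usable),
        "bonferroni_m": bonferroni_m,
    }


def run_validation(config: RunConfig) -> ValidationReport:
    """Execute the full NPI+ workflow on a cohort file."""
    df = read_cohort(config.cohort_path)
    n_input = len(df)
    logger.info("stage read_cohort: %d patients in", n_input)

    profiles = _profiles(df)
    statuses = [resolve_her2(p, config.her2_mode) for p in profiles]
    excluded_ids = [p.patient_id for p, s in zip(profiles, statuses) if s == "excluded"]
    logger.info(
        "stage resolve_her2: %d in -> %d kept, %d HER2-equivocal excluded",
        n_input, n_input - len(excluded_ids), len(excluded_ids),
    )

    kept = [(p, s) for p, s in zip(profiles, statuses) if s != "excluded"]
    cutoffs: CutoffTable = build_cutoff_table(
        [p for p, _ in kept], expert_cutoffs=config.expert_cutoffs
    )
    logger.info("stage cutoffs: %s", {c.marker: c.cutoff for c in cutoffs.cutoffs.values()})

    records = []
    for (profile, status), (_, row) in zip(
        [(p, s) for p, s in zip(profiles, statuses)], df.iterrows()
    ):
        if status == "excluded":
            continue
        bclass, confidence = classify(
            profile, cutoffs, config.rulebase, her2_status=status
        )
        cp = _clinpath(row)
        surv = _survival(row)
        index_value: float | None = None
        group_label = ""
        if bclass is not BiologicalClass.UNCLASSIFIED and cp is not None:
            index_value = compute_index(bclass, cp, config.formulae)
            formula = config.formulae[bclass]
            if formula.cutpoints:
                group_label = assign_group(bclass, index_value, formula).label
        records.append({
            "patient_id": profile.patient_id,
            "biological_class": bclass.value,
            "confidence": round(float(confidence), 6),
            "prognostic_index": (
                round(index_value, 6) if index_value is not None else np.nan
            ),
            "prognostic_group": group_label,
            "grade": cp.grade if cp is not None else pd.NA,
            "size_cat": cp.size_cat if cp is not None else pd.NA,
            "stage": cp.stage if cp is not None else pd.NA,
            "time_years": surv.time if surv is not None else np.nan,
            "event": surv.event if surv is not None else "",
        })
    assignments = pd.DataFrame(records)
    excluded = pd.DataFrame({"patient_id": excluded_ids})
    n_classified = int((assignments["biological_class"] != BiologicalClass.UNCLASSIFIED.value).sum()) if len(assignments) else 0
    logger.info(
        "stage classify: %d named-class, %d unclassified",
        n_classified, len(assignments) - n_classified,
    )

    # class distribution (Unclassified and HER2-excluded reported separately)
    dist_rows = [
        {
            "biological_class": c.value,
            "n": int((assignments["biological_class"] == c.value).sum()) if len(assignments) else 0,
        }
        for c in BiologicalClass
    ]
    dist_rows.append({"biological_class": "HER2 equivocal (excluded)", "n": len(excluded)})
    class_distribution = pd.DataFrame(dist_rows)
    class_distribution["fraction"] = (
        class_distribution["n"] / n_input if n_input else 0.0
    ).round(6)

    # class x clinicopathology associations (named classes only)
    named = assignments[
        assignments["biological_class"] != BiologicalClass.UNCLASSIFIED.value
    ] if len(assignments) else assignments
    assoc_rows = []
    for variable in ("grade", "size_cat", "stage"):
        if not len(named):
            break
        sub = named.dropna(subset=[variable])
        if sub.empty:
            continue
        table = pd.crosstab(sub[variable], sub["biological_class"])
        if table.shape[0] < 2 or table.shape[1] < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result: AssociationResult = associate(ContingencyTable(table))
        assoc_rows.append({
            "variable": variable, "chi2": round(result.chi2, 6), "dof": result.dof,
            "p": result.p, "cramers_v": round(result.v, 6), "n": result.n,
        })
    associations = pd.DataFrame(
        assoc_rows, columns=["variable", "chi2", "dof", "p", "cramers_v", "n"]
    )

    # prognostic-group distribution
    grouped = named[named["prognostic_group"] != ""] if len(named) else named
    group_rows = []
    for bclass in CLASS_ORDER:
        formula = config.formulae.get(bclass)
        if formula is None:
            continue
        for label in formula.group_labels:
            n_g = int((grouped["prognostic_group"] == label).sum()) if len(grouped) else 0
            group_rows.append({
                "biological_class": bclass.value, "group": label, "n": n_g,
            })
    group_distribution = pd.DataFrame(group_rows)

    # KM curves and log-rank per class and per group
    def _surv_arrays(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        sub = frame.dropna(subset=["time_years"])
        sub = sub[sub["event"] != ""]
        recs = [SurvivalRecord(t, e) for t, e in zip(sub["time_years"], sub["event"])]
        return encode_records(recs)

    by_class = {
        c.value: _surv_arrays(named[named["biological_class"] == c.value])
        for c in CLASS_ORDER
    } if len(named) else {}
    by_group = {
        f"{row['biological_class']}|{row['group']}": _surv_arrays(
            grouped[grouped["prognostic_group"] == row["group"]]
        )
        for _, row in group_distribution.iterrows()
    } if len(group_distribution) else {}
    km_curves = pd.concat(
        [
            _km_frame({k: v for k, v in by_class.items() if len(v[0]) > 0}),
            _km_frame({k: v for k, v in by_group.items() if len(v[0]) > 0}),
        ],
        ignore_index=True,
    ) if (by_class or by_group) else _km_frame({})

    logrank_rows = []
    tests = []
    t = _logrank_frame(by_class, "between biological classes", config.alpha, 1)
    if t:
        tests.append(t)
    for bclass in CLASS_ORDER:
        formula = config.formulae.get(bclass)
        if formula is None or not len(group_distribution):
            continue
        class_groups = {
            label: by_group.get(f"{bclass.value}|{label}", (np.empty(0), np.empty(0)))
            for label in formula.group_labels
        }
        t = _logrank_frame(
            class_groups, f"between groups of {bclass.value}", config.alpha, 1
        )
        if t:
            tests.append(t)
        else:
            logger.warning(
                "log-rank skipped for %s: empty or event-free group(s)", bclass.value
            )
    if tests:
        m = len(tests)
        flags = bonferroni_adjust([x["p"] for x in tests], alpha=config.alpha) if config.bonferroni else [
            x["p"] < config.alpha for x in tests
        ]
        for x, flag in zip(tests, flags):
            x["bonferroni_m"] = m if config.bonferroni else 1
            x["significant"] = bool(flag)
            logrank_rows.append(x)
    logrank = pd.DataFrame(
        logrank_rows,
        columns=["comparison", "groups", "statistic", "dof", "p",
                 "n_groups", "bonferroni_m", "significant"],
    )

    meta = {
        "package": "npiplus",
        "version": __version__,
        "seed": config.seed,
        "her2_mode": config.her2_mode,
        "alpha": config.alpha,
        "bonferroni": config.bonferroni,
        "n_input": n_input,
        "n_classified": n_classified,
        "n_unclassified": int(len(assignments) - n_classified),
        "n_excluded": len(excluded),
        "cutoffs": cutoffs.to_config(),
        "cohort_sha256": hashlib.sha256(
            Path(config.cohort_path).read_bytes()
        ).hexdigest(),
    }

    report = ValidationReport(
        class_distribution=class_distribution,
        associations=associations,
        group_distribution=group_distribution,
        km_curves=km_curves,
        logrank=logrank,
        assignments=assignments,
        excluded=excluded,
        meta=meta,
    )
    report.reconcile(n_input)
    return report


def write_report(report: ValidationReport, out_dir: str | Path) -> list[Path]:
    """Write all report artefacts as CSV/JSON; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in (
        ("class_distribution", report.class_distribution),
        ("associations", report.associations),
        ("group_distribution", report.group_distribution),
        ("km_curves", report.km_curves),
        ("logrank", report.logrank),
        ("assignments", report.assignments),
        ("excluded", report.excluded),
    ):
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False, lineterminator="\n")
        written.append(path)
    meta_path = out / "run_meta.json"
    meta_path.write_text(json.dumps(report.meta, indent=2, sort_keys=True) + "\n",
                         encoding="utf-8")
    written.append(meta_path)
    logger.info("report written to %s (%d files)", out, len(written))
    return written
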