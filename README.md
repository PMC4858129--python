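# npiplus

The Nottingham Prognostic Index Plus (NPI+) is a two-tier clinical
decision-making tool for early-stage invasive breast cancer.  The classic
NPI combines tumour size, lymph-node stage and histological grade into one
score for every patient; NPI+ first assigns each tumour to one of seven
**biological classes** from a ten-biomarker immunohistochemistry panel
(ER, PgR, CK5/6, CK7/8, EGFR, HER2, HER3, HER4, p53, MUC1), and only then
applies a **class-specific** prognostic formula over clinicopathological
variables, so that the weighting of the classical prognostic factors can
differ between, say, a Luminal A and a HER2+/ER− tumour.

`npiplus` is a tested re-implementation of that pipeline for
biostatisticians and pathology researchers, exercisable end-to-end on
synthetic cohorts:

- **IHC scoring** — H-scores (Σ intensity × % cells, 0–300), cohort-median
  and expert dichotomisation cut-offs, ASCO/CAP-style HER2 resolution with
  exclusion or ISH resolution of equivocal 2+ cases.
- **Fuzzy classification** — a configurable Mamdani-style rule base
  (min-conjunction within rules, max across a class's rules, trapezoidal
  memberships around each cut-off) assigning Luminal A/N/B, Basal p53
  altered/normal, HER2+/ER+, HER2+/ER− or Unclassified.
- **Prognostic indices** — the published per-class formulae, e.g.
  Luminal A: `0.8·Mitosis + 0.5·Size + 1.8·NodalRatio`, HER2+/ER−:
  `0.9·Stage − 0.6·NodalRatio`, with cutpoints mapping the index to
  prognostic groups ("1.1" … "7.2"), plus Cox-regression-based
  re-derivation of formulae and log-rank-optimal cutpoints.
- **Validation statistics** — Kaplan–Meier estimation, log-rank tests with
  Bonferroni control at α = 0.01, Cox proportional-hazards fits (Efron
  ties), Pearson chi-square and Cramér's V
  (`V = sqrt(χ² / (n·(min(r,c)−1)))`) for cohort comparisons.
- **Synthetic cohorts** — a seeded generator producing marker,
  clinicopathology and breast-cancer-specific survival (BCSS) structure
  consistent with the published class proportions, with hidden truth
  columns for recovery testing.

## Worked example

```python
from npiplus import (compute_hscore, MarkerProfile, classify, default_rulebase,
                     ClinPath, compute_index, assign_group, default_formulae)
from npiplus.ihc import Cutoff, CutoffTable, MARKERS

er = compute_hscore({1: 20, 2: 30, 3: 50})          # 20% weak, 30% moderate, 50% strong
cutoffs = CutoffTable({m: Cutoff(m, 100.0, "expert") for m in MARKERS})
profile = MarkerProfile(
    "case-001",
    {"ER": er, "PgR": 240, "CK7/8": 260, "CK5/6": 0, "EGFR": 5,
     "HER3": 15, "HER4": 10, "p53": 10, "MUC1": 220},
    her2_ihc="1+",
)
bclass, confidence = classify(profile, cutoffs, default_rulebase())
cp = ClinPath(tubules=2, pleomorphism=2, mitosis=2, size_cm=2.2,
              stage=2, nodes_positive=2, nodes_total=8)
index = compute_index(bclass, cp)
group = assign_group(bclass, index, default_formulae()[bclass])
print(er, bclass.value, confidence, cp.grade, round(index, 2), group.label)
```

prints

```
230.0 Luminal A 1.0 2 3.05 1.2
```

The ER H-score is 20·1 + 30·2 + 50·3 = 230.  The hormone-receptor-positive,
HER2-negative profile fully activates the Luminal A rule (confidence 1.0).
The tumour is grade 2 (component sum 6), its Luminal A index is
0.8·2 + 0.5·2 + 1.8·(2/8) = 3.05, which falls between the class cutpoints
2.2 and 3.4, i.e. intermediate prognostic group **1.2**.

## Command line

```bash
npiplus simulate --n 1000 --seed 17 --out cohort.csv   # synthetic cohort + truth file
npiplus validate cohort.csv --out report/              # full two-tier validation
npiplus classify cohort.csv --out classes.csv
npiplus score cohort.csv --out scores.csv
npiplus derive-formula cohort.csv --class "Luminal A"
npiplus derive-cutpoints scores.csv --n-groups 2
```

`validate` writes `class_distribution.csv`, `associations.csv` (Cramér's V
per clinicopathological variable), `group_distribution.csv`,
`km_curves.csv` (replotting-ready survival curves), `logrank.csv` and
`run_meta.json`.  Reruns with identical inputs are byte-identical, and
every patient is accounted for exactly once across classified /
unclassified / HER2-excluded.

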