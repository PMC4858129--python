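# Methods

## The two-tier model

NPI+ prognostication proceeds in two stages.

**Stage 1 — biological class.**  Ten biomarkers are scored by
immunohistochemistry with the modified Histochemical score
(H-score = Σ over intensities 0–3 of intensity × percent of cells, range
0–300).  Each marker is dichotomised at a cut-off: the cohort median for
ER, PgR, CK7/8, HER3, HER4 and MUC1, and expert-chosen values for CK5/6,
EGFR, p53 and HER2.  A marker whose cohort median is 0 cannot separate
negatives from positives, so the builder substitutes an expert fallback
(default 20) there — mirroring stated practice for zero-median markers.
HER2 status never comes from an H-score: the clinical IHC category decides
(3+ positive, 0/1+ negative), with equivocal 2+ tumours either excluded
from analysis (the default, matching the validation study) or resolved by
in-situ hybridisation.

Classification is fuzzy rather than crisp: each H-score is converted to
(μ_low, μ_high) memberships via a piecewise-linear shoulder of half-width
*w* around its cut-off (μ_high = 0 at cutoff−w, 1 at cutoff+w, 0.5 at the
cut-off; μ_low = 1 − μ_high).  A rule is a conjunction of (marker, side)
antecedents evaluated with Mamdani semantics — min within a rule, max
across the rules of one class, missing markers vetoing the rule — and the
argmax class wins, with a deterministic fixed-order tie-break and an
Unclassified verdict when the best activation falls below a threshold.

The original induced rules are unpublished; the shipped default rule base
encodes the accepted marker patterns of the seven classes and is an
editable, clearly approximate configuration:

- Luminal (CK7/8 high, ER high, HER2 negative), split by PgR/HER3/HER4:
  A = PgR high; N = PgR low with HER3 and HER4 low; B = PgR low with HER3
  or HER4 high.
- Basal (CK5/6 or EGFR high, ER low, HER2 negative), split by p53:
  altered = p53 high, normal = p53 low.
- HER2+ (HER2 positive), split by ER.  The ER-negative rule additionally
  requires PgR low: without it, a HER2+ tumour whose ER value sits exactly
  at the ER cut-off scores 0.5 for both HER2 rules and the winner would be
  decided only by tie-break order.  ER-negative tumours are almost always
  PgR-negative, so the extra antecedent changes nothing biologically while
  removing the systematic tie.

**Stage 2 — prognostic group.**  Each named class has a linear index over
clinicopathological variables whose coefficients are the published Cox
regression betas for breast-cancer-specific survival (BCSS) within that
class (e.g. Luminal A: 0.8·Mitosis + 0.5·Size + 1.8·NodalRatio; HER2+/ER−
carries the panel's only negative term, −0.6·NodalRatio).  Grade
components are 1–3 scores, stage is lymph-node stage 1–3, nodal ratio is
positive/total nodes, and Size is coded as the binary category (1 if
< 1.5 cm, 2 otherwise) because the source tables dichotomise size at
1.5 cm; continuous-cm coding is available behind `size_coding`.  Cutting
the index at per-class cutpoints yields the prognostic groups ("1.1" …
"7.2"; Luminal A has three groups, all other classes two).

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| membership half-width *w* | 20 | H-score | narrow enough that saturated profiles are crisp; per-marker overridable |
| activation threshold | 0.5 | — | a profile must at least sit on the positive side of every antecedent's cut-off; values at a cut-off (activation exactly 0.5) remain classified |
| expert cut-offs | CK5/6 10, EGFR 10, p53 20 | H-score | defaults, not from the source study (which leaves them unpublished): any convincing staining for the basal markers, accumulation beyond weak physiological staining for p53 |
| zero-median fallback | 20 | H-score | expert substitute when a median-policy marker has cohort median 0 |
| boundary conventions | value ≥ cut-off ⇒ high; index = cutpoint ⇒ worse group | — | deterministic; ties toward positivity / toward higher risk |
| significance for variable retention | 0.05 per-variable Wald | — | the derivation procedure keeps "most significant" variables without naming a level; 0.05 is the conventional choice |
| log-rank family control | Bonferroni at α = 0.01 | — | as in the validation analysis |

Formula derivation (`derive_formula`) fits a Cox model (lifelines, Efron
tie handling) on the candidate variables, retains those with Wald
p < 0.05, refits on the retained set and rounds coefficients to one
decimal — the precision of the published formulae.  Cutpoint derivation
(`derive_cutpoints`) replaces the unpublished original cutpoints by a
deterministic grid search: candidate cuts are midpoints between adjacent
distinct index values (quantile-thinned only when the combination count
would exceed a budget), each admissible combination keeping every group
above a minimum size fraction (default 10%) is scored by the log-rank
statistic, and exact ties resolve to the median candidate.

## Synthetic cohorts

The patient-level development and validation series are not publicly
deposited, so the generator emulates the *structure* the pipeline assumes
rather than any real dataset:

- **Classes** are drawn from the published development-series proportions
  (26.8 / 19.1 / 17.3 / 10.5 / 8.9 / 5.8 / 7.9 / 3.5%, Unclassified
  included).  The Unclassified pattern is an ER-positive profile without
  luminal cytokeratin or basal/HER2 features, which no default rule
  matches.
- **Markers** are near-binary: positives are clipped normals sitting
  almost entirely at H-score 300, negatives almost entirely at 0.  This
  idealisation is deliberate: with the median cut-off policy, a marker
  whose positive fraction exceeds one half (ER is positive in ~72% of the
  cohort) necessarily has its cohort median inside the positive mode, and
  under min-conjunction any tumour strictly below the median can never
  reach activation 0.5.  Saturated expression piles the median onto the
  ceiling value, where ties count as positive, so generated labels remain
  recoverable.  Real IHC H-scores are continuous, over-dispersed and
  scorer-dependent; passing recovery tests on these cohorts demonstrates
  correctness of the machinery, not expected accuracy on real stains.
  Profiles with any H-score in the ambiguous band (30–270) carry a
  `borderline` truth flag and are reported separately.
- **HER2** is 3+ in the HER2 classes and 0/1+ elsewhere, with a 7.5%
  equivocal (2+) fraction across the cohort — comparable to the 67/885
  exclusions reported in the validation series.
- **Clinicopathology** is drawn from class-conditional categoricals
  (basal/HER2 classes tilted toward higher grade and stage), with
  nodes-positive counts consistent with the drawn lymph-node stage
  (stage 1: 0; stage 2: 1–3; stage 3: ≥ 4).
- **Survival** is exponential with per-patient hazard
  baseline(class) × exp(index), where the index is the class's own
  published formula — so formula re-derivation has a known truth.
  Baselines were solved once, numerically, to give 10-year BCSS of about
  91/89/86% (luminal), 80/83% (basal) and 68/63% (HER2+), reproducing the
  qualitative ordering of the published survival curves.  Other-cause
  death is an independent exponential time (rate 0.012/yr) encoded as
  censoring — matching the BCSS censoring rule, not a competing-risks
  model — and administrative censoring is uniform over 5–25 years.

All randomness flows from one integer seed; identical configurations give
byte-identical cohorts.

## Numerical and design choices

- Chi-square tests use no continuity correction anywhere (including 2×2),
  keeping Cramér's V consistent across table sizes; V is the classical
  uncorrected statistic.  Expected counts below 5 warn but do not switch
  to exact tests.  All-zero rows/columns are dropped with a warning.
- Kaplan–Meier curves are right-continuous; evaluation at an event time
  returns the post-drop value, and queries beyond the last follow-up
  return the last value with an extrapolation warning.  Censored subjects
  tied with an event time are counted at risk at that time.
- Cox fits use the Efron tie approximation (lifelines' default);
  non-convergence and constant columns raise rather than return garbage.
- Degenerate inputs: empty rule bases, all-censored log-rank input,
  cohorts of one patient and empty classes are handled explicitly — the
  pipeline skips statistics it cannot compute and reports the skip rather
  than failing.
- The default prognostic-group cutpoints are placeholders (the originals
  are unpublished).  They were calibrated once so that within-class group
  proportions on the default synthetic cohort resemble the published
  group-size pattern, and `derive_cutpoints` can replace them from data.

## Known limitations

- The rule base and expert cut-offs are documented approximations of
  unpublished originals; on real cohorts both should be reviewed by a
  pathologist and, where labelled data exist, re-induced.
- The generator does not emulate TMA core sampling artefacts,
  inter-laboratory staining variation, scorer disagreement, missing-data
  patterns or treatment effects; treatment is not modelled at all.
- Other-cause mortality is independent of class and age, which real
  cohorts violate.
- The published per-cohort survival figures (e.g. 10-year BCSS of the two
  series) cannot be recomputed without the patient-level data; the test
  suite substitutes oracle-equivalence and parameter-recovery properties
  on synthetic data, with problem sizes of 1000–4000 patients and 20–50
  simulation replicates.
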