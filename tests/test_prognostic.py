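"""Prognostic index formulae, group assignment and data-driven derivation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from npiplus.fuzzy import BiologicalClass
from npiplus.prognostic import (
    ClinPath,
    IndexFormula,
    assign_group,
    compute_index,
    default_formulae,
    derive_cutpoints,
    derive_formula,
    formulae_from_config,
    formulae_to_config,
    nodal_ratio,
)

C = BiologicalClass

# Literal transcription of the published per-class formulae.
PUBLISHED_TERMS = {
    C.LUMINAL_A: (("mitosis", 0.8), ("size", 0.5), ("nodal_ratio", 1.8)),
    C.LUMINAL_N: (("tubules", 0.8), ("stage", 0.6)),
    C.LUMINAL_B: (("mitosis", 0.7), ("nodal_ratio", 1.0)),
    C.BASAL_P53_ALTERED: (("nodal_ratio", 1.4), ("size", 0.4)),
    C.BASAL_P53_NORMAL: (("stage", 0.6), ("pleomorphism", 1.8)),
    C.HER2_ER_POS: (("size", 0.5), ("stage", 0.9)),
    C.HER2_ER_NEG: (("stage", 0.9), ("nodal_ratio", -0.6)),
}


def _cp(**kwargs) -> ClinPath:
    base = dict(tubules=2, pleomorphism=2, mitosis=1, size_cm=1.0, stage=1,
                nodes_positive=0, nodes_total=4)
    base.update(kwargs)
    return ClinPath(**base)


class TestNodalRatio:
    @pytest.mark.parametrize("pos,total,expected", [(0, 4, 0.0), (2, 4, 0.5), (4, 4, 1.0)])
    def test_exact_quotient(self, pos, total, expected):
        assert nodal_ratio(pos, total) == expected

    @pytest.mark.parametrize("pos,total", [(5, 4), (1, 0), (-1, 4)])
    def test_invalid_counts_rejected(self, pos, total):
        with pytest.raises(ValueError):
            nodal_ratio(pos, total)


class TestClinPath:
    @pytest.mark.parametrize(
        "scores,grade", [((1, 1, 1), 1), ((2, 2, 1), 1), ((2, 2, 2), 2),
                         ((3, 3, 1), 2), ((3, 3, 2), 3), ((3, 3, 3), 3)]
    )
    def test_grade_from_component_sum(self, scores, grade):
        t, p, m = scores
        assert _cp(tubules=t, pleomorphism=p, mitosis=m).grade == grade

    def test_size_category_dichotomised_at_15mm(self):
        assert _cp(size_cm=1.49).size_cat == 1
        assert _cp(size_cm=1.5).size_cat == 2

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError):
            _cp(mitosis=4)
        with pytest.raises(ValueError):
            _cp(size_cm=0.0)
        with pytest.raises(ValueError):
            _cp(nodes_positive=9, nodes_total=4)


class TestComputeIndex:
    def test_default_formulae_transcribe_published_coefficients_exactly(self):
        formulae = default_formulae()
        for bclass, terms in PUBLISHED_TERMS.items():
            assert formulae[bclass].terms == terms
        # Luminal A is stratified into 3 groups, all other classes into 2
        assert len(formulae[C.LUMINAL_A].group_labels) == 3
        for bclass in PUBLISHED_TERMS:
            if bclass is not C.LUMINAL_A:
                assert len(formulae[bclass].group_labels) == 2

    @pytest.mark.parametrize(
        "bclass,cp,expected",
        [
            (C.LUMINAL_A, _cp(mitosis=1, size_cm=1.0, nodes_positive=0), 1.3),
            (C.HER2_ER_NEG, _cp(stage=1, nodes_positive=4, nodes_total=4), 0.3),
            (C.LUMINAL_B, _cp(mitosis=3, nodes_positive=2, nodes_total=4), 2.6),
            (C.LUMINAL_N, _cp(tubules=3, stage=2), 3.6),
            (C.BASAL_P53_NORMAL, _cp(stage=1, pleomorphism=3), 6.0),
        ],
    )
    def test_direct_substitution(self, bclass, cp, expected):
        assert compute_index(bclass, cp) == pytest.approx(expected)

    def test_unclassified_rejected(self):
        with pytest.raises(ValueError, match="Unclassified"):
            compute_index(C.UNCLASSIFIED, _cp())

    def test_continuous_size_coding_switch(self):
        cp = _cp(mitosis=1, size_cm=3.0, nodes_positive=0)
        assert compute_index(C.LUMINAL_A, cp, size_coding="continuous") == pytest.approx(
            0.8 + 0.5 * 3.0
        )

    def test_monotone_in_positive_terms_and_negative_nodal_ratio_term(self):
        low = compute_index(C.LUMINAL_A, _cp(mitosis=1))
        high = compute_index(C.LUMINAL_A, _cp(mitosis=3))
        assert high > low
        # HER2+/ER- carries the only negative coefficient: more positive
        # nodes lower the index
        few = compute_index(C.HER2_ER_NEG, _cp(stage=2, nodes_positive=0, nodes_total=8))
        many = compute_index(C.HER2_ER_NEG, _cp(stage=2, nodes_positive=8, nodes_total=8))
        assert many < few

    def test_config_round_trip(self):
        formulae = default_formulae()
        again = formulae_from_config(formulae_to_config(formulae))
        assert again == formulae


class TestAssignGroup:
    FORMULA = IndexFormula(C.LUMINAL_A, PUBLISHED_TERMS[C.LUMINAL_A],
                           (2.0, 3.0), ("1.1", "1.2", "1.3"))

    def test_below_first_cutpoint(self):
        assert assign_group(C.LUMINAL_A, 1.5, self.FORMULA).label == "1.1"

    def test_boundary_goes_to_worse_group(self):
        assert assign_group(C.LUMINAL_A, 2.0, self.FORMULA).label == "1.2"
        assert assign_group(C.LUMINAL_A, 3.0, self.FORMULA).label == "1.3"

    @given(st.floats(-10, 10, allow_nan=False))
    def test_partitions_the_real_line(self, index):
        group = assign_group(C.LUMINAL_A, index, self.FORMULA)
        assert group.label in self.FORMULA.group_labels
        # monotone: a strictly larger index never lowers the group rank
        bigger = assign_group(C.LUMINAL_A, index + 1.0, self.FORMULA)
        assert self.FORMULA.group_labels.index(bigger.label) >= \
            self.FORMULA.group_labels.index(group.label)

    def test_missing_cutpoints_instruct_configuration(self):
        bare = IndexFormula(C.LUMINAL_N, PUBLISHED_TERMS[C.LUMINAL_N], (), ("2.1",))
        with pytest.raises(ValueError, match="derive_cutpoints"):
            assign_group(C.LUMINAL_N, 2.0, bare)

    def test_cutpoints_must_ascend(self):
        with pytest.raises(ValueError, match="ascending"):
            IndexFormula(C.LUMINAL_A, PUBLISHED_TERMS[C.LUMINAL_A],
                         (3.0, 2.0), ("a", "b", "c"))


def _simulate_class_subset(rng, n, terms, *, extra_noise_vars=True):
    """ClinPath draws with exponential BCSS driven by the given terms."""
    cps, times, events = [], [], []
    for _ in range(n):
        stage = int(rng.integers(1, 4))
        npos = 0 if stage == 1 else (int(rng.integers(1, 4)) if stage == 2
                                     else int(rng.integers(4, 10)))
        ntot = int(max(4, npos + rng.integers(2, 12)))
        cp = ClinPath(
            tubules=int(rng.integers(1, 4)),
            pleomorphism=int(rng.integers(1, 4)),
            mitosis=int(rng.integers(1, 4)),
            size_cm=float(rng.uniform(0.5, 5.0)),
            stage=stage, nodes_positive=npos, nodes_total=ntot,
        )
        lp = sum(coef * cp.variable(name) for name, coef in terms)
        t_bc = rng.exponential(1.0 / (0.02 * np.exp(lp)))
        t_cens = rng.uniform(5.0, 25.0)
        times.append(min(t_bc, t_cens))
        events.append(1 if t_bc <= t_cens else 0)
        cps.append(cp)
    return cps, np.array(times), np.array(events)


class TestDeriveFormula:
    def test_recovers_generating_coefficients(self):
        rng = np.random.default_rng(5)
        terms = (("mitosis", 0.8), ("nodal_ratio", 1.8))
        cps, times, events = _simulate_class_subset(rng, 1000, terms)
        result = derive_formula(cps, times, events,
                                ("mitosis", "nodal_ratio", "tubules"))
        assert set(result.retained) == {"mitosis", "nodal_ratio"}
        for name, true_coef in terms:
            assert abs(result.raw_betas[name] - true_coef) < 0.15
        assert dict(result.terms)["mitosis"] == pytest.approx(0.8, abs=0.2)

    def test_single_binary_covariate_matches_closed_form_log_hazard_ratio(self):
        # exponential two-group data: the Cox beta estimates the log of the
        # ratio of event rates (events / person-time) between the groups
        rng = np.random.default_rng(9)
        n = 4000
        x = rng.integers(0, 2, n)
        rate = 0.05 * np.exp(np.log(2.0) * x)
        t_event = rng.exponential(1.0 / rate)
        t_cens = np.full(n, 30.0)
        times = np.minimum(t_event, t_cens)
        events = (t_event <= t_cens).astype(int)
        from npiplus.survival import cox_fit

        fit = cox_fit(pd.DataFrame({"x": x}), times, events)
        d1, pt1 = events[x == 1].sum(), times[x == 1].sum()
        d0, pt0 = events[x == 0].sum(), times[x == 0].sum()
        closed_form = np.log((d1 / pt1) / (d0 / pt0))
        assert fit.betas["x"] == pytest.approx(closed_form, abs=0.05)

    def test_no_events_rejected(self):
        rng = np.random.default_rng(1)
        cps, times, _ = _simulate_class_subset(rng, 50, (("mitosis", 0.8),))
        with pytest.raises(ValueError, match="events"):
            derive_formula(cps, times, np.zeros(50, dtype=int), ("mitosis",))


class TestDeriveCutpoints:
    def test_cutpoint_lands_in_survival_gap(self):
        # two well-separated subpopulations with an index gap (1, 2)
        rng = np.random.default_rng(3)
        n = 120
        index = np.concatenate([rng.uniform(0, 1, n), rng.uniform(2, 3, n)])
        rates = np.concatenate([np.full(n, 0.02), np.full(n, 0.5)])
        t_event = rng.exponential(1.0 / rates)
        times = np.minimum(t_event, 20.0)
        events = (t_event <= 20.0).astype(int)
        cuts = derive_cutpoints(index, times, events, n_groups=2)
        assert len(cuts) == 1 and 1.0 < cuts[0] < 2.0
        # exhaustive oracle: no admissible split beats the returned one
        from npiplus.survival import logrank_test

        def stat_at(c):
            hi = index > c
            return logrank_test([(times[~hi], events[~hi]), (times[hi], events[hi])])[0]

        distinct = np.unique(index)
        grid = (distinct[:-1] + distinct[1:]) / 2
        admissible = [c for c in grid if min((index <= c).sum(), (index > c).sum()) >= 24]
        assert stat_at(cuts[0]) == pytest.approx(max(stat_at(c) for c in admissible))

    def test_homogeneous_survival_ties_resolve_to_median_candidate(self):
        index = np.arange(10, dtype=float)
        times = np.full(10, 5.0)
        events = np.ones(10, dtype=int)
        cuts = derive_cutpoints(index, times, events, n_groups=2,
                                min_group_fraction=0.2)
        mids = (index[:-1] + index[1:]) / 2
        admissible = [c for c in mids if min((index <= c).sum(), (index > c).sum()) >= 2]
        assert cuts[0] == admissible[len(admissible) // 2]

    def test_three_groups_ascending(self):
        rng = np.random.default_rng(8)
        index = rng.uniform(0, 3, 150)
        rates = 0.02 * np.exp(index)
        t_event = rng.exponential(1.0 / rates)
        times = np.minimum(t_event, 15.0)
        events = (t_event <= 15.0).astype(int)
        cuts = derive_cutpoints(index, times, events, n_groups=3)
        assert len(cuts) == 2 and cuts[0] < cuts[1]

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            derive_cutpoints([1.0, 1.0, 1.0], [1, 2, 3], [1, 1, 1], n_groups=2)
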