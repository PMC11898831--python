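"""Set-overlap concordance metrics, on the study fixture and by construction."""
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multirater import (
    ConcordanceModel,
    PanelError,
    Recommendation,
    SyntheticPanelConfig,
    case_hit,
    case_prf,
    generate_panel,
    macro_prf,
    mean_options_count,
    overlap_agreement_matrix,
    reference_agreement,
    stratify_by_consensus,
    union_accuracy,
    union_reference,
)

from conftest import make_panel

option_sets = st.lists(
    st.sampled_from(range(1, 12)), min_size=1, max_size=5, unique=True
)


class TestUnionReference:
    def test_fixture_case_3_union(self, study_panel):
        assert union_reference(study_panel.case(3), study_panel.reference_raters) == {1, 4, 7}

    def test_fixture_case_9_union_with_multi_option_cell(self, study_panel):
        assert union_reference(study_panel.case(9), study_panel.reference_raters) == {4, 5, 10}

    def test_identical_references_collapse(self):
        panel = make_panel([{"a": (1,), "r1": (8,), "r2": (8,)}], ["a"], ["r1", "r2"])
        assert union_reference(panel.case(1), panel.reference_raters) == {8}

    def test_empty_roster_rejected(self, study_panel):
        with pytest.raises(PanelError):
            union_reference(study_panel.case(1), ())


class TestCaseHit:
    @pytest.mark.parametrize(
        "options, ref, expected",
        [((1, 2), {1, 7}, True), ((2,), {1, 7}, False), ((6,), {4, 5, 10}, False)],
    )
    def test_overlap_rule(self, options, ref, expected):
        assert case_hit(Recommendation(options), frozenset(ref)) is expected

    def test_fixture_case_13_chatgpt_misses_union(self, study_panel):
        case = study_panel.case(13)
        ref = union_reference(case, study_panel.reference_raters)
        assert ref == {4, 5, 10}
        assert not case_hit(case.recommendation("chatgpt"), ref)


class TestUnionAccuracy:
    @pytest.mark.parametrize(
        "candidate, hits",
        [("chatgpt", 18), ("gemini", 19), ("perplexity", 17), ("deepseek", 14), ("copilot", 9)],
    )
    def test_fixture_values(self, study_panel, candidate, hits):
        p = union_accuracy(study_panel, candidate)
        assert (p.numerator, p.denominator) == (hits, 22)

    def test_candidate_equal_to_a_reference_is_perfect(self, study_panel):
        # clone surgeon1's column into a candidate: every case self-overlaps
        rows = [
            {**{r: c.recommendation(r).options for r in study_panel.raters},
             "clone": c.recommendation("surgeon1").options}
            for c in study_panel.cases
        ]
        panel = make_panel(
            rows, list(study_panel.candidate_raters) + ["clone"],
            study_panel.reference_raters,
        )
        p = union_accuracy(panel, "clone")
        assert (p.numerator, p.denominator) == (22, 22)

    def test_unknown_rater_rejected(self, study_panel):
        with pytest.raises(PanelError):
            union_accuracy(study_panel, "nobody")


class TestReferenceAgreement:
    @pytest.mark.parametrize(
        "candidate, hits",
        [("chatgpt", 16), ("gemini", 17), ("perplexity", 12), ("copilot", 7)],
    )
    def test_fixture_surgeon1_intersection_rule(self, study_panel, candidate, hits):
        p = reference_agreement(study_panel, candidate, "surgeon1")
        assert (p.numerator, p.denominator) == (hits, 22)

    def test_universal_candidate_agrees_everywhere(self, study_panel):
        rows = [
            {**{r: c.recommendation(r).options for r in study_panel.raters},
             "all": tuple(range(1, 12))}
            for c in study_panel.cases
        ]
        panel = make_panel(
            rows, list(study_panel.candidate_raters) + ["all"],
            study_panel.reference_raters,
        )
        for ref in panel.reference_raters:
            assert reference_agreement(panel, "all", ref).numerator == 22

    def test_alternative_rules_are_stricter(self, study_panel):
        for cand in study_panel.candidate_raters:
            for ref in study_panel.reference_raters:
                inter = reference_agreement(study_panel, cand, ref, "intersection")
                for rule in ("equality", "primary"):
                    assert (
                        reference_agreement(study_panel, cand, ref, rule).numerator
                        <= inter.numerator
                    )

    def test_primary_rule_chatgpt_surgeon2(self, study_panel):
        p = reference_agreement(study_panel, "chatgpt", "surgeon2", "primary")
        assert (p.numerator, p.denominator) == (7, 22)


class TestMeanOptionsCount:
    def test_fixture_chatgpt_and_copilot(self, study_panel):
        assert mean_options_count(study_panel, "chatgpt") == Fraction(42, 22)
        assert mean_options_count(study_panel, "copilot") == Fraction(1)

    def test_all_singleton_rater_is_one(self, toy_panel):
        assert mean_options_count(toy_panel, "r1") == 1


class TestCasePRF:
    @pytest.mark.parametrize(
        "options, ref, expected",
        [
            ((1, 2, 4), {1, 4, 7}, (Fraction(2, 3), Fraction(2, 3), Fraction(2, 3))),
            ((8,), {8}, (1, 1, 1)),
            ((6,), {4, 5, 10}, (0, 0, 0)),
        ],
    )
    def test_direct_set_counts(self, options, ref, expected):
        assert case_prf(Recommendation(options), frozenset(ref)) == expected

    @given(option_sets, option_sets)
    @settings(max_examples=200, deadline=None)
    def test_subset_gives_perfect_precision_superset_perfect_recall(self, a, b):
        cand = Recommendation(tuple(a))
        ref = frozenset(b)
        p, r, _ = case_prf(cand, ref)
        if cand.option_set <= ref:
            assert p == 1
        if ref <= cand.option_set:
            assert r == 1

    @given(option_sets, option_sets, st.sampled_from(range(1, 12)))
    @settings(max_examples=200, deadline=None)
    def test_adding_an_option_never_decreases_hit_or_recall(self, a, b, extra):
        cand = Recommendation(tuple(a))
        ref = frozenset(b)
        if extra in cand.option_set:
            grown = cand
        else:
            grown = Recommendation(cand.options + (extra,))
        assert case_hit(grown, ref) >= case_hit(cand, ref)
        assert case_prf(grown, ref)[1] >= case_prf(cand, ref)[1]


class TestMacroPRF:
    def test_fixture_chatgpt_macro_precision(self, study_panel):
        p, r, f = macro_prf(study_panel, "chatgpt")
        # independent oracle: average the 22 per-case precisions directly
        expected = sum(
            (
                Fraction(
                    len(
                        c.recommendation("chatgpt").option_set
                        & union_reference(c, study_panel.reference_raters)
                    ),
                    len(c.recommendation("chatgpt").option_set),
                )
                for c in study_panel.cases
            ),
            Fraction(0),
        ) / 22
        assert p == expected
        assert abs(float(p) - 0.485) < 1e-3

    def test_perfect_candidate_scores_ones(self, study_panel):
        rows = [
            {**{r: c.recommendation(r).options for r in study_panel.raters},
             "oracle": tuple(sorted(union_reference(c, study_panel.reference_raters)))}
            for c in study_panel.cases
        ]
        panel = make_panel(
            rows, list(study_panel.candidate_raters) + ["oracle"],
            study_panel.reference_raters,
        )
        assert macro_prf(panel, "oracle") == (1, 1, 1)

    def test_two_case_mean(self):
        panel = make_panel(
            [{"a": (1,), "r": (1,)}, {"a": (2,), "r": (3,)}], ["a"], ["r"]
        )
        p, r, f = macro_prf(panel, "a")
        assert p == r == f == Fraction(1, 2)

    def test_micro_pools_counts(self, study_panel):
        p, r, f = macro_prf(study_panel, "chatgpt", average="micro")
        assert p == Fraction(
            sum(
                len(
                    c.recommendation("chatgpt").option_set
                    & union_reference(c, study_panel.reference_raters)
                )
                for c in study_panel.cases
            ),
            42,
        )


class TestConsensusStratification:
    def test_fixture_strict_set_unanimous_cases(self, study_panel):
        s = stratify_by_consensus(study_panel, "strict_set")
        assert set(s.unanimous_case_ids) == {5, 18}
        assert set(s.unanimous_case_ids) | set(s.non_unanimous_case_ids) == set(
            study_panel.case_ids
        )
        assert not set(s.unanimous_case_ids) & set(s.non_unanimous_case_ids)

    def test_fixture_primary_match_includes_case_6(self, study_panel):
        s = stratify_by_consensus(study_panel, "primary_match")
        assert set(s.unanimous_case_ids) == {5, 6, 18}

    def test_always_agreeing_references_leave_empty_stratum(self):
        rows = [{"a": (1,), "r1": (2,), "r2": (2,)} for _ in range(3)]
        s = stratify_by_consensus(make_panel(rows, ["a"], ["r1", "r2"]), "strict_set")
        assert s.non_unanimous_case_ids == ()
        assert s.accuracy["a"]["non_unanimous"] is None

    def test_invalid_definition_rejected(self, study_panel):
        with pytest.raises(ValueError):
            stratify_by_consensus(study_panel, "majority")


class TestOverlapAgreementMatrix:
    def test_fixture_chatgpt_gemini(self, study_panel):
        m = overlap_agreement_matrix(study_panel)
        p = m.get("chatgpt", "gemini")
        assert (p.numerator, p.denominator) == (21, 22)
        assert m.get("gemini", "chatgpt") == p  # symmetric
        assert m.get("chatgpt", "chatgpt").value == 1.0  # diagonal

    def test_identical_and_disjoint_raters(self):
        rows = [{"x": (1,), "y": (1,), "z": (2,), "r": (1,)} for _ in range(4)]
        m = overlap_agreement_matrix(make_panel(rows, ["x", "y", "z"], ["r"]))
        assert m.get("x", "y").value == 1.0
        assert m.get("x", "z").value == 0.0

    def test_needs_two_raters(self, study_panel):
        with pytest.raises(PanelError):
            overlap_agreement_matrix(study_panel, ["chatgpt"])

    def test_matches_brute_force_on_all_two_case_subset_panels(self):
        """Exhaustive: every 2-rater, 2-case panel over subsets of {1,2,3}."""
        import itertools

        subsets = [
            tuple(s)
            for r in (1, 2, 3)
            for s in itertools.combinations((1, 2, 3), r)
        ]
        for cells in itertools.product(
            itertools.product(subsets, repeat=2), repeat=2
        ):
            rows = [{"a": pair[0], "r": pair[1]} for pair in cells]
            panel = make_panel(rows, ["a"], ["r"])
            m = overlap_agreement_matrix(panel, ("a", "r"))
            hits = sum(bool(set(pair[0]) & set(pair[1])) for pair in cells)
            assert m.get("a", "r").numerator == hits

    def test_matches_brute_force_double_loop_on_random_panels(self):
        for seed in range(40):
            config = SyntheticPanelConfig(
                n_cases=5, vocabulary=(1, 2, 3, 4), n_reference=2,
                n_candidate=3, adherence=0.5, extra_rate=0.4, seed=seed,
            )
            panel = generate_panel(config)
            m = overlap_agreement_matrix(panel, panel.raters)
            for i, a in enumerate(panel.raters):
                for b in panel.raters[i + 1:]:
                    hits = 0
                    for case in panel.cases:  # the oracle: literal double loop
                        sa = set(case.recommendation(a).options)
                        sb = set(case.recommendation(b).options)
                        if sa & sb:
                            hits += 1
                    assert m.get(a, b).numerator == hits


class TestUnionDominance:
    def test_on_fixture(self, study_panel):
        for cand in study_panel.candidate_raters:
            ua = union_accuracy(study_panel, cand).fraction
            for ref in study_panel.reference_raters:
                assert ua >= reference_agreement(study_panel, cand, ref).fraction

    def test_on_200_random_synthetic_panels(self):
        for seed in range(200):
            config = SyntheticPanelConfig(
                n_cases=8, vocabulary=tuple(range(1, 7)), n_reference=3,
                n_candidate=2, adherence=0.3 + 0.002 * seed, extra_rate=0.25,
                seed=seed,
            )
            panel = generate_panel(config)
            for cand in panel.candidate_raters:
                ua = union_accuracy(panel, cand).fraction
                for ref in panel.reference_raters:
                    assert ua >= reference_agreement(panel, cand, ref).fraction


class TestConcordanceModel:
    def test_results_consistent_with_primitives(self, study_panel):
        res = ConcordanceModel(study_panel).fit()
        cc = res.candidate("gemini")
        assert cc.union_accuracy == union_accuracy(study_panel, "gemini")
        assert cc.average_reference_agreement == sum(
            (p.fraction for p in cc.per_reference_agreement.values()), Fraction(0)
        ) / 3
        assert len(cc.case_detail) == 22

    def test_from_dataframe_roundtrip(self, study_panel):
        frame = study_panel.to_frame()
        model = ConcordanceModel.from_dataframe(
            frame, study_panel.candidate_raters, study_panel.reference_raters
        )
        res = model.fit()
        assert res.candidate("copilot").union_accuracy.numerator == 9

    def test_all_proportions_in_unit_interval(self, study_panel):
        res = ConcordanceModel(study_panel).fit()
        frame = res.to_frame()
        pct = frame[frame["metric"] != "mean_options_count"]
        assert ((pct["value"] >= 0) & (pct["value"] <= 1)).all()
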