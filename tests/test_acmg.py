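"""Unit and property tests for the four-stage classification engine."""

import pytest
from hypothesis import given, strategies as st

from varpheno.acmg import (
    CRITERIA,
    CATEGORY_SIZES,
    COMBINATION_RULES,
    WEIGHTS,
    CriterionCode,
    DeNovoStatus,
    EvidenceProfile,
    Polarity,
    Strength,
    StrengthCounts,
    ValidationError,
    VariantContext,
    check_vus_overrides,
    classify,
    compute_weighted_score,
    evaluate_combination_rules,
    resolve_conflict,
    score_to_class,
    summarize_report,
)

from oracles import (
    count_vectors,
    profile_codes_for_counts,
    score_band_oracle,
    stage1_oracle,
)

profiles = st.frozensets(st.sampled_from(CRITERIA)).map(EvidenceProfile)

FAVOURABLE_CONTEXT = VariantContext(
    functional_studies_done=True,
    in_hotspot_or_critical_domain=True,
    de_novo_status=DeNovoStatus.CONFIRMED,
    observed_healthy_inconsistent_genotype=False,
    alternate_molecular_basis=False,
)


class TestInventory:
    def test_exactly_28_criteria_partitioned_by_category(self):
        assert len(CRITERIA) == 28
        assert CATEGORY_SIZES == {
            "PVS": 1, "PS": 4, "PM": 6, "PP": 5, "BA": 1, "BS": 4, "BP": 7,
        }
        for prefix, n in CATEGORY_SIZES.items():
            assert sum(c.startswith(prefix) for c in CRITERIA) == n

    @pytest.mark.parametrize(
        "code,strength,polarity",
        [
            ("PVS1", Strength.VERY_STRONG, Polarity.PATHOGENIC),
            ("PS3", Strength.STRONG, Polarity.PATHOGENIC),
            ("PM6", Strength.MODERATE, Polarity.PATHOGENIC),
            ("PP5", Strength.SUPPORTING, Polarity.PATHOGENIC),
            ("BA1", Strength.STAND_ALONE, Polarity.BENIGN),
            ("BS4", Strength.STRONG, Polarity.BENIGN),
            ("BP7", Strength.SUPPORTING, Polarity.BENIGN),
        ],
    )
    def test_strength_and_polarity_follow_the_prefix(self, code, strength, polarity):
        criterion = CriterionCode(code)
        assert criterion.strength is strength
        assert criterion.polarity is polarity

    @pytest.mark.parametrize("bad", ["PS9", "PVS2", "BA2", "XX1", ""])
    def test_unknown_code_rejected_by_name(self, bad):
        with pytest.raises(ValidationError, match="unknown"):
            CriterionCode(bad)
        with pytest.raises(ValidationError):
            EvidenceProfile(frozenset({bad}))

    def test_counts_respect_category_caps(self):
        counts = StrengthCounts.from_codes(CRITERIA)
        assert counts == StrengthCounts(1, 4, 6, 5, 1, 4, 7)
        assert counts.total == 28
        with pytest.raises(ValidationError):
            StrengthCounts(nPVS=2)


class TestWeightedScore:
    def test_printed_weight_table(self):
        assert WEIGHTS == {"BA": 1, "BS": 2, "BP": 3, "PP": 4, "PM": 8, "PS": 16, "PVS": 32}

    @pytest.mark.parametrize(
        "codes,expected",
        [
            ({"PVS1"}, 32),
            (set(), 0),
            ({"PM1", "PM2", "PP3"}, 20),
            (set(CRITERIA), 194),
        ],
    )
    def test_score_examples(self, codes, expected):
        assert compute_weighted_score(EvidenceProfile(frozenset(codes))) == expected

    @given(st.frozensets(st.sampled_from(CRITERIA)), st.sampled_from(CRITERIA))
    def test_monotone_under_adding_a_criterion(self, codes, extra):
        base = compute_weighted_score(EvidenceProfile(codes))
        grown = compute_weighted_score(EvidenceProfile(codes | {extra}))
        assert grown >= base

    @given(st.frozensets(st.sampled_from(CRITERIA)), st.frozensets(st.sampled_from(CRITERIA)))
    def test_additive_over_disjoint_profiles(self, a, b):
        b = b - a
        total = compute_weighted_score(EvidenceProfile(a | b))
        assert total == (
            compute_weighted_score(EvidenceProfile(a))
            + compute_weighted_score(EvidenceProfile(b))
        )


class TestScoreBands:
    @pytest.mark.parametrize(
        "score,expected",
        [(0, "LB"), (1, "LB"), (2, "LB"), (3, "B"), (8, "B"), (9, "VUS"),
         (12, "VUS"), (16, "VUS"), (17, "VUS"), (20, "VUS"), (25, "VUS"),
         (26, "LP"), (48, "LP"), (49, "P"), (96, "P"), (194, "P")],
    )
    def test_band_boundaries(self, score, expected):
        assert score_to_class(score) == expected

    def test_total_over_achievable_range(self):
        # 194 is the maximum achievable score (all 28 criteria activated)
        for score in range(0, 195):
            assert score_to_class(score) == score_band_oracle(score)

    def test_negative_score_rejected(self):
        with pytest.raises(ValidationError):
            score_to_class(-1)


class TestCombinationRules:
    def test_rule_table_is_data(self):
        assert len(COMBINATION_RULES) == 18
        tiers = {r.tier for r in COMBINATION_RULES}
        assert tiers == {"P", "LP", "B", "LB"}

    def test_pvs1_plus_pm2_is_likely_pathogenic(self):
        outcome = evaluate_combination_rules(EvidenceProfile(frozenset({"PVS1", "PM2"})))
        assert outcome.tentative == "LP"
        assert "LP: PVS1+1PM" in [r.rule_id for r in outcome.pathogenic_rules]
        assert not outcome.benign_rules

    def test_empty_profile_satisfies_nothing(self):
        outcome = evaluate_combination_rules(EvidenceProfile())
        assert outcome.tentative is None
        assert not outcome.pathogenic_rules and not outcome.benign_rules

    def test_ba1_is_stand_alone_benign(self):
        outcome = evaluate_combination_rules(EvidenceProfile(frozenset({"BA1"})))
        assert outcome.tentative == "B"
        assert [r.rule_id for r in outcome.benign_rules] == ["B: BA1"]

    def test_both_sides_firing_marks_a_conflict(self):
        outcome = evaluate_combination_rules(
            EvidenceProfile(frozenset({"PVS1", "PS1", "BS1", "BS2"}))
        )
        assert outcome.tentative == "conflict"
        assert outcome.conflict

    def test_every_satisfied_rule_is_reported(self):
        # PVS1 + PS1 + PM1 + PM2 satisfies several pathogenic rules at once
        outcome = evaluate_combination_rules(
            EvidenceProfile(frozenset({"PVS1", "PS1", "PM1", "PM2"}))
        )
        ids = {r.rule_id for r in outcome.pathogenic_rules}
        assert {"P: PVS1+>=1PS", "P: PVS1+>=2PM", "LP: PVS1+1PM"} <= ids

    def test_oracle_equivalence_over_all_count_vectors(self):
        """Stage 1 agrees with an independently coded rule-table lookup over
        all 33,600 admissible strength-count vectors."""
        n = 0
        for vec in count_vectors():
            n += 1
            profile = EvidenceProfile(profile_codes_for_counts(*vec))
            outcome = evaluate_combination_rules(profile)
            expected = stage1_oracle(*vec)
            assert outcome.tentative == expected, f"counts {vec}"
        assert n == 33_600


class TestConflictResolution:
    def _resolve(self, codes):
        profile = EvidenceProfile(frozenset(codes))
        outcome = evaluate_combination_rules(profile)
        return resolve_conflict(profile, outcome.pathogenic_rules, outcome.benign_rules)

    def test_strong_pathogenic_outweighs_supporting_benign(self):
        # PVS/PS present, benign side holds only BP criteria
        assert self._resolve({"PVS1", "PS3", "BP4", "BP7"}) == "P"

    def test_multiple_pm_outweighs_benign_lacking_bs(self):
        assert self._resolve({"PM1", "PM2", "PM4", "BP1", "BP4"}) == "LP"

    def test_comparable_strong_evidence_defaults_to_vus(self):
        assert self._resolve({"PVS1", "PS1", "BA1", "BS2"}) == "VUS"

    def test_bs_outweighs_pathogenic_lacking_ps(self):
        # benign side strong (BS), pathogenic side only moderates: the
        # benign-side tier (LB via 1BS+1BP) prevails
        assert self._resolve({"PM1", "PM2", "PM3", "BS1", "BP1"}) == "LB"

    def test_requires_a_true_conflict(self):
        profile = EvidenceProfile(frozenset({"PVS1", "PS1"}))
        outcome = evaluate_combination_rules(profile)
        with pytest.raises(ValidationError):
            resolve_conflict(profile, outcome.pathogenic_rules, outcome.benign_rules)

    def test_depends_only_on_the_activated_set(self):
        codes = ["PM1", "PM2", "PM4", "BP1", "BP4"]
        a = self._resolve(codes)
        b = self._resolve(list(reversed(codes)))
        assert a == b


class TestVusOverrides:
    def test_functional_studies_not_done_forces_vus(self):
        context = VariantContext(
            functional_studies_done=False,
            in_hotspot_or_critical_domain=True,
            de_novo_status=DeNovoStatus.CONFIRMED,
        )
        outcome = check_vus_overrides(EvidenceProfile(frozenset({"PP3"})), context)
        assert outcome is not None
        cls, reasons = outcome
        assert cls == "VUS"
        assert any("functional studies" in r for r in reasons)

    def test_assumed_de_novo_forces_vus(self):
        context = VariantContext(
            functional_studies_done=True,
            in_hotspot_or_critical_domain=True,
            de_novo_status=DeNovoStatus.ASSUMED,
        )
        outcome = check_vus_overrides(EvidenceProfile(frozenset({"PM6"})), context)
        assert outcome is not None
        assert any("de novo" in r for r in outcome[1])

    def test_all_flags_favourable_yields_no_override(self):
        outcome = check_vus_overrides(
            EvidenceProfile(frozenset({"PM1", "PP3"})), FAVOURABLE_CONTEXT
        )
        assert outcome is None


class TestClassifyHierarchy:
    def test_pvs1_pm2_decided_by_combination_rule(self):
        result = classify(EvidenceProfile(frozenset({"PVS1", "PM2"})), FAVOURABLE_CONTEXT)
        assert result.final_class == "LP"
        assert result.deciding_stage == "combination_rule"
        assert result.rationale == "PVS1 + PM2"
        assert result.satisfied_rules
        assert result.total_score == 40

    def test_empty_profile_with_missing_evidence_is_override_vus(self):
        result = classify(EvidenceProfile(), VariantContext(functional_studies_done=False))
        assert result.final_class == "VUS"
        assert result.deciding_stage == "vus_override"

    def test_empty_profile_is_vus_even_with_favourable_context(self):
        # score 0 must NOT fall into the LB band: no evidence is not benign evidence
        result = classify(EvidenceProfile(), FAVOURABLE_CONTEXT)
        assert result.final_class == "VUS"
        assert result.total_score == 0

    def test_two_pm_one_pp_falls_through_to_scoring(self):
        result = classify(EvidenceProfile(frozenset({"PM1", "PM4", "PP3"})), FAVOURABLE_CONTEXT)
        assert result.deciding_stage == "weighted_score"
        assert result.total_score == 20
        assert result.final_class == "VUS"
        assert result.rationale == "Score-based VUS"

    def test_conflicting_strong_evidence_resolves_to_vus(self):
        result = classify(EvidenceProfile(frozenset({"PVS1", "PS1", "BA1", "BS2"})))
        assert result.deciding_stage == "conflict_resolution"
        assert result.final_class == "VUS"

    def test_guard_blocks_overrides_when_strong_evidence_present(self):
        # single BS: no rule fires, but the guard (no PVS/PS/BS) fails, so the
        # score decides: weight 2 -> LB band
        result = classify(EvidenceProfile(frozenset({"BS1"})),
                          VariantContext(functional_studies_done=False))
        assert result.deciding_stage == "weighted_score"
        assert result.final_class == "LB"

    @given(profiles)
    def test_total_and_deterministic(self, profile):
        a = classify(profile, FAVOURABLE_CONTEXT)
        b = classify(profile, FAVOURABLE_CONTEXT)
        assert a.final_class in ("P", "LP", "VUS", "LB", "B")
        assert (a.final_class, a.deciding_stage, a.total_score) == (
            b.final_class, b.deciding_stage, b.total_score
        )

    @given(profiles)
    def test_stage1_class_side_matches_evidence_side(self, profile):
        result = classify(profile, FAVOURABLE_CONTEXT)
        if result.deciding_stage == "combination_rule":
            if result.final_class in ("P", "LP"):
                assert profile.pathogenic
            if result.final_class in ("B", "LB"):
                assert profile.benign

    @given(profiles, st.sampled_from(["BA1", "BS1", "BS3", "BP1", "BP4", "BP7"]))
    def test_adding_benign_evidence_never_strengthens_pathogenic(self, profile, benign_code):
        rank = {"B": 0, "LB": 1, "VUS": 2, "LP": 3, "P": 4}
        before = classify(profile, FAVOURABLE_CONTEXT)
        if before.deciding_stage != "combination_rule" or before.final_class not in ("P", "LP"):
            return
        after = classify(
            EvidenceProfile(profile.activated | {benign_code}), FAVOURABLE_CONTEXT
        )
        assert rank[after.final_class] <= rank[before.final_class]


class TestReport:
    def test_counts_and_score_for_pvs1_pm2(self):
        context = VariantContext(variant_name="NM_004006.3:c.9568C>T", condition="DMD")
        result = classify(EvidenceProfile(frozenset({"PVS1", "PM2"})), FAVOURABLE_CONTEXT)
        report = summarize_report(result, context)
        assert report.final_class == "LP"
        assert report.counts == {"PVS": 1, "PS": 0, "PM": 1, "PP": 0, "BA1": 0, "BS": 0, "BP": 0}
        assert report.total_score == 40
        assert "PVS:1 PS:0 PM:1 PP:0 BA1:0 BS:0 BP:0" in report.to_text()
        assert report.variant_name == "NM_004006.3:c.9568C>T"

    def test_empty_profile_report(self):
        report = summarize_report(classify(EvidenceProfile(), FAVOURABLE_CONTEXT))
        assert sum(report.counts.values()) == 0
        assert report.total_score == 0

    def test_all_criteria_report(self):
        result = classify(EvidenceProfile(frozenset(CRITERIA)), FAVOURABLE_CONTEXT)
        report = summarize_report(result)
        assert report.counts == {"PVS": 1, "PS": 4, "PM": 6, "PP": 5, "BA1": 1, "BS": 4, "BP": 7}
        assert report.total_score == 194

    def test_json_round_trip(self):
        import json

        result = classify(EvidenceProfile(frozenset({"PVS1", "PM2"})), FAVOURABLE_CONTEXT)
        report = summarize_report(result)
        parsed = json.loads(report.to_json())
        assert parsed["final_class"] == "LP"
        assert parsed["counts"]["PVS"] == 1
        assert parsed["activated"] == ["PVS1", "PM2"]
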