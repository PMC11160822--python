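"""PM3/BP2 biallelic point scoring with caps, PS4 gates, PS3/BS3 combination."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atmcurate import (
    CaseControlResult,
    ObservationRecord,
    bp2_aggregate,
    pm3_aggregate,
    ps3_bs3_combine,
    ps4_case_control,
)
from atmcurate.clinical import (
    AssayVerdict,
    OtherVariantClass,
    Phase,
    PhenotypeTier,
    Source,
    bp2_observation_points,
    pm3_observation_points,
)
from atmcurate.model import Direction, RuleConstants, StrengthLevel

S = StrengthLevel


def proband(tier, phase, other=OtherVariantClass.pathogenic_or_LP, pid="p"):
    return ObservationRecord(
        proband_id=pid, at_affected=True, phenotype_tier=tier,
        other_variant_class=other, phase=phase,
    )


def carrier(phase, other=OtherVariantClass.pathogenic_or_LP, source=Source.clinical_laboratory, pid="c"):
    return ObservationRecord(
        proband_id=pid, adult_unaffected=True, other_variant_class=other,
        phase=phase, source=source,
    )


class TestPm3Points:
    @pytest.mark.parametrize(
        "tier,phase,other,points",
        [
            (PhenotypeTier.confident, Phase.confirmed_in_trans, OtherVariantClass.pathogenic_or_LP, 4),
            (PhenotypeTier.confident, Phase.phase_unknown, OtherVariantClass.pathogenic_or_LP, 2),
            (PhenotypeTier.confident, Phase.phase_unknown, OtherVariantClass.VUS, 1),
            (PhenotypeTier.confident, Phase.homozygous, OtherVariantClass.pathogenic_or_LP, 2),
            (PhenotypeTier.consistent, Phase.confirmed_in_trans, OtherVariantClass.pathogenic_or_LP, 2),
            (PhenotypeTier.consistent, Phase.phase_unknown, OtherVariantClass.pathogenic_or_LP, 1),
            (PhenotypeTier.consistent, Phase.phase_unknown, OtherVariantClass.unidentified, 0.5),
            (PhenotypeTier.consistent, Phase.homozygous, OtherVariantClass.pathogenic_or_LP, 1),
        ],
    )
    def test_point_table(self, tier, phase, other, points):
        assert pm3_observation_points(proband(tier, phase, other)) == points

    def test_non_proband_rejected(self):
        with pytest.raises(ValueError):
            pm3_observation_points(carrier(Phase.homozygous))

    def test_single_max_weight_proband_reaches_very_strong(self):
        item = pm3_aggregate([proband(PhenotypeTier.confident, Phase.confirmed_in_trans)])
        assert item.code_id == "PM3" and item.strength is S.very_strong

    def test_two_consistent_phase_unknown_probands_reach_strong(self):
        obs = [
            proband(PhenotypeTier.consistent, Phase.phase_unknown, pid="p1"),
            proband(PhenotypeTier.consistent, Phase.phase_unknown, pid="p2"),
        ]
        assert pm3_aggregate(obs).strength is S.strong

    def test_half_point_maps_to_supporting(self):
        obs = [proband(PhenotypeTier.consistent, Phase.phase_unknown,
                       OtherVariantClass.unidentified)]
        assert pm3_aggregate(obs).strength is S.supporting

    def test_empty_list_yields_nothing(self):
        assert pm3_aggregate([]) is None

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(list(PhenotypeTier)),
                st.sampled_from(list(Phase)),
                st.sampled_from(list(OtherVariantClass)),
            ),
            min_size=1, max_size=8,
        )
    )
    def test_adding_a_proband_never_lowers_strength(self, specs):
        obs = [proband(t, p, o, pid=f"p{i}") for i, (t, p, o) in enumerate(specs)]
        before = pm3_aggregate(obs[:-1])
        after = pm3_aggregate(obs)
        if before is not None:
            assert after is not None and after.strength >= before.strength


class TestBp2Points:
    def test_lab_weights(self):
        assert bp2_observation_points(carrier(Phase.homozygous)) == -1
        assert bp2_observation_points(carrier(Phase.confirmed_in_trans)) == -1
        assert bp2_observation_points(carrier(Phase.phase_unknown)) == -0.5

    def test_database_weights_half_of_lab(self):
        assert bp2_observation_points(carrier(Phase.phase_unknown, source=Source.database)) == -0.25
        assert bp2_observation_points(carrier(Phase.homozygous, source=Source.database)) == -0.5

    def test_non_qualifying_carrier_scores_zero(self):
        rec = carrier(Phase.phase_unknown, other=OtherVariantClass.VUS)
        assert bp2_observation_points(rec) == 0

    def test_affected_record_rejected(self):
        with pytest.raises(ValueError):
            bp2_observation_points(proband(PhenotypeTier.confident, Phase.homozygous))

    def test_homozygous_subtotal_capped_at_minus_two(self):
        obs = [carrier(Phase.homozygous, pid=f"c{i}") for i in range(5)]
        item = bp2_aggregate(obs)
        assert item.strength is S.moderate  # counted as two supporting lines

    def test_compound_het_carriers_reach_strong_at_minus_four(self):
        obs = [carrier(Phase.confirmed_in_trans, pid=f"c{i}") for i in range(4)]
        assert bp2_aggregate(obs).strength is S.strong

    def test_total_capped_at_minus_four(self):
        obs = [carrier(Phase.confirmed_in_trans, pid=f"c{i}") for i in range(12)]
        item = bp2_aggregate(obs)
        assert item.strength is S.strong and "-4" in item.provenance

    def test_empty_yields_nothing(self):
        assert bp2_aggregate([]) is None

    @settings(derandomize=True, max_examples=60)
    @given(
        n_hom=st.integers(0, 10),
        n_trans=st.integers(0, 10),
        source=st.sampled_from(list(Source)),
    )
    def test_caps_hold_for_any_mix(self, n_hom, n_trans, source):
        constants = RuleConstants()
        obs = [carrier(Phase.homozygous, source=source, pid=f"h{i}") for i in range(n_hom)]
        obs += [carrier(Phase.confirmed_in_trans, source=source, pid=f"t{i}") for i in range(n_trans)]
        hom_total = max(sum(bp2_observation_points(o, constants) for o in obs[:n_hom]), -2.0)
        assert hom_total >= -2.0
        item = bp2_aggregate(obs, constants)
        if item is not None:
            assert item.strength <= S.strong


class TestPs4:
    @pytest.mark.parametrize(
        "odds,p,ci,passes",
        [
            (2.5, 0.01, 1.6, True),
            (2.5, 0.2, 1.6, False),
            (1.8, 0.01, 1.6, False),
            (2.5, 0.01, 1.4, False),
            (2.0, 0.049, 1.51, True),
        ],
    )
    def test_conjunctive_gates(self, odds, p, ci, passes):
        item = ps4_case_control(CaseControlResult(odds_ratio=odds, p_value=p, ci_lower=ci))
        assert (item is not None) is passes
        if item:
            assert item.strength is S.strong

    def test_disjunctive_config_switch(self):
        constants = RuleConstants(ps4_disjunctive=True)
        item = ps4_case_control(
            CaseControlResult(odds_ratio=1.8, p_value=0.01, ci_lower=1.6), constants
        )
        assert item is not None


class TestPs3Bs3:
    A = AssayVerdict

    @pytest.mark.parametrize(
        "kinase,radio,code,strength",
        [
            (A.nonfunctional, A.nonfunctional, "PS3", S.moderate),
            (A.nonfunctional, A.unavailable, "PS3", S.supporting),
            (A.unavailable, A.nonfunctional, None, None),
            (A.nonfunctional, A.functional, None, None),
            (A.functional, A.nonfunctional, None, None),
            (A.functional, A.functional, "BS3", S.moderate),
            (A.functional, A.unavailable, "BS3", S.supporting),
            (A.unavailable, A.functional, "BS3", S.supporting),
            (A.unavailable, A.unavailable, None, None),
        ],
    )
    def test_combination_table(self, kinase, radio, code, strength):
        item = ps3_bs3_combine(kinase, radio)
        assert (item.code_id if item else None) == code
        if item:
            assert item.strength is strength

    def test_never_both_directions(self):
        for k in AssayVerdict:
            for r in AssayVerdict:
                item = ps3_bs3_combine(k, r)
                if item is not None:
                    assert item.direction in (Direction.pathogenic, Direction.benign)
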