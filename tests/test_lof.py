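"""PVS1 decision tree: reading-frame arithmetic, NMD/domain weighting,
CNV and splice branches, RNA observations."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atmcurate import StrengthLevel, exon_event_frame, one_level_below, rna_evidence
from atmcurate.lof import (
    LofCategory,
    LofVariant,
    PredictedEvent,
    RnaAssayResult,
    RnaEffect,
    SpliceSite,
    TandemStatus,
    donor_conforms_consensus,
    evaluate_pvs1,
    pvs1_initiation,
    pvs1_ptc,
    pvs1_splice,
)
from atmcurate.model import Exon, TranscriptModel
from atmcurate.synth import random_transcript

S = StrengthLevel


def toy_tx(*lengths):
    exons, phase = [], 0
    for i, length in enumerate(lengths, start=1):
        end = (phase + length) % 3
        exons.append(Exon(index=i, coding_length_nt=length, start_phase=phase, end_phase=end))
        phase = end
    return TranscriptModel(
        name="toy", exons=exons, protein_length_aa=sum(lengths) // 3 - 1,
        complete=sum(lengths) % 3 == 0,
    )


class TestExonEventFrame:
    @pytest.mark.parametrize(
        "span,expected",
        [((2, 2), "frameshift"), ((2, 3), "in_frame"), ((1, 4), "in_frame")],
    )
    def test_toy_transcript(self, span, expected):
        tx = toy_tx(126, 88, 101, 45)
        assert exon_event_frame(tx, span) == expected

    def test_zero_length_exon_is_in_frame(self):
        tx = toy_tx(126, 0, 100, 45  + 3)
        assert exon_event_frame(tx, (2, 2)) == "in_frame"

    def test_invalid_span_rejected(self):
        tx = toy_tx(126, 88, 101, 45)
        with pytest.raises(ValueError):
            exon_event_frame(tx, (3, 9))

    def test_agrees_with_nucleotide_counting_oracle(self):
        """Brute force: concatenate per-exon nucleotide runs and count the
        excised letters directly."""
        rng = random.Random(20240501)
        for _ in range(300):
            tx = random_transcript(rng)
            seq = "".join(chr(ord("a") + e.index % 26) * e.coding_length_nt for e in tx.exons)
            first = rng.randint(1, len(tx.exons))
            last = rng.randint(first, len(tx.exons))
            letters = {chr(ord("a") + e.index % 26) for e in tx.exons[first - 1 : last]}
            removed = sum(seq.count(c) for c in letters)
            expected = "in_frame" if removed % 3 == 0 else "frameshift"
            assert exon_event_frame(tx, (first, last)) == expected

    def test_frame_equals_phase_comparison(self):
        rng = random.Random(99)
        for _ in range(100):
            tx = random_transcript(rng)
            first = rng.randint(1, len(tx.exons))
            last = rng.randint(first, len(tx.exons))
            span = tx.exon_span_slice(first, last)
            by_phase = "in_frame" if span[0].start_phase == span[-1].end_phase else "frameshift"
            assert exon_event_frame(tx, (first, last)) == by_phase


class TestPtc:
    def test_nmd_predicted_stop_is_very_strong_with_pm5(self, transcript, domain_map, constants):
        v = LofVariant(category=LofCategory.nonsense, ptc_aa=481)
        res = pvs1_ptc(v, transcript, domain_map, constants)
        assert res.strength is S.very_strong and res.pm5_supporting

    def test_last_critical_residue_eligible_without_pm5(self, transcript, domain_map, constants):
        # the most C-terminal pathogenic stop: still fully eligible, but not
        # "upstream of" itself, so no PM5 co-application
        v = LofVariant(category=LofCategory.nonsense, ptc_aa=3047, nmd_predicted=False)
        res = pvs1_ptc(v, transcript, domain_map, constants)
        assert res.strength is S.very_strong and not res.pm5_supporting

    def test_downstream_of_last_critical_residue_gets_no_weight(
        self, transcript, domain_map, constants
    ):
        v = LofVariant(category=LofCategory.nonsense, ptc_aa=3050)
        res = pvs1_ptc(v, transcript, domain_map, constants)
        assert res.strength is S.none and not res.pm5_supporting

    def test_early_stop_before_met94_stays_eligible(self, transcript, domain_map, constants):
        v = LofVariant(category=LofCategory.nonsense, ptc_aa=40)
        assert pvs1_ptc(v, transcript, domain_map, constants).strength is S.very_strong

    def test_missing_ptc_rejected(self, transcript, domain_map, constants):
        with pytest.raises(ValueError):
            pvs1_ptc(
                LofVariant(category=LofCategory.frameshift), transcript, domain_map, constants
            )


class TestExonCnv:
    def test_frameshifting_nmd_prone_deletion_very_strong(
        self, transcript, domain_map, constants
    ):
        v = LofVariant(
            category=LofCategory.exon_deletion, exon_span=(5, 5),
            event_in_frame=False, nmd_predicted=True,
        )
        res = evaluate_pvs1(v, transcript, domain_map, constants)
        assert res.strength is S.very_strong and res.pm5_supporting

    def test_in_frame_deletion_in_n_solenoid_strong(self, transcript, domain_map, constants):
        v = LofVariant(
            category=LofCategory.exon_deletion, exon_span=(5, 6),
            event_in_frame=True, affected_domain="n_solenoid",
        )
        assert evaluate_pvs1(v, transcript, domain_map, constants).strength is S.strong

    def test_in_frame_deletion_in_fatkin_very_strong(self, transcript, domain_map, constants):
        v = LofVariant(
            category=LofCategory.exon_deletion, exon_span=(60, 61),
            event_in_frame=True, affected_domain="fatkin",
        )
        assert evaluate_pvs1(v, transcript, domain_map, constants).strength is S.very_strong

    def test_domain_derived_from_transcript_when_not_annotated(
        self, transcript, domain_map, constants
    ):
        # early exons encode N-Solenoid residues only
        v = LofVariant(
            category=LofCategory.exon_deletion, exon_span=(3, 4), event_in_frame=True
        )
        assert evaluate_pvs1(v, transcript, domain_map, constants).strength is S.strong

    @pytest.mark.parametrize(
        "tandem,domain,expected",
        [
            (TandemStatus.confirmed, "fatkin", S.very_strong),
            (TandemStatus.presumed, "fatkin", S.strong),
            (TandemStatus.confirmed, "n_solenoid", S.strong),
            (TandemStatus.presumed, "n_solenoid", S.moderate),
        ],
    )
    def test_in_frame_duplication_weights(
        self, transcript, domain_map, constants, tandem, domain, expected
    ):
        v = LofVariant(
            category=LofCategory.exon_duplication, exon_span=(5, 6),
            tandem_status=tandem, event_in_frame=True, affected_domain=domain,
        )
        assert evaluate_pvs1(v, transcript, domain_map, constants).strength is expected

    def test_duplication_spanning_both_domains_no_weight(
        self, transcript, domain_map, constants
    ):
        v = LofVariant(
            category=LofCategory.exon_duplication, exon_span=(5, 60),
            tandem_status=TandemStatus.confirmed, event_in_frame=True,
        )
        assert evaluate_pvs1(v, transcript, domain_map, constants).strength is S.none

    def test_duplication_involving_utr_no_weight(self, transcript, domain_map, constants):
        v = LofVariant(
            category=LofCategory.exon_duplication, exon_span=(2, 3),
            tandem_status=TandemStatus.confirmed, involves_utr=True,
        )
        assert evaluate_pvs1(v, transcript, domain_map, constants).strength is S.none

    def test_duplication_requires_tandem_status(self, transcript, domain_map, constants):
        with pytest.raises(ValueError):
            evaluate_pvs1(
                LofVariant(category=LofCategory.exon_duplication, exon_span=(2, 3)),
                transcript, domain_map, constants,
            )


def splice_variant(**kwargs):
    base = dict(
        category=LofCategory.canonical_splice,
        splice_site=SpliceSite.donor,
        intron_offset=1,
    )
    base.update(kwargs)
    return LofVariant(**base)


class TestSplice:
    def test_frameshift_exon_skip_nmd_very_strong(self, transcript, domain_map, constants):
        v = splice_variant(
            predicted_event=PredictedEvent.exon_skip, event_in_frame=False, nmd_predicted=True
        )
        assert pvs1_splice(v, transcript, domain_map, constants).strength is S.very_strong

    def test_in_frame_skip_in_n_solenoid_strong(self, transcript, domain_map, constants):
        v = splice_variant(
            predicted_event=PredictedEvent.exon_skip, event_in_frame=True,
            affected_domain="n_solenoid",
        )
        assert pvs1_splice(v, transcript, domain_map, constants).strength is S.strong

    def test_plus2_t_to_c_without_predicted_impact_no_weight(
        self, transcript, domain_map, constants
    ):
        v = splice_variant(
            intron_offset=2, alt_base="C", spliceai=0.05, predicted_event=PredictedEvent.none
        )
        assert pvs1_splice(v, transcript, domain_map, constants).strength is S.none

    def test_plus2_t_to_c_with_predicted_impact_keeps_weight(
        self, transcript, domain_map, constants
    ):
        v = splice_variant(
            intron_offset=2, alt_base="C", spliceai=0.8,
            predicted_event=PredictedEvent.exon_skip, event_in_frame=False, nmd_predicted=True,
        )
        assert pvs1_splice(v, transcript, domain_map, constants).strength is S.very_strong

    def test_atypical_native_site_c7515_no_weight(self, transcript, domain_map, constants):
        v = splice_variant(
            intron_offset=2, special_site_id="c.7515+2", predicted_event=PredictedEvent.none
        )
        assert pvs1_splice(v, transcript, domain_map, constants).strength is S.none

    def test_in_frame_cryptic_site_with_deleterious_provean_supporting(
        self, transcript, domain_map, constants
    ):
        v = splice_variant(
            predicted_event=PredictedEvent.cryptic_site, event_in_frame=True, provean=-4.5
        )
        assert pvs1_splice(v, transcript, domain_map, constants).strength is S.supporting

    def test_missing_splice_site_rejected(self, transcript, domain_map, constants):
        with pytest.raises(ValueError):
            pvs1_splice(
                LofVariant(
                    category=LofCategory.canonical_splice,
                    predicted_event=PredictedEvent.exon_skip,
                    event_in_frame=False,
                ),
                transcript, domain_map, constants,
            )

    @pytest.mark.parametrize("context,conforms", [
        ("GGTAAGT", True), ("GGTGAGT", True), ("ggtaagt", True),
        ("GGTCCGT", False), ("GATAAGT", False),
    ])
    def test_donor_consensus_check(self, context, conforms):
        assert donor_conforms_consensus(context) is conforms

    def test_last_nucleotide_reduced_one_level_across_all_branches(
        self, transcript, domain_map, constants
    ):
        """Full branch enumeration: the last-nucleotide weight equals one
        level below the weight of the matched +1/2 variant."""
        cases = []
        for event in (PredictedEvent.exon_skip, PredictedEvent.intron_retention):
            for in_frame in (False, True):
                for domain in ("n_solenoid", "fatkin", "both"):
                    for nmd in (False, True):
                        cases.append(
                            dict(
                                predicted_event=event, event_in_frame=in_frame,
                                affected_domain=domain, nmd_predicted=nmd,
                            )
                        )
        for provean in (-4.0, 0.0):
            cases.append(
                dict(
                    predicted_event=PredictedEvent.cryptic_site, event_in_frame=True,
                    affected_domain="n_solenoid", provean=provean,
                )
            )
        for kw in cases:
            base = pvs1_splice(splice_variant(**kw), transcript, domain_map, constants)
            last = pvs1_splice(
                splice_variant(category=LofCategory.last_nucleotide, **kw),
                transcript, domain_map, constants,
            )
            if base.strength is S.none:
                assert last.strength is S.none
            else:
                assert last.strength is one_level_below(base.strength)


class TestInitiationAndRna:
    def test_initiation_codon_very_strong(self):
        res = pvs1_initiation(LofVariant(category=LofCategory.initiation_codon))
        assert res.strength is S.very_strong

    def test_wrong_category_rejected(self):
        with pytest.raises(ValueError):
            pvs1_initiation(LofVariant(category=LofCategory.nonsense, ptc_aa=5))

    def test_observed_splice_defect_becomes_pvs1_rna(self):
        item = rna_evidence(
            RnaAssayResult(
                effect=RnaEffect.deleterious_splice_defect, quality_weight=S.very_strong
            )
        )
        assert item.code_id == "PVS1" and item.rna_flag and item.strength is S.very_strong

    def test_normal_splicing_becomes_bp7_rna(self):
        item = rna_evidence(
            RnaAssayResult(effect=RnaEffect.no_aberrant_splicing, quality_weight=S.strong)
        )
        assert item.code_id == "BP7" and item.rna_flag and item.strength is S.strong

    def test_bp7_rna_capped_at_strong(self):
        with pytest.raises(ValueError):
            RnaAssayResult(
                effect=RnaEffect.no_aberrant_splicing, quality_weight=S.very_strong
            )

    def test_inconclusive_assay_yields_nothing(self):
        assert rna_evidence(RnaAssayResult(effect=RnaEffect.inconclusive)) is None


@settings(derandomize=True, max_examples=100)
@given(
    ptc=st.integers(2, 3200),
    nmd=st.booleans(),
)
def test_ptc_strength_never_stand_alone_and_pm5_only_at_very_strong(ptc, nmd):
    from atmcurate import load_atm_domain_map, load_atm_transcript, load_default_constants

    res = pvs1_ptc(
        LofVariant(category=LofCategory.nonsense, ptc_aa=ptc, nmd_predicted=nmd),
        load_atm_transcript(), load_atm_domain_map(), load_default_constants(),
    )
    assert res.strength is not S.stand_alone
    if res.pm5_supporting:
        assert res.strength is S.very_strong
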