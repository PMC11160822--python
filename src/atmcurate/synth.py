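"""Synthetic data: random transcript models and annotation-bundle generators.

``all_branches`` mode emits a deterministic suite of bundles that exercises
every decision-tree branch and every adopted evidence code at least once;
``random`` mode draws seeded random bundles for fuzzing.  Both are
deterministic for a fixed seed.
"""

from __future__ import annotations

import random
from typing import Literal

from .clinical import (
    AssayVerdict,
    CaseControlResult,
    ObservationRecord,
    OtherVariantClass,
    Phase,
    PhenotypeTier,
    Source,
)
from .insilico import (
    PredictionScores,
    Ps1Baseline,
    Ps1Comparison,
    Ps1Relation,
    VariantLocation,
)
from .lof import (
    LofCategory,
    LofVariant,
    PredictedEvent,
    RnaAssayResult,
    RnaEffect,
    SpliceSite,
    TandemStatus,
)
from .model import Exon, StrengthLevel, TranscriptModel
from .pipeline import AnnotationBundle, Consequence
from .population import PopulationData, Subpopulation


def random_transcript(
    rng: random.Random,
    n_exons: int | None = None,
    min_len: int = 20,
    max_len: int = 300,
) -> TranscriptModel:
    """A random multi-exon transcript with chained phases and a consistent
    protein length (total coding length forced to a multiple of three)."""
    n = n_exons if n_exons is not None else rng.randint(2, 20)
    lengths = [rng.randint(min_len, max_len) for _ in range(n)]
    total = sum(lengths)
    lengths[-1] += (3 - total % 3) % 3
    if sum(lengths) < 6:
        lengths[-1] += 6
    exons = []
    phase = 0
    for i, length in enumerate(lengths, start=1):
        end_phase = (phase + length) % 3
        exons.append(
            Exon(index=i, coding_length_nt=length, start_phase=phase, end_phase=end_phase)
        )
        phase = end_phase
    return TranscriptModel(
        name=f"synthetic-{n}",
        exons=exons,
        protein_length_aa=sum(lengths) // 3 - 1,
    )


def _pop(af: float | None, count: int = 0, under: bool = False) -> PopulationData:
    return PopulationData(
        subpops=[
            Subpopulation(
                name="pooled",
                filtering_af=af,
                allele_count=count,
                underrepresented=under,
            )
        ]
    )


_RARE = _pop(0.0, 0)


def _branch_bundles() -> list[AnnotationBundle]:
    """One bundle per decision-tree branch / evidence code."""
    b: list[AnnotationBundle] = []

    # population codes
    b.append(AnnotationBundle(variant_id="syn-ba1", consequence=Consequence.missense,
                              population=_pop(0.02, 500)))
    b.append(AnnotationBundle(variant_id="syn-bs1", consequence=Consequence.missense,
                              population=_pop(0.002, 40)))
    b.append(AnnotationBundle(variant_id="syn-pm2-absent", consequence=Consequence.missense,
                              population=_pop(None, 0)))
    b.append(AnnotationBundle(variant_id="syn-pm2-under", consequence=Consequence.missense,
                              population=_pop(0.00002, 1, under=True)))

    # PVS1: nonsense/frameshift branches
    b.append(AnnotationBundle(
        variant_id="syn-nonsense-nmd", consequence=Consequence.nonsense,
        population=_RARE,
        lof=LofVariant(category=LofCategory.nonsense, ptc_aa=481)))
    b.append(AnnotationBundle(
        variant_id="syn-nonsense-critical", consequence=Consequence.nonsense,
        population=_RARE,
        lof=LofVariant(category=LofCategory.nonsense, ptc_aa=3047, nmd_predicted=False)))
    b.append(AnnotationBundle(
        variant_id="syn-nonsense-downstream", consequence=Consequence.nonsense,
        population=_RARE,
        lof=LofVariant(category=LofCategory.nonsense, ptc_aa=3050, nmd_predicted=False)))
    b.append(AnnotationBundle(
        variant_id="syn-frameshift-nmd", consequence=Consequence.frameshift,
        population=_RARE,
        lof=LofVariant(category=LofCategory.frameshift, ptc_aa=376)))

    # PVS1: gross deletions / duplications
    b.append(AnnotationBundle(
        variant_id="syn-del-fs-nmd", consequence=Consequence.structural,
        population=_RARE,
        lof=LofVariant(category=LofCategory.exon_deletion, exon_span=(5, 5),
                       event_in_frame=False, nmd_predicted=True)))
    b.append(AnnotationBundle(
        variant_id="syn-del-inframe-nsol", consequence=Consequence.structural,
        population=_RARE,
        lof=LofVariant(category=LofCategory.exon_deletion, exon_span=(5, 6),
                       event_in_frame=True, affected_domain="n_solenoid")))
    b.append(AnnotationBundle(
        variant_id="syn-del-inframe-fatkin", consequence=Consequence.structural,
        population=_RARE,
        lof=LofVariant(category=LofCategory.exon_deletion, exon_span=(55, 56),
                       event_in_frame=True, affected_domain="fatkin")))
    b.append(AnnotationBundle(
        variant_id="syn-dup-utr", consequence=Consequence.structural,
        population=_RARE,
        lof=LofVariant(category=LofCategory.exon_duplication, exon_span=(2, 3),
                       tandem_status=TandemStatus.confirmed, involves_utr=True)))
    b.append(AnnotationBundle(
        variant_id="syn-dup-both-domains", consequence=Consequence.structural,
        population=_RARE,
        lof=LofVariant(category=LofCategory.exon_duplication, exon_span=(10, 50),
                       tandem_status=TandemStatus.confirmed, event_in_frame=True,
                       affected_domain="both")))
    b.append(AnnotationBundle(
        variant_id="syn-dup-fatkin-confirmed", consequence=Consequence.structural,
        population=_RARE,
        lof=LofVariant(category=LofCategory.exon_duplication, exon_span=(55, 56),
                       tandem_status=TandemStatus.confirmed, event_in_frame=True,
                       affected_domain="fatkin")))
    b.append(AnnotationBundle(
        variant_id="syn-dup-nsol-presumed", consequence=Consequence.structural,
        population=_RARE,
        lof=LofVariant(category=LofCategory.exon_duplication, exon_span=(5, 6),
                       tandem_status=TandemStatus.presumed, event_in_frame=True,
                       affected_domain="n_solenoid")))

    # PVS1: splice branches
    b.append(AnnotationBundle(
        variant_id="syn-splice-fs-nmd", consequence=Consequence.intronic,
        population=_RARE, canonical_dinucleotide=True,
        lof=LofVariant(category=LofCategory.canonical_splice, splice_site=SpliceSite.donor,
                       intron_offset=1, predicted_event=PredictedEvent.exon_skip,
                       event_in_frame=False, nmd_predicted=True)))
    b.append(AnnotationBundle(
        variant_id="syn-splice-inframe-nsol", consequence=Consequence.intronic,
        population=_RARE, canonical_dinucleotide=True,
        lof=LofVariant(category=LofCategory.canonical_splice, splice_site=SpliceSite.donor,
                       intron_offset=1, predicted_event=PredictedEvent.exon_skip,
                       event_in_frame=True, affected_domain="n_solenoid")))
    b.append(AnnotationBundle(
        variant_id="syn-splice-plus2tc", consequence=Consequence.intronic,
        population=_RARE, canonical_dinucleotide=True,
        lof=LofVariant(category=LofCategory.canonical_splice, splice_site=SpliceSite.donor,
                       intron_offset=2, alt_base="C", spliceai=0.05,
                       predicted_event=PredictedEvent.none)))
    b.append(AnnotationBundle(
        variant_id="syn-splice-7515", consequence=Consequence.intronic,
        population=_RARE, canonical_dinucleotide=True,
        lof=LofVariant(category=LofCategory.canonical_splice, splice_site=SpliceSite.donor,
                       intron_offset=2, special_site_id="c.7515+2",
                       predicted_event=PredictedEvent.none)))
    b.append(AnnotationBundle(
        variant_id="syn-splice-cryptic-provean", consequence=Consequence.intronic,
        population=_RARE, canonical_dinucleotide=True,
        lof=LofVariant(category=LofCategory.canonical_splice, splice_site=SpliceSite.acceptor,
                       intron_offset=-1, predicted_event=PredictedEvent.cryptic_site,
                       event_in_frame=True, provean=-4.0)))
    b.append(AnnotationBundle(
        variant_id="syn-last-nt", consequence=Consequence.synonymous,
        population=_RARE, canonical_dinucleotide=True,
        lof=LofVariant(category=LofCategory.last_nucleotide, splice_site=SpliceSite.donor,
                       intron_offset=0, native_donor_context="GGTCCGT",
                       predicted_event=PredictedEvent.exon_skip,
                       event_in_frame=False, nmd_predicted=True)))
    b.append(AnnotationBundle(
        variant_id="syn-initiation", consequence=Consequence.start_loss,
        population=_RARE,
        lof=LofVariant(category=LofCategory.initiation_codon)))

    # RNA observations
    b.append(AnnotationBundle(
        variant_id="syn-rna-deleterious", consequence=Consequence.intronic,
        population=_RARE,
        rna_assay=RnaAssayResult(effect=RnaEffect.deleterious_splice_defect,
                                 quality_weight=StrengthLevel.very_strong)))
    b.append(AnnotationBundle(
        variant_id="syn-rna-normal", consequence=Consequence.intronic,
        population=_RARE,
        scores=PredictionScores(spliceai=0.05),
        rna_assay=RnaAssayResult(effect=RnaEffect.no_aberrant_splicing,
                                 quality_weight=StrengthLevel.strong)))

    # in silico codes
    b.append(AnnotationBundle(
        variant_id="syn-pp3-protein", consequence=Consequence.missense,
        population=_RARE, scores=PredictionScores(revel=0.9, spliceai=0.05)))
    b.append(AnnotationBundle(
        variant_id="syn-bp4-protein", consequence=Consequence.missense,
        scores=PredictionScores(revel=0.1, spliceai=0.05)))
    b.append(AnnotationBundle(
        variant_id="syn-pp3-splice", consequence=Consequence.intronic,
        population=_RARE, scores=PredictionScores(spliceai=0.6),
        location=VariantLocation(site=SpliceSite.donor, offset=5)))
    b.append(AnnotationBundle(
        variant_id="syn-bp4-bp7-intronic", consequence=Consequence.intronic,
        scores=PredictionScores(spliceai=0.02),
        location=VariantLocation(site=SpliceSite.donor, offset=12)))
    b.append(AnnotationBundle(
        variant_id="syn-bp4-bp7-synonymous", consequence=Consequence.synonymous,
        scores=PredictionScores(spliceai=0.01),
        location=VariantLocation(synonymous_exonic=True)))
    b.append(AnnotationBundle(
        variant_id="syn-ps1", consequence=Consequence.intronic,
        population=_RARE,
        ps1=Ps1Comparison(vua_at_canonical_dinucleotide=False,
                          vua_baseline_code=Ps1Baseline.PP3,
                          relation=Ps1Relation.same_nucleotide,
                          comparison_classification="pathogenic"),
        scores=PredictionScores(spliceai=0.6)))
    b.append(AnnotationBundle(
        variant_id="syn-pm4", consequence=Consequence.stop_loss,
        population=_RARE))

    # clinical codes
    b.append(AnnotationBundle(
        variant_id="syn-pm3", consequence=Consequence.missense,
        population=_RARE, scores=PredictionScores(revel=0.8),
        observations=[
            ObservationRecord(proband_id="p1", at_affected=True,
                              phenotype_tier=PhenotypeTier.confident,
                              other_variant_class=OtherVariantClass.pathogenic_or_LP,
                              phase=Phase.confirmed_in_trans),
        ]))
    b.append(AnnotationBundle(
        variant_id="syn-bp2", consequence=Consequence.missense,
        scores=PredictionScores(revel=0.1),
        observations=[
            ObservationRecord(proband_id=f"c{i}", adult_unaffected=True,
                              phase=Phase.homozygous,
                              source=Source.clinical_laboratory)
            for i in range(4)
        ] + [
            ObservationRecord(proband_id=f"t{i}", adult_unaffected=True,
                              other_variant_class=OtherVariantClass.pathogenic_or_LP,
                              phase=Phase.confirmed_in_trans,
                              source=Source.clinical_laboratory)
            for i in range(2)
        ]))
    b.append(AnnotationBundle(
        variant_id="syn-ps4", consequence=Consequence.missense,
        population=_RARE, scores=PredictionScores(revel=0.8),
        case_control=CaseControlResult(odds_ratio=2.5, p_value=0.01, ci_lower=1.7)))
    b.append(AnnotationBundle(
        variant_id="syn-ps3-moderate", consequence=Consequence.missense,
        population=_RARE, scores=PredictionScores(revel=0.8),
        kinase_assay=AssayVerdict.nonfunctional,
        radiosensitivity_assay=AssayVerdict.nonfunctional))
    b.append(AnnotationBundle(
        variant_id="syn-ps3-supporting", consequence=Consequence.missense,
        population=_RARE,
        kinase_assay=AssayVerdict.nonfunctional))
    b.append(AnnotationBundle(
        variant_id="syn-bs3-moderate", consequence=Consequence.missense,
        scores=PredictionScores(revel=0.1),
        kinase_assay=AssayVerdict.functional,
        radiosensitivity_assay=AssayVerdict.functional))
    return b


def _random_bundle(rng: random.Random, idx: int) -> AnnotationBundle:
    consequence = rng.choice(list(Consequence))
    kwargs: dict = {"variant_id": f"rnd-{idx}", "consequence": consequence}
    af = rng.choice([None, 0.0, 1e-6, 1e-4, 1e-3, 1e-2])
    kwargs["population"] = _pop(af, rng.randint(0, 100) if af else 0)
    if rng.random() < 0.7:
        kwargs["scores"] = PredictionScores(
            revel=round(rng.random(), 3), spliceai=round(rng.random(), 3)
        )
    if consequence in (Consequence.nonsense, Consequence.frameshift):
        kwargs["lof"] = LofVariant(
            category=LofCategory(consequence.value), ptc_aa=rng.randint(2, 3056)
        )
    return AnnotationBundle(**kwargs)


def generate_synthetic_bundles(
    seed: int,
    n: int = 50,
    coverage: Literal["all_branches", "random"] = "all_branches",
) -> list[AnnotationBundle]:
    """Deterministic synthetic annotation bundles.

    ``all_branches`` starts from the fixed branch-coverage suite and pads
    with seeded random bundles up to ``n`` (``n`` is a floor: the coverage
    suite is never truncated); ``random`` draws all ``n`` bundles at random.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = random.Random(seed)
    bundles: list[AnnotationBundle] = []
    if coverage == "all_branches":
        bundles.extend(_branch_bundles())
    while len(bundles) < n:
        bundles.append(_random_bundle(rng, len(bundles)))
    return bundles
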