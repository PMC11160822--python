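"""End-to-end evaluation: annotation bundle -> evidence profile -> tier.

An :class:`AnnotationBundle` carries all raw per-variant inputs (population
frequencies, predictor scores, loss-of-function annotations, RNA and
protein assay verdicts, biallelic observations, case-control statistics).
``evaluate_bundle`` derives every applicable evidence code, validates the
co-application restrictions and returns the validated profile with its
classification.  No predictor is executed and no clinical adjudication is
performed: scores and phenotype labels are inputs.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

from .clinical import (
    AssayVerdict,
    CaseControlResult,
    ObservationRecord,
    bp2_aggregate,
    pm3_aggregate,
    ps3_bs3_combine,
    ps4_case_control,
)
from .combiner import RestrictionMatrix, classify, validate_profile
from .insilico import (
    PredictionScores,
    Ps1Comparison,
    VariantLocation,
    bp7_eligible,
    merge_pp3_bp4,
    pm4_stop_loss,
    pp3_bp4_protein,
    pp3_bp4_splice,
    ps1_item,
)
from .lof import LofVariant, RnaAssayResult, pvs1_items, rna_evidence
from .population import PopulationData, evaluate_population_codes
from .model import (
    Classification,
    DomainMap,
    EvidenceItem,
    EvidenceProfile,
    RuleConstants,
    TranscriptModel,
    load_atm_domain_map,
    load_atm_transcript,
    load_default_constants,
    make_item,
)


class Consequence(str, enum.Enum):
    missense = "missense"
    synonymous = "synonymous"
    intronic = "intronic"
    nonsense = "nonsense"
    frameshift = "frameshift"
    inframe_indel = "inframe_indel"
    stop_loss = "stop_loss"
    start_loss = "start_loss"
    structural = "structural"
    other = "other"


class AnnotationBundle(BaseModel):
    """All raw inputs for one variant; unknown fields are rejected."""

    model_config = ConfigDict(extra="forbid")

    variant_id: str
    consequence: Consequence = Consequence.other
    lof: Optional[LofVariant] = None
    population: Optional[PopulationData] = None
    scores: Optional[PredictionScores] = None
    canonical_dinucleotide: bool = False
    location: Optional[VariantLocation] = None
    rna_assay: Optional[RnaAssayResult] = None
    kinase_assay: AssayVerdict = AssayVerdict.unavailable
    radiosensitivity_assay: AssayVerdict = AssayVerdict.unavailable
    observations: list[ObservationRecord] = Field(default_factory=list)
    case_control: Optional[CaseControlResult] = None
    ps1: Optional[Ps1Comparison] = None
    curator_overrides: list[EvidenceItem] = Field(default_factory=list)


def evaluate_bundle(
    bundle: AnnotationBundle,
    tx: Optional[TranscriptModel] = None,
    dm: Optional[DomainMap] = None,
    constants: Optional[RuleConstants] = None,
    matrix: Optional[RestrictionMatrix] = None,
) -> tuple[EvidenceProfile, Classification]:
    """Derive, validate and combine all evidence codes for one bundle."""
    tx = tx or load_atm_transcript()
    dm = dm or load_atm_domain_map()
    constants = constants or load_default_constants()

    items: list[EvidenceItem] = []
    warnings: list[str] = []

    if bundle.population is not None:
        pop_item = evaluate_population_codes(bundle.population, constants)
        if pop_item is not None:
            items.append(pop_item)

    if bundle.lof is not None:
        lof_items, lof_warnings = pvs1_items(bundle.lof, tx, dm, constants)
        items.extend(lof_items)
        warnings.extend(lof_warnings)

    if bundle.rna_assay is not None:
        rna_item = rna_evidence(bundle.rna_assay)
        if rna_item is not None:
            items.append(rna_item)

    if bundle.scores is not None:
        calls = []
        protein_scored = bundle.consequence in (
            Consequence.missense,
            Consequence.inframe_indel,
            Consequence.stop_loss,
        ) and (bundle.scores.revel is not None or bundle.scores.provean is not None)
        if protein_scored:
            calls.append(pp3_bp4_protein(bundle.scores, constants))
        if not bundle.canonical_dinucleotide and bundle.scores.spliceai is not None:
            calls.append(pp3_bp4_splice(bundle.scores, constants))
        merged, merge_warnings = merge_pp3_bp4(calls)
        warnings.extend(merge_warnings)
        if merged is not None:
            items.append(merged)

    has_bp4 = any(i.code_id == "BP4" for i in items)
    if bundle.location is not None and has_bp4 and bp7_eligible(bundle.location, constants):
        items.append(make_item("BP7", provenance="synonymous/deep-intronic with BP4 met"))

    pm4 = pm4_stop_loss(bundle.consequence.value)
    if pm4 is not None:
        items.append(pm4)

    if bundle.ps1 is not None:
        ps1 = ps1_item(bundle.ps1)
        if ps1 is not None:
            items.append(ps1)

    probands = [o for o in bundle.observations if o.at_affected]
    carriers = [o for o in bundle.observations if o.adult_unaffected]
    pm3 = pm3_aggregate(probands, constants) if probands else None
    if pm3 is not None:
        items.append(pm3)
    bp2 = bp2_aggregate(carriers, constants) if carriers else None
    if bp2 is not None:
        items.append(bp2)

    if bundle.case_control is not None:
        ps4 = ps4_case_control(bundle.case_control, constants)
        if ps4 is not None:
            items.append(ps4)

    ps3_bs3 = ps3_bs3_combine(bundle.kinase_assay, bundle.radiosensitivity_assay)
    if ps3_bs3 is not None:
        items.append(ps3_bs3)

    for override in bundle.curator_overrides:
        items = [
            i
            for i in items
            if not (i.code_id == override.code_id and i.rna_flag == override.rna_flag)
        ]
        items.append(override)

    profile = validate_profile(items, matrix, variant_id=bundle.variant_id)
    profile.warnings[:0] = warnings
    return profile, classify(profile)
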