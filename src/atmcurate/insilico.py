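"""Computational/predictive evidence: PP3/BP4, BP7 eligibility, PS1, PM4.

Protein impact uses REVEL for single-nucleotide variants (damaging at
>= 0.733, neutral at <= 0.249) and PROVEAN for small in-frame indels; splice
impact uses SpliceAI (PP3 at >= 0.2 for non-canonical variants, BP4 at
<= 0.1).  BP7 extends the synonymous rule to deep-intronic positions beyond
(but not including) +7 at the donor and -40 at the acceptor, and is applied
only together with BP4.  PS1 is the splice-hotspot table: weight depends on
where the comparison (likely) pathogenic variant sits relative to the
variant under assessment and on the predictive code each carries.
"""

from __future__ import annotations

import enum
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field

from .lof import SpliceSite
from .model import EvidenceItem, RuleConstants, StrengthLevel, make_item


class PredictionScores(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    revel: Optional[float] = Field(default=None, ge=0, le=1)
    spliceai: Optional[float] = Field(default=None, ge=0, le=1)
    provean: Optional[float] = None


def pp3_bp4_protein(
    scores: PredictionScores, constants: RuleConstants
) -> Optional[EvidenceItem]:
    """PP3/BP4 from the protein predictor (REVEL; PROVEAN for in-frame indels)."""
    if scores.revel is not None:
        if scores.revel >= constants.revel_hi:
            return make_item("PP3", provenance=f"REVEL {scores.revel:g} (protein)")
        if scores.revel <= constants.revel_lo:
            return make_item("BP4", provenance=f"REVEL {scores.revel:g} (protein)")
        return None
    if scores.provean is not None:
        if scores.provean <= constants.provean_deleterious_cutoff:
            return make_item("PP3", provenance=f"PROVEAN {scores.provean:g} (in-frame indel)")
        return None
    return None


def pp3_bp4_splice(
    scores: PredictionScores, constants: RuleConstants
) -> Optional[EvidenceItem]:
    """PP3/BP4 from SpliceAI, for variants outside the canonical dinucleotides."""
    if scores.spliceai is None:
        return None
    if scores.spliceai >= constants.spliceai_hi:
        return make_item("PP3", provenance=f"SpliceAI {scores.spliceai:g} (splice)")
    if scores.spliceai <= constants.spliceai_lo:
        return make_item("BP4", provenance=f"SpliceAI {scores.spliceai:g} (splice)")
    return None


def merge_pp3_bp4(
    calls: Sequence[Optional[EvidenceItem]],
) -> tuple[Optional[EvidenceItem], list[str]]:
    """Combine per-mechanism PP3/BP4 calls into a single per-variant item.

    ACMG codes are per-variant, not per-mechanism: a damaging prediction for
    either mechanism yields PP3 (provenance records which), while BP4
    requires every scored mechanism to call benign — an intermediate score
    for one mechanism blocks BP4.  A ``None`` entry means the mechanism was
    scored but landed between the thresholds.
    """
    present = [c for c in calls if c is not None]
    pp3 = [c for c in present if c.code_id == "PP3"]
    if pp3:
        merged = make_item("PP3", provenance="; ".join(c.provenance for c in pp3))
        warnings = []
        if len(present) > len(pp3):
            warnings.append(
                "benign prediction for the other mechanism not applied "
                "(damaging call dominates)"
            )
        return merged, warnings
    if calls and present and len(present) == len(list(calls)):
        merged = make_item("BP4", provenance="; ".join(c.provenance for c in present))
        return merged, []
    return None, []


class VariantLocation(BaseModel):
    """Position class for BP7: synonymous exonic, or intronic offset from a
    donor/acceptor site (donor offsets positive, acceptor negative)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    synonymous_exonic: bool = False
    site: Optional[SpliceSite] = None
    offset: Optional[int] = None


def bp7_eligible(
    location: VariantLocation, constants: Optional[RuleConstants] = None
) -> bool:
    """Positional eligibility for BP7 (the caller must also require BP4)."""
    constants = constants or RuleConstants()
    if location.synonymous_exonic:
        return True
    if location.site is None or location.offset is None:
        return False
    if location.site is SpliceSite.donor:
        return location.offset > constants.bp7_donor_min_offset
    return location.offset < constants.bp7_acceptor_min_offset


class Ps1Relation(str, enum.Enum):
    same_nucleotide = "same_nucleotide"
    same_motif = "same_motif"
    same_dinucleotide = "same_dinucleotide"
    same_region_outside_dinucleotide = "same_region_outside_dinucleotide"


class Ps1Baseline(str, enum.Enum):
    PP3 = "PP3"
    PVS1 = "PVS1"
    PVS1_strong_or_lower = "PVS1_strong_or_lower"


class Ps1Comparison(BaseModel):
    """Relation between the variant under assessment (VUA) and a classified
    comparison variant with the same predicted splicing event."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    vua_at_canonical_dinucleotide: bool
    vua_baseline_code: Ps1Baseline
    relation: Ps1Relation
    comparison_classification: str  # "pathogenic" or "likely_pathogenic"


# (at_dinucleotide, baseline, relation, comparison) -> strength
_PS1_TABLE: dict[tuple[bool, Ps1Baseline, Ps1Relation, str], Optional[StrengthLevel]] = {
    (False, Ps1Baseline.PP3, Ps1Relation.same_nucleotide, "pathogenic"): StrengthLevel.strong,
    (False, Ps1Baseline.PP3, Ps1Relation.same_nucleotide, "likely_pathogenic"): StrengthLevel.moderate,
    (False, Ps1Baseline.PP3, Ps1Relation.same_motif, "pathogenic"): StrengthLevel.moderate,
    (False, Ps1Baseline.PP3, Ps1Relation.same_motif, "likely_pathogenic"): StrengthLevel.supporting,
    (True, Ps1Baseline.PVS1, Ps1Relation.same_dinucleotide, "pathogenic"): StrengthLevel.supporting,
    (True, Ps1Baseline.PVS1, Ps1Relation.same_dinucleotide, "likely_pathogenic"): None,
    (True, Ps1Baseline.PVS1, Ps1Relation.same_region_outside_dinucleotide, "pathogenic"): StrengthLevel.supporting,
    (True, Ps1Baseline.PVS1, Ps1Relation.same_region_outside_dinucleotide, "likely_pathogenic"): StrengthLevel.supporting,
    (True, Ps1Baseline.PVS1_strong_or_lower, Ps1Relation.same_dinucleotide, "pathogenic"): StrengthLevel.strong,
    (True, Ps1Baseline.PVS1_strong_or_lower, Ps1Relation.same_dinucleotide, "likely_pathogenic"): None,
    (True, Ps1Baseline.PVS1_strong_or_lower, Ps1Relation.same_region_outside_dinucleotide, "pathogenic"): StrengthLevel.moderate,
    (True, Ps1Baseline.PVS1_strong_or_lower, Ps1Relation.same_region_outside_dinucleotide, "likely_pathogenic"): StrengthLevel.supporting,
}


def ps1_weight(c: Ps1Comparison) -> Optional[StrengthLevel]:
    """PS1 strength for a splice-hotspot comparison, or None when no weight
    applies; raises for relations illegal for the position class."""
    key = (
        c.vua_at_canonical_dinucleotide,
        c.vua_baseline_code,
        c.relation,
        c.comparison_classification,
    )
    if key not in _PS1_TABLE:
        raise ValueError(
            f"relation {c.relation.value!r} is not legal for this position class "
            f"(baseline {c.vua_baseline_code.value})"
        )
    return _PS1_TABLE[key]


def ps1_item(c: Ps1Comparison) -> Optional[EvidenceItem]:
    strength = ps1_weight(c)
    if strength is None:
        return None
    return make_item(
        "PS1",
        strength,
        provenance=f"splice hotspot: {c.relation.value}, "
        f"{c.comparison_classification} comparison",
    )


def pm4_stop_loss(consequence: str) -> Optional[EvidenceItem]:
    """PM4 for stop-loss variants (in-frame indels carry no PM4 for ATM)."""
    if consequence == "stop_loss":
        return make_item("PM4", provenance="stop-loss variant")
    return None
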