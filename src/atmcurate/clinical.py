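"""Phenotype and functional-assay evidence: PM3, BP2, PS4, PS3/BS3.

PM3 scores unrelated A-T probands carrying the variant together with a
second ATM allele.  Points depend on the confidence of the A-T phenotype
(``confident``/``consistent``) and on the phase/identity of the second
variant; points add across probands and the cumulative total maps to a
strength (0.5 supporting / 1 moderate / 2 strong / 4 very strong).

BP2 scores unaffected adults with the variant homozygous or biallelic with
a known pathogenic allele; points are negative, lab reports weigh twice
database reports, the homozygous subtotal is capped at -2 (a hypomorphic
allele can hide behind mild homozygotes) and the overall total at -4
(BP2_Strong).

PS4 gates a case-control result (OR >= 2, p < 0.05, lower 95% CI > 1.5).
PS3/BS3 combine an ATM-specific kinase assay with a radiosensitivity assay:
concordant non-functional results reach PS3_Moderate, kinase-only
non-functional PS3_Supporting, radiosensitivity alone carries no weight,
and discordant results cancel.  Concordant functional (normal) results give
BS3 at moderate weight, counted downstream as two supporting benign lines.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .model import EvidenceItem, RuleConstants, StrengthLevel, make_item


class PhenotypeTier(str, enum.Enum):
    confident = "confident"
    consistent = "consistent"


class OtherVariantClass(str, enum.Enum):
    pathogenic_or_LP = "pathogenic_or_LP"
    VUS = "VUS"
    unidentified = "unidentified"


class Phase(str, enum.Enum):
    confirmed_in_trans = "confirmed_in_trans"
    phase_unknown = "phase_unknown"
    homozygous = "homozygous"


class Source(str, enum.Enum):
    clinical_laboratory = "clinical_laboratory"
    database = "database"


class ObservationRecord(BaseModel):
    """One biallelic observation: an A-T proband (PM3) or an unaffected
    adult carrier (BP2)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    proband_id: str
    at_affected: bool = False
    adult_unaffected: bool = False
    phenotype_tier: Optional[PhenotypeTier] = None
    other_variant_class: OtherVariantClass = OtherVariantClass.unidentified
    phase: Phase = Phase.phase_unknown
    source: Source = Source.clinical_laboratory

    @model_validator(mode="after")
    def _consistency(self) -> "ObservationRecord":
        if self.at_affected and self.adult_unaffected:
            raise ValueError("a record cannot be both A-T affected and unaffected")
        if self.at_affected and self.phenotype_tier is None:
            raise ValueError("phenotype_tier is required for A-T probands")
        return self


def _pm3_column(o: ObservationRecord) -> str:
    if o.phase is Phase.homozygous:
        return "homozygous"
    if o.other_variant_class is not OtherVariantClass.pathogenic_or_LP:
        return "vus_or_unidentified"
    if o.phase is Phase.confirmed_in_trans:
        return "confirmed_in_trans"
    return "phase_unknown"


def pm3_observation_points(
    o: ObservationRecord, constants: Optional[RuleConstants] = None
) -> float:
    """Points contributed by one unrelated A-T proband."""
    constants = constants or RuleConstants()
    if not o.at_affected:
        raise ValueError("PM3 points require an A-T affected proband")
    if o.phenotype_tier is None:
        raise ValueError("phenotype_tier is required for PM3 scoring")
    return constants.pm3_point_table[o.phenotype_tier.value][_pm3_column(o)]


def _breaks_to_strength(
    total: float, breaks: dict[str, float]
) -> Optional[StrengthLevel]:
    for name in ("very_strong", "strong", "moderate", "supporting"):
        if name in breaks and total >= breaks[name]:
            return StrengthLevel(name)
    return None


def pm3_aggregate(
    observations: list[ObservationRecord], constants: Optional[RuleConstants] = None
) -> Optional[EvidenceItem]:
    """Additive PM3 points over probands, mapped to a final strength."""
    constants = constants or RuleConstants()
    total = sum(pm3_observation_points(o, constants) for o in observations)
    strength = _breaks_to_strength(total, constants.pm3_strength_breaks)
    if strength is None:
        return None
    return make_item(
        "PM3", strength, provenance=f"{total:g} points from {len(observations)} proband(s)"
    )


def bp2_observation_points(
    o: ObservationRecord, constants: Optional[RuleConstants] = None
) -> float:
    """Negative points contributed by one unaffected adult carrier."""
    constants = constants or RuleConstants()
    if o.at_affected:
        raise ValueError("BP2 points require an unaffected adult, not an A-T proband")
    if not o.adult_unaffected:
        return 0.0
    qualifies = (
        o.phase is Phase.homozygous
        or o.other_variant_class is OtherVariantClass.pathogenic_or_LP
    )
    if not qualifies:
        return 0.0
    column = "homozygous" if o.phase is Phase.homozygous else o.phase.value
    return constants.bp2_point_table[o.source.value][column]


def bp2_aggregate(
    observations: list[ObservationRecord], constants: Optional[RuleConstants] = None
) -> Optional[EvidenceItem]:
    """BP2 with the homozygous subtotal capped at -2 and the total at -4.

    A moderate-level total (two points) is emitted as a moderate-strength
    benign item, which the combiner counts as two supporting lines.
    """
    constants = constants or RuleConstants()
    homozygous = sum(
        bp2_observation_points(o, constants)
        for o in observations
        if o.phase is Phase.homozygous
    )
    others = sum(
        bp2_observation_points(o, constants)
        for o in observations
        if o.phase is not Phase.homozygous
    )
    homozygous = max(homozygous, constants.bp2_homozygous_cap)
    total = max(homozygous + others, constants.bp2_total_cap)
    strength = _breaks_to_strength(abs(total), constants.bp2_strength_breaks)
    if strength is None:
        return None
    return make_item(
        "BP2",
        strength,
        provenance=f"{total:g} points from {len(observations)} unaffected carrier(s)",
    )


class CaseControlResult(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    odds_ratio: float
    p_value: float
    ci_lower: float

    @model_validator(mode="after")
    def _positive(self) -> "CaseControlResult":
        if self.odds_ratio <= 0 or self.ci_lower <= 0 or not (0 <= self.p_value <= 1):
            raise ValueError("case-control statistics must be positive and finite")
        return self


def ps4_case_control(
    r: CaseControlResult, constants: Optional[RuleConstants] = None
) -> Optional[EvidenceItem]:
    """PS4 (strong) when the case-control gates pass."""
    constants = constants or RuleConstants()
    significant = r.p_value < constants.ps4_p_max
    or_pass = r.odds_ratio >= constants.ps4_or_min
    ci_pass = r.ci_lower > constants.ps4_ci_low_min
    effect_pass = (or_pass or ci_pass) if constants.ps4_disjunctive else (or_pass and ci_pass)
    if significant and effect_pass:
        return make_item(
            "PS4",
            provenance=f"OR {r.odds_ratio:g}, p {r.p_value:g}, CI low {r.ci_lower:g}",
        )
    return None


class AssayVerdict(str, enum.Enum):
    nonfunctional = "nonfunctional"
    functional = "functional"
    unavailable = "unavailable"


def ps3_bs3_combine(
    kinase: AssayVerdict, radiosensitivity: AssayVerdict
) -> Optional[EvidenceItem]:
    """Combine the ATM-specific kinase assay with the radiosensitivity assay."""
    k, r = kinase, radiosensitivity
    if k is AssayVerdict.nonfunctional and r is AssayVerdict.nonfunctional:
        return make_item(
            "PS3", StrengthLevel.moderate, provenance="kinase + radiosensitivity non-functional"
        )
    if k is AssayVerdict.nonfunctional and r is AssayVerdict.unavailable:
        return make_item(
            "PS3", StrengthLevel.supporting, provenance="kinase assay non-functional"
        )
    if k is AssayVerdict.functional and r is AssayVerdict.functional:
        # moderate does not exist on the benign side of the 2015 scheme;
        # counted by the combiner as two supporting benign lines
        return make_item(
            "BS3", StrengthLevel.moderate, provenance="kinase + radiosensitivity normal"
        )
    if (k is AssayVerdict.functional) != (r is AssayVerdict.functional) and (
        AssayVerdict.unavailable in (k, r)
    ):
        which = "kinase" if k is AssayVerdict.functional else "radiosensitivity"
        return make_item(
            "BS3", StrengthLevel.supporting, provenance=f"{which} assay normal"
        )
    return None
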