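"""PVS1 decision tree over the five loss-of-function variant categories.

Categories: initiation-codon, nonsense/frameshift, single-to-multi exon
deletions, single-to-multi exon duplications, and canonical (+/-1,2) splice
variants including eligible last-nucleotide substitutions.  The weight is
driven by

1. predicted nonsense-mediated decay (NMD; the 50-nt rule, configurable),
2. which functional domain an NMD-escaping product damages (FATKIN losses
   are Very_Strong, N-Solenoid-only losses Strong),
3. eligibility boundaries: premature stops after the last critical residue
   (p.Arg3047) carry no weight, and early stops before the first alternate
   in-frame methionine (p.Met94) stay fully eligible, and
4. splice-specific special cases (+2T>C without predicted impact, the
   atypical native c.7515+2 site, in-frame alternate-site rescue scored by
   PROVEAN, last-nucleotide weights one level below the matched +1/2 weight).

RNA assay observations enter separately: an observed deleterious splice
defect becomes PVS1(RNA) at curator-weighted strength and supplants the
predictive codes; observed normal splicing becomes BP7(RNA).

PM5_Supporting is co-applied with PVS1/PVS1(RNA) at Very_Strong for
PTC-producing variants strictly upstream of the last critical residue —
such products are at least as severe as the most C-terminal pathogenic
nonsense variant.
"""

from __future__ import annotations

import enum
import re
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model import (
    DomainMap,
    EvidenceItem,
    RuleConstants,
    StrengthLevel,
    TranscriptModel,
    make_item,
    one_level_below,
)


class LofCategory(str, enum.Enum):
    initiation_codon = "initiation_codon"
    nonsense = "nonsense"
    frameshift = "frameshift"
    exon_deletion = "exon_deletion"
    exon_duplication = "exon_duplication"
    canonical_splice = "canonical_splice"
    last_nucleotide = "last_nucleotide"


class SpliceSite(str, enum.Enum):
    donor = "donor"
    acceptor = "acceptor"


class PredictedEvent(str, enum.Enum):
    exon_skip = "exon_skip"
    cryptic_site = "cryptic_site"
    intron_retention = "intron_retention"
    none = "none"


class AffectedDomain(str, enum.Enum):
    n_solenoid = "n_solenoid"
    fatkin = "fatkin"
    both = "both"
    none = "none"


class TandemStatus(str, enum.Enum):
    confirmed = "confirmed"
    presumed = "presumed"
    unknown = "unknown"


class LofVariant(BaseModel):
    """Annotations of one PVS1-eligible variant (category-dependent fields)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    category: LofCategory
    ptc_aa: Optional[int] = Field(default=None, ge=1)
    exon_span: Optional[tuple[int, int]] = None
    tandem_status: Optional[TandemStatus] = None
    involves_utr: bool = False
    splice_site: Optional[SpliceSite] = None
    intron_offset: Optional[int] = None
    native_donor_context: Optional[str] = None
    predicted_event: Optional[PredictedEvent] = None
    event_in_frame: Optional[bool] = None
    affected_domain: Optional[AffectedDomain] = None
    nmd_predicted: Optional[bool] = None
    spliceai: Optional[float] = Field(default=None, ge=0, le=1)
    provean: Optional[float] = None
    alt_base: Optional[str] = None
    special_site_id: Optional[str] = None


class RnaEffect(str, enum.Enum):
    deleterious_splice_defect = "deleterious_splice_defect"
    no_aberrant_splicing = "no_aberrant_splicing"
    inconclusive = "inconclusive"


class RnaAssayResult(BaseModel):
    """Curator verdict on an RNA splicing assay with a quality weight."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    effect: RnaEffect
    quality_weight: StrengthLevel = StrengthLevel.strong

    @model_validator(mode="after")
    def _bounds(self) -> "RnaAssayResult":
        if self.quality_weight not in (
            StrengthLevel.supporting,
            StrengthLevel.moderate,
            StrengthLevel.strong,
            StrengthLevel.very_strong,
        ):
            raise ValueError("quality_weight must be supporting..very_strong")
        if (
            self.effect is RnaEffect.no_aberrant_splicing
            and self.quality_weight > StrengthLevel.strong
        ):
            raise ValueError("BP7(RNA) quality weight is capped at strong")
        return self


class PVS1Result(BaseModel):
    model_config = ConfigDict(frozen=True)

    strength: StrengthLevel
    pm5_supporting: bool = False
    warnings: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# reading-frame arithmetic


def exon_event_frame(tx: TranscriptModel, span: tuple[int, int]) -> str:
    """``"in_frame"`` iff the summed coding length of the exon span is a
    multiple of three (equivalently: start phase of the first exon equals the
    end phase of the last), else ``"frameshift"``."""
    exons = tx.exon_span_slice(*span)
    total = sum(e.coding_length_nt for e in exons)
    return "in_frame" if total % 3 == 0 else "frameshift"


def _truncation_domain(dm: DomainMap, first_lost_aa: int) -> AffectedDomain:
    """Domain adversely affected by losing residues from ``first_lost_aa`` on."""
    if first_lost_aa <= dm.n_solenoid[1]:
        return AffectedDomain.both
    return AffectedDomain.fatkin


def _interval_domain(dm: DomainMap, aa_start: int, aa_end: int) -> AffectedDomain:
    in_nsol = aa_start <= dm.n_solenoid[1]
    in_fatkin = aa_end >= dm.fatkin[0]
    if in_nsol and in_fatkin:
        return AffectedDomain.both
    if in_fatkin:
        return AffectedDomain.fatkin
    if in_nsol:
        return AffectedDomain.n_solenoid
    return AffectedDomain.none


def _domain_strength(domain: AffectedDomain) -> StrengthLevel:
    """NMD-escaping / in-frame weight by damaged domain."""
    if domain in (AffectedDomain.fatkin, AffectedDomain.both):
        return StrengthLevel.very_strong
    if domain is AffectedDomain.n_solenoid:
        return StrengthLevel.strong
    return StrengthLevel.none


# ---------------------------------------------------------------------------
# category handlers


def pvs1_ptc(
    v: LofVariant, tx: TranscriptModel, dm: DomainMap, constants: RuleConstants
) -> PVS1Result:
    """Nonsense/frameshift weight from the premature-stop position."""
    if v.category not in (LofCategory.nonsense, LofCategory.frameshift):
        raise ValueError(f"pvs1_ptc does not handle category {v.category.value}")
    if v.ptc_aa is None:
        raise ValueError("ptc_aa is required for nonsense/frameshift variants")
    if v.ptc_aa > dm.last_critical_aa:
        return PVS1Result(
            strength=StrengthLevel.none,
            warnings=(
                f"PTC at codon {v.ptc_aa} lies downstream of the last critical "
                f"amino acid ({dm.last_critical_aa}); not PVS1 eligible",
            ),
        )
    cds_pos = (v.ptc_aa - 1) * 3 + 1
    if v.nmd_predicted if v.nmd_predicted is not None else tx.nmd_predicted(
        cds_pos, constants.nmd_window_nt
    ):
        strength = StrengthLevel.very_strong
    else:
        strength = _domain_strength(_truncation_domain(dm, v.ptc_aa))
        # any truncation at or before the last critical residue removes part
        # of the critical window, so NMD-escaping stops stay very strong
        if v.ptc_aa <= dm.critical_window[1]:
            strength = StrengthLevel.very_strong
    pm5 = strength is StrengthLevel.very_strong and v.ptc_aa < dm.last_critical_aa
    return PVS1Result(strength=strength, pm5_supporting=pm5)


def pvs1_exon_cnv(
    v: LofVariant, tx: TranscriptModel, dm: DomainMap, constants: RuleConstants
) -> PVS1Result:
    """Gross (>=1 exon) deletion / duplication weight."""
    if v.category not in (LofCategory.exon_deletion, LofCategory.exon_duplication):
        raise ValueError(f"pvs1_exon_cnv does not handle category {v.category.value}")
    if v.exon_span is None:
        raise ValueError("exon_span is required for gross deletions/duplications")
    frame = (
        ("in_frame" if v.event_in_frame else "frameshift")
        if v.event_in_frame is not None
        else exon_event_frame(tx, v.exon_span)
    )
    aa_start, aa_end = tx.span_aa_interval(*v.exon_span)
    domain = v.affected_domain or _interval_domain(dm, aa_start, aa_end)

    if v.category is LofCategory.exon_deletion:
        if frame == "frameshift":
            junction_pos = tx.cds_offset_before(v.exon_span[0]) + 1
            includes_last = v.exon_span[1] == tx.exons[-1].index
            nmd = (
                v.nmd_predicted
                if v.nmd_predicted is not None
                else (not includes_last)
                and tx.nmd_predicted(junction_pos, constants.nmd_window_nt)
            )
            if nmd:
                return PVS1Result(strength=StrengthLevel.very_strong, pm5_supporting=True)
            return PVS1Result(strength=_domain_strength(_truncation_domain(dm, aa_start)))
        return PVS1Result(strength=_domain_strength(domain))

    # duplication
    if v.tandem_status is None:
        raise ValueError("tandem_status is required for gross duplications")
    if v.involves_utr:
        return PVS1Result(
            strength=StrengthLevel.none,
            warnings=("duplication involves a UTR; not PVS1 eligible",),
        )
    if v.tandem_status is TandemStatus.unknown:
        return PVS1Result(
            strength=StrengthLevel.none,
            warnings=("tandem status unknown; no PVS1 weight for the duplication",),
        )
    if domain in (AffectedDomain.both, AffectedDomain.none):
        return PVS1Result(
            strength=StrengthLevel.none,
            warnings=(
                "duplication breakpoints do not both lie within one functional "
                "domain; neither domain is disrupted",
            ),
        )
    confirmed = v.tandem_status is TandemStatus.confirmed
    if frame == "frameshift":
        # tandem frameshifting duplication behaves like an NMD-prone frameshift
        return PVS1Result(
            strength=StrengthLevel.very_strong if confirmed else StrengthLevel.strong
        )
    if domain is AffectedDomain.fatkin:
        return PVS1Result(
            strength=StrengthLevel.very_strong if confirmed else StrengthLevel.strong
        )
    return PVS1Result(
        strength=StrengthLevel.strong if confirmed else StrengthLevel.moderate
    )


_DONOR_CONSENSUS = re.compile(r"^G GT [AG]{2} GT$".replace(" ", ""), re.IGNORECASE)


def donor_conforms_consensus(context: str) -> bool:
    """Check a 7-base native donor context (exon last base + 6 intronic bases)
    against the U2 consensus Ggtrrgt (r = purine)."""
    if len(context) != 7:
        raise ValueError("native donor context must be 7 bases")
    return _DONOR_CONSENSUS.match(context) is not None


def _splice_baseline(
    v: LofVariant, tx: TranscriptModel, dm: DomainMap, constants: RuleConstants
) -> PVS1Result:
    """Weight of the predicted transcript event, before any last-nucleotide
    reduction: the same NMD/domain logic used for direct PTCs, plus the
    in-frame alternate-site PROVEAN branch."""
    warnings: list[str] = []
    if v.special_site_id == "c.7515+2":
        # atypical native C at +2: a C>T substitution restores the consensus
        return PVS1Result(
            strength=StrengthLevel.none,
            warnings=("c.7515+2 has a native cytosine; C>T improves the splice site",),
        )
    if (
        v.splice_site is SpliceSite.donor
        and v.intron_offset == 2
        and (v.alt_base or "").upper() == "C"
        and (v.spliceai is None or v.spliceai < constants.spliceai_hi)
    ):
        return PVS1Result(
            strength=StrengthLevel.none,
            warnings=("+2T>C without a predicted splice impact; no PVS1 weight",),
        )
    if v.predicted_event is None:
        raise ValueError("predicted_event is required for canonical splice variants")
    if v.predicted_event is PredictedEvent.none:
        return PVS1Result(
            strength=StrengthLevel.none,
            warnings=("no predicted splice event; no PVS1 weight",),
        )
    if v.event_in_frame is None:
        if v.exon_span is not None and v.predicted_event is PredictedEvent.exon_skip:
            in_frame = exon_event_frame(tx, v.exon_span) == "in_frame"
        else:
            raise ValueError("event_in_frame is required for the predicted event")
    else:
        in_frame = v.event_in_frame

    if in_frame:
        if v.predicted_event is PredictedEvent.cryptic_site and v.provean is not None:
            if v.provean <= constants.provean_deleterious_cutoff:
                return PVS1Result(strength=StrengthLevel.supporting)
            return PVS1Result(
                strength=StrengthLevel.none,
                warnings=("in-frame alternate splice site with benign PROVEAN score",),
            )
        domain = v.affected_domain
        if domain is None:
            if v.exon_span is None:
                raise ValueError("affected_domain or exon_span required for in-frame event")
            domain = _interval_domain(dm, *tx.span_aa_interval(*v.exon_span))
        return PVS1Result(strength=_domain_strength(domain), warnings=tuple(warnings))

    # frameshift event
    nmd = v.nmd_predicted
    if nmd is None:
        if v.exon_span is not None:
            junction_pos = tx.cds_offset_before(v.exon_span[0]) + 1
            nmd = tx.nmd_predicted(junction_pos, constants.nmd_window_nt)
        else:
            nmd = True  # canonical-splice frameshifts are NMD-prone by default
    if nmd:
        return PVS1Result(strength=StrengthLevel.very_strong, warnings=tuple(warnings))
    domain = v.affected_domain
    if domain is None:
        if v.exon_span is None:
            raise ValueError("affected_domain or exon_span required for NMD-escaping event")
        aa_start, _ = tx.span_aa_interval(*v.exon_span)
        domain = _truncation_domain(dm, aa_start)
    return PVS1Result(strength=_domain_strength(domain), warnings=tuple(warnings))


def pvs1_splice(
    v: LofVariant, tx: TranscriptModel, dm: DomainMap, constants: RuleConstants
) -> PVS1Result:
    """Canonical +/-1,2 and last-nucleotide splice weight.

    Last-nucleotide substitutions take the weight of the matched +1/2 variant
    reduced by one strength level; the native donor context is checked
    against the Ggtrrgt consensus and recorded as a warning (a conforming
    donor suggests a weaker splicing impact).
    """
    if v.category not in (LofCategory.canonical_splice, LofCategory.last_nucleotide):
        raise ValueError(f"pvs1_splice does not handle category {v.category.value}")
    if v.splice_site is None:
        raise ValueError("splice_site is required for splice variants")
    baseline = _splice_baseline(v, tx, dm, constants)
    if v.category is LofCategory.canonical_splice:
        return baseline

    warnings = list(baseline.warnings)
    if v.native_donor_context is not None:
        if donor_conforms_consensus(v.native_donor_context):
            warnings.append(
                "native donor conforms to the Ggtrrgt consensus; a last-nucleotide "
                "substitution may have a weaker splicing impact"
            )
    if baseline.strength is StrengthLevel.none:
        return PVS1Result(strength=StrengthLevel.none, warnings=tuple(warnings))
    return PVS1Result(
        strength=one_level_below(baseline.strength), warnings=tuple(warnings)
    )


def pvs1_initiation(v: LofVariant) -> PVS1Result:
    """Initiation-codon variants: Very_Strong (no rescue from p.Met94)."""
    if v.category is not LofCategory.initiation_codon:
        raise ValueError(f"pvs1_initiation does not handle category {v.category.value}")
    return PVS1Result(strength=StrengthLevel.very_strong)


def evaluate_pvs1(
    v: LofVariant,
    tx: TranscriptModel,
    dm: DomainMap,
    constants: RuleConstants,
) -> PVS1Result:
    """Dispatch to the single category handler for this variant."""
    if v.category is LofCategory.initiation_codon:
        return pvs1_initiation(v)
    if v.category in (LofCategory.nonsense, LofCategory.frameshift):
        return pvs1_ptc(v, tx, dm, constants)
    if v.category in (LofCategory.exon_deletion, LofCategory.exon_duplication):
        return pvs1_exon_cnv(v, tx, dm, constants)
    return pvs1_splice(v, tx, dm, constants)


def pvs1_items(
    v: LofVariant,
    tx: TranscriptModel,
    dm: DomainMap,
    constants: RuleConstants,
) -> tuple[list[EvidenceItem], list[str]]:
    """Evidence items (PVS1 at the computed weight, plus PM5_Supporting when
    co-applicable) and any warnings."""
    res = evaluate_pvs1(v, tx, dm, constants)
    items: list[EvidenceItem] = []
    if res.strength is not StrengthLevel.none:
        items.append(
            make_item("PVS1", res.strength, provenance=f"category {v.category.value}")
        )
        if res.pm5_supporting:
            items.append(
                make_item(
                    "PM5",
                    StrengthLevel.supporting,
                    provenance="PTC upstream of the last critical residue with "
                    "PVS1 at very strong",
                )
            )
    return items, list(res.warnings)


def rna_evidence(r: RnaAssayResult) -> Optional[EvidenceItem]:
    """PVS1(RNA) / BP7(RNA) from an RNA assay verdict, at curator weight."""
    if r.effect is RnaEffect.deleterious_splice_defect:
        return make_item(
            "PVS1", r.quality_weight, provenance="RNA assay: deleterious splice defect",
            rna_flag=True,
        )
    if r.effect is RnaEffect.no_aberrant_splicing:
        return make_item(
            "BP7", r.quality_weight, provenance="RNA assay: no aberrant splicing",
            rna_flag=True,
        )
    return None
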