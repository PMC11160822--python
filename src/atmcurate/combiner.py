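"""Code-combination validation and five-tier classification.

``validate_profile`` enforces the pairwise co-application restrictions
(PVS1 and PP3 may not combine, an observed RNA defect supplants the
predictive codes, BP4 and BP7 may combine, ...), repairing violations by
dropping the weaker member and recording a warning.

``classify`` applies the 2015 ACMG/AMP categorical combining rules with the
two ATM-specific modifications: a very-strong line plus one supporting line
reaches likely pathogenic, and a single strong benign line suffices for
likely benign.  Moderate-level benign items (BS3/BP2 at moderate) count as
two supporting benign lines.  Evidence in both directions yields uncertain
— except that PM2_Supporting never blocks a benign outcome, and BP7 never
conflicts with a body of evidence for a pathogenic splice defect.

``classify_points`` is an independent Tavtigian-style point cross-check
(supporting 1, moderate 2, strong 4, very strong 8; benign negative;
pathogenic at >= 10 points, likely pathogenic at 6–9, likely benign at
-1..-6, benign at <= -7).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

from .model import (
    ADOPTED_CODES,
    Classification,
    Direction,
    EvidenceItem,
    EvidenceProfile,
    RuleConstants,
    StrengthLevel,
)

_DATA_DIR = Path(__file__).parent / "data"

#: codes that never conflict with a benign body of evidence
NON_CONFLICTING_WITH_BENIGN = frozenset({"PM2"})


def _matrix_key(item: EvidenceItem) -> str:
    code = item.code_id.upper()
    if code in ("PS3", "BS3"):
        return "PS3|BS3"
    return code + ("(RNA)" if item.rna_flag else "")


class RestrictionMatrix:
    """Symmetric pairwise co-application constraints between evidence codes.

    Statuses: ``allowed``, ``forbidden``, ``not_applicable``.  Pairs absent
    from the matrix are unrestricted.
    """

    def __init__(self, pairs: dict[frozenset[str], str]):
        self._pairs = pairs

    @classmethod
    def from_dict(cls, data: dict) -> "RestrictionMatrix":
        pairs: dict[frozenset[str], str] = {}
        rank = {"forbidden": 2, "allowed": 1, "not_applicable": 0}
        for entry in data["pairs"]:
            key = frozenset((entry["a"], entry["b"]))
            status = entry["status"]
            # forbidden dominates on conflicting duplicate entries
            if key in pairs and rank[pairs[key]] >= rank[status]:
                continue
            pairs[key] = status
        return cls(pairs)

    @classmethod
    def load_default(cls) -> "RestrictionMatrix":
        return cls.from_dict(json.loads((_DATA_DIR / "restriction_matrix.json").read_text()))

    def status(self, a: EvidenceItem, b: EvidenceItem) -> str:
        key = frozenset((_matrix_key(a), _matrix_key(b)))
        if len(key) == 1:  # diagonal not consulted
            return "not_applicable"
        return self._pairs.get(key, "not_applicable")

    def forbidden(self, a: EvidenceItem, b: EvidenceItem) -> bool:
        return self.status(a, b) == "forbidden"


def _drop_order_key(item: EvidenceItem) -> tuple:
    # the member to drop sorts first: lower strength, then benign direction
    return (
        item.strength.rank,
        0 if item.direction is Direction.benign else 1,
        item.code_id,
        item.rna_flag,
    )


def validate_profile(
    items: Iterable[EvidenceItem],
    matrix: Optional[RestrictionMatrix] = None,
    variant_id: str = "",
) -> EvidenceProfile:
    """Repair a set of applied codes into a matrix-consistent profile.

    Always succeeds; every dropped item leaves a warning.  Idempotent.
    """
    matrix = matrix or RestrictionMatrix.load_default()
    kept = list(items)
    warnings: list[str] = []

    if any(i.code_id == "PVS1" and i.rna_flag for i in kept):
        supplanted = [
            i
            for i in kept
            if (i.code_id in ("PVS1", "PP3", "BP4", "BP7") and not i.rna_flag)
        ]
        for i in supplanted:
            warnings.append(
                f"{i.display} supplanted by the observed RNA splice defect (PVS1(RNA))"
            )
        kept = [i for i in kept if i not in supplanted]

    changed = True
    while changed:
        changed = False
        for a in sorted(kept, key=_drop_order_key):
            partner = next(
                (b for b in kept if b is not a and matrix.forbidden(a, b)), None
            )
            if partner is not None:
                kept.remove(a)
                warnings.append(
                    f"{a.display} dropped: may not be combined with {partner.display}"
                )
                changed = True
                break

    for i in kept:
        if i.code_id not in ADOPTED_CODES:
            warnings.append(
                f"{i.code_id} is not a VCEP-adopted code for ATM; "
                "counted at its annotated strength"
            )

    return EvidenceProfile(
        variant_id=variant_id, items=kept, warnings=warnings, validated=True
    )


def _split(profile: EvidenceProfile):
    path = [i for i in profile.items if i.direction is Direction.pathogenic]
    benign = [i for i in profile.items if i.direction is Direction.benign]
    return path, benign


def _has_splice_defect_evidence(path_items: list[EvidenceItem]) -> bool:
    return any(i.code_id == "PVS1" for i in path_items)


def _conflicting_sides(path_items, benign_items):
    path_c = [i for i in path_items if i.code_id not in NON_CONFLICTING_WITH_BENIGN]
    benign_c = benign_items
    if _has_splice_defect_evidence(path_items):
        benign_c = [i for i in benign_c if not (i.code_id == "BP7" and not i.rna_flag)]
    return bool(path_c) and bool(benign_c)


def _pathogenic_tier(path_items: list[EvidenceItem]) -> Classification:
    vs = sum(1 for i in path_items if i.strength is StrengthLevel.very_strong)
    s = sum(1 for i in path_items if i.strength is StrengthLevel.strong)
    m = sum(1 for i in path_items if i.strength is StrengthLevel.moderate)
    p = sum(1 for i in path_items if i.strength is StrengthLevel.supporting)

    if (
        vs >= 2
        or (vs >= 1 and (s >= 1 or m >= 2 or (m >= 1 and p >= 1) or p >= 2))
        or s >= 2
        or (s >= 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)))
    ):
        return Classification.pathogenic
    if (
        (vs >= 1 and (m >= 1 or p >= 1))
        or (s == 1 and 1 <= m <= 2)
        or (s >= 1 and p >= 2)
        or m >= 3
        or (m == 2 and p >= 2)
        or (m == 1 and p >= 4)
    ):
        return Classification.likely_pathogenic
    return Classification.uncertain


def _benign_tier(benign_items: list[EvidenceItem]) -> Classification:
    if any(i.strength is StrengthLevel.stand_alone for i in benign_items):
        return Classification.benign
    strong = sum(1 for i in benign_items if i.strength is StrengthLevel.strong)
    # moderate benign items count as two supporting lines
    supporting = sum(1 for i in benign_items if i.strength is StrengthLevel.supporting)
    supporting += 2 * sum(1 for i in benign_items if i.strength is StrengthLevel.moderate)
    if strong >= 2:
        return Classification.benign
    if strong == 1 or supporting >= 2:
        return Classification.likely_benign
    return Classification.uncertain


def classify(profile: EvidenceProfile) -> Classification:
    """Five-tier classification from a validated profile."""
    if not profile.validated:
        raise ValueError("profile must pass validate_profile before classification")
    path_items, benign_items = _split(profile)
    if _conflicting_sides(path_items, benign_items):
        return Classification.uncertain
    if benign_items:
        tier = _benign_tier(benign_items)
        if tier is not Classification.uncertain:
            return tier
    if path_items:
        return _pathogenic_tier(path_items)
    return Classification.uncertain


def evidence_points(profile: EvidenceProfile, constants: RuleConstants) -> float:
    """Signed point total (stand-alone BA1 excluded; it forces benign)."""
    total = 0.0
    for i in profile.items:
        if i.strength is StrengthLevel.stand_alone:
            continue
        pts = constants.strength_points[i.strength.value]
        total += pts if i.direction is Direction.pathogenic else -pts
    return total


def classify_points(
    profile: EvidenceProfile, constants: Optional[RuleConstants] = None
) -> Classification:
    """Point-based cross-check of :func:`classify` on the Tavtigian scale."""
    if not profile.validated:
        raise ValueError("profile must pass validate_profile before classification")
    constants = constants or RuleConstants()
    path_items, benign_items = _split(profile)
    if _conflicting_sides(path_items, benign_items):
        return Classification.uncertain
    if any(i.strength is StrengthLevel.stand_alone for i in benign_items):
        return Classification.benign
    total = evidence_points(profile, constants)
    if total >= constants.point_tier_pathogenic_min:
        return Classification.pathogenic
    if total >= constants.point_tier_likely_pathogenic_min:
        return Classification.likely_pathogenic
    if total <= constants.point_tier_benign_max:
        return Classification.benign
    if total <= constants.point_tier_likely_benign_max:
        return Classification.likely_benign
    return Classification.uncertain
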