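"""Core domain types for the ATM ACMG/AMP rules engine.

The engine represents each applied ACMG/AMP criterion as an
:class:`EvidenceItem` (code id, direction, strength), collects the items for
one variant into an :class:`EvidenceProfile`, and resolves the profile into a
five-tier :class:`Classification`.  Every numeric threshold and point value
used anywhere in the engine lives in :class:`RuleConstants` so that a single
versioned configuration document defines the rule set.

Transcript-level reading-frame arithmetic (gross deletions/duplications,
nonsense-mediated-decay prediction) runs against a :class:`TranscriptModel`,
an exon table with coding lengths and phases, plus a :class:`DomainMap`
locating the N-Solenoid and FATKIN functional domains of the protein.
"""

from __future__ import annotations

import enum
import json
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

_DATA_DIR = Path(__file__).parent / "data"


class StrengthLevel(str, enum.Enum):
    """ACMG/AMP evidence strength, totally ordered.

    ``stand_alone > very_strong > strong > moderate > supporting > none``.
    ``stand_alone`` is reserved for BA1; ``none`` means no weight.
    """

    stand_alone = "stand_alone"
    very_strong = "very_strong"
    strong = "strong"
    moderate = "moderate"
    supporting = "supporting"
    none = "none"

    @property
    def rank(self) -> int:
        return _STRENGTH_RANK[self]

    def __lt__(self, other: "StrengthLevel") -> bool:  # type: ignore[override]
        return self.rank < other.rank

    def __le__(self, other: "StrengthLevel") -> bool:  # type: ignore[override]
        return self.rank <= other.rank

    def __gt__(self, other: "StrengthLevel") -> bool:  # type: ignore[override]
        return self.rank > other.rank

    def __ge__(self, other: "StrengthLevel") -> bool:  # type: ignore[override]
        return self.rank >= other.rank


_STRENGTH_RANK = {
    StrengthLevel.none: 0,
    StrengthLevel.supporting: 1,
    StrengthLevel.moderate: 2,
    StrengthLevel.strong: 3,
    StrengthLevel.very_strong: 4,
    StrengthLevel.stand_alone: 5,
}
_RANK_STRENGTH = {v: k for k, v in _STRENGTH_RANK.items()}


def compare_strength(a: StrengthLevel, b: StrengthLevel) -> int:
    """Total-order comparison: negative if ``a < b``, 0 if equal, positive if ``a > b``."""
    return a.rank - b.rank


def one_level_below(level: StrengthLevel) -> StrengthLevel:
    """The adjacent lower strength level; below supporting is ``none``.

    ``none`` has no level below it.
    """
    if level is StrengthLevel.none:
        raise ValueError("no strength level below 'none'")
    return _RANK_STRENGTH[level.rank - 1]


class Direction(str, enum.Enum):
    pathogenic = "pathogenic"
    benign = "benign"


class Classification(str, enum.Enum):
    """The five-tier ACMG/AMP classification."""

    pathogenic = "pathogenic"
    likely_pathogenic = "likely_pathogenic"
    uncertain = "uncertain"
    likely_benign = "likely_benign"
    benign = "benign"


#: Default direction for each ACMG/AMP code family, keyed by code prefix.
_BENIGN_PREFIXES = ("BA", "BS", "BP")

#: Default (unmodified) strength per code family.
_DEFAULT_STRENGTH_BY_PREFIX = {
    "PVS": StrengthLevel.very_strong,
    "PS": StrengthLevel.strong,
    "PM": StrengthLevel.moderate,
    "PP": StrengthLevel.supporting,
    "BA": StrengthLevel.stand_alone,
    "BS": StrengthLevel.strong,
    "BP": StrengthLevel.supporting,
}

#: Codes the HBOP VCEP adopted for ATM.  Non-adopted codes appearing in an
#: input profile are accepted and counted, with a warning.
ADOPTED_CODES = frozenset(
    {
        "PVS1", "PS1", "PS3", "PS4", "PM2", "PM3", "PM4", "PM5",
        "PP3", "BA1", "BS1", "BS3", "BP2", "BP4", "BP7",
    }
)


def code_direction(code_id: str) -> Direction:
    """Direction implied by the code family (BA/BS/BP benign, rest pathogenic)."""
    for prefix in _BENIGN_PREFIXES:
        if code_id.upper().startswith(prefix):
            return Direction.benign
    return Direction.pathogenic


def default_strength(code_id: str) -> StrengthLevel:
    """Unmodified ACMG/AMP strength for a code id (PVS very strong, PS/BS strong...)."""
    cid = code_id.upper()
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if cid.startswith(prefix):
            return _DEFAULT_STRENGTH_BY_PREFIX[prefix]
    raise ValueError(f"unrecognized ACMG/AMP code id: {code_id!r}")


class EvidenceItem(BaseModel):
    """One applied ACMG/AMP criterion with its direction and strength.

    ``rna_flag`` distinguishes the RNA-observation variants of a code —
    PVS1(RNA) and BP7(RNA) — from their predictive counterparts.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    code_id: str
    direction: Direction
    strength: StrengthLevel
    provenance: str = ""
    rna_flag: bool = False

    @model_validator(mode="after")
    def _check_strength(self) -> "EvidenceItem":
        if self.direction is Direction.benign and self.strength is StrengthLevel.very_strong:
            raise ValueError("benign-direction items never carry very_strong")
        if self.strength is StrengthLevel.stand_alone and self.code_id.upper() != "BA1":
            raise ValueError("stand_alone strength is reserved for BA1")
        if self.strength is StrengthLevel.none:
            raise ValueError("items with no weight are omitted, not carried")
        return self

    @property
    def display(self) -> str:
        suffix = "" if self.strength == default_strength(self.code_id) else f"_{self.strength.value}"
        rna = "(RNA)" if self.rna_flag else ""
        return f"{self.code_id}{rna}{suffix}"


class EvidenceProfile(BaseModel):
    """The set of evidence items applied to one variant."""

    model_config = ConfigDict(extra="forbid")

    variant_id: str
    items: list[EvidenceItem] = Field(default_factory=list)
    warnings: list[str] = Field(default_factory=list)
    validated: bool = False

    @field_validator("items")
    @classmethod
    def _unique_codes(cls, items: list[EvidenceItem]) -> list[EvidenceItem]:
        seen = [(i.code_id, i.rna_flag) for i in items]
        if len(seen) != len(set(seen)):
            raise ValueError("duplicate evidence code in profile")
        return items


class Exon(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    index: int
    coding_length_nt: int = Field(ge=0)
    start_phase: int = Field(ge=0, le=2)
    end_phase: int = Field(ge=0, le=2)

    @model_validator(mode="after")
    def _phase_arithmetic(self) -> "Exon":
        if (self.start_phase + self.coding_length_nt) % 3 != self.end_phase:
            raise ValueError(
                f"exon {self.index}: end_phase must equal (start_phase + length) mod 3"
            )
        return self


class TranscriptModel(BaseModel):
    """Coding-exon table with phases, for reading-frame and NMD arithmetic.

    Exon phases chain: the end phase of exon *i* equals the start phase of
    exon *i+1*.  When ``complete`` the coding lengths sum to
    ``3 * (protein_length_aa + 1)`` (stop codon included).
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    exons: list[Exon]
    protein_length_aa: int = Field(gt=0)
    complete: bool = True
    schema_version: str = "1"

    @model_validator(mode="after")
    def _chain_and_total(self) -> "TranscriptModel":
        if not self.exons:
            raise ValueError("transcript requires at least one coding exon")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end_phase != b.start_phase:
                raise ValueError(
                    f"phase chain broken between exons {a.index} and {b.index}"
                )
        if self.exons[0].start_phase != 0:
            raise ValueError("first coding exon must start in phase 0")
        if self.complete:
            total = sum(e.coding_length_nt for e in self.exons)
            expected = 3 * (self.protein_length_aa + 1)
            if total != expected:
                raise ValueError(
                    f"coding length {total} != 3*(protein_length_aa+1) = {expected}"
                )
        return self

    # -- coordinate helpers -------------------------------------------------

    @property
    def cds_length(self) -> int:
        return sum(e.coding_length_nt for e in self.exons)

    def _exon_positions(self) -> dict[int, int]:
        return {e.index: i for i, e in enumerate(self.exons)}

    def exon_span_slice(self, first: int, last: int) -> list[Exon]:
        pos = self._exon_positions()
        if first not in pos or last not in pos or pos[first] > pos[last]:
            raise ValueError(f"exon span [{first}, {last}] outside transcript {self.name}")
        return self.exons[pos[first] : pos[last] + 1]

    def cds_offset_before(self, exon_index: int) -> int:
        """Total coding nucleotides upstream of the given exon."""
        pos = self._exon_positions()
        if exon_index not in pos:
            raise ValueError(f"exon {exon_index} outside transcript {self.name}")
        return sum(e.coding_length_nt for e in self.exons[: pos[exon_index]])

    def span_aa_interval(self, first: int, last: int) -> tuple[int, int]:
        """Closed 1-based amino-acid interval touched by an exon span."""
        span = self.exon_span_slice(first, last)
        start_nt = self.cds_offset_before(first) + 1
        end_nt = start_nt - 1 + sum(e.coding_length_nt for e in span)
        aa_start = (start_nt - 1) // 3 + 1
        aa_end = (end_nt - 1) // 3 + 1
        return aa_start, min(aa_end, self.protein_length_aa)

    def nmd_predicted(self, cds_pos: int, window_nt: int = 50) -> bool:
        """Standard 50-nt rule: a PTC escapes NMD when it lies in the last
        exon or within ``window_nt`` upstream of the final exon–exon junction."""
        if len(self.exons) == 1:
            return False
        boundary = self.cds_length - self.exons[-1].coding_length_nt - window_nt
        return cds_pos <= boundary


class DomainMap(BaseModel):
    """Protein-domain coordinates (closed, 1-based amino-acid intervals).

    For ATM the N-Solenoid spans aa 1–1892 and the FATKIN domain the
    remainder; the critical window p.Leu2980–p.Arg3047 holds the most
    C-terminal residues whose loss is known to abolish kinase function, with
    p.Arg3047 the last critical amino acid.  The alternate-start window
    covers Met1 up to the next in-frame methionine (p.Met94), shown unable to
    rescue translation.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    protein_length_aa: int = 3056
    n_solenoid: tuple[int, int] = (1, 1892)
    fatkin: tuple[int, int] = (1893, 3056)
    critical_window: tuple[int, int] = (2980, 3047)
    last_critical_aa: int = 3047
    alt_start_window: tuple[int, int] = (1, 94)

    @model_validator(mode="after")
    def _partition(self) -> "DomainMap":
        if self.n_solenoid[0] != 1 or self.fatkin[1] != self.protein_length_aa:
            raise ValueError("n_solenoid and fatkin must span the protein")
        if self.n_solenoid[1] + 1 != self.fatkin[0]:
            raise ValueError("n_solenoid and fatkin must partition the protein")
        return self


class RuleConstants(BaseModel):
    """Every tunable threshold and point value of the ATM rule set.

    Allele-frequency thresholds are fractions (BA1 0.5% -> 0.005).  BA1/BS1
    trigger on strictly-greater comparisons, PM2_Supporting on
    less-than-or-equal, following the published inequalities.
    """

    model_config = ConfigDict(extra="forbid")

    schema_version: str = "1"

    # population frequency
    ba1_af: float = 0.005
    bs1_af: float = 0.0005
    pm2_af: float = 0.00001

    # in silico predictors
    revel_hi: float = 0.733
    revel_lo: float = 0.249
    spliceai_hi: float = 0.2
    spliceai_lo: float = 0.1
    provean_deleterious_cutoff: float = -2.5

    # BP7 deep-intronic eligibility (exclusive bounds)
    bp7_donor_min_offset: int = 7
    bp7_acceptor_min_offset: int = -40

    # PS4 case-control gates
    ps4_or_min: float = 2.0
    ps4_p_max: float = 0.05
    ps4_ci_low_min: float = 1.5
    ps4_disjunctive: bool = False  # alternative reading: OR>=2 OR CI_low>=1.5

    # PM3 / BP2 biallelic point scoring
    pm3_point_table: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "confident": {
                "confirmed_in_trans": 4.0,
                "phase_unknown": 2.0,
                "vus_or_unidentified": 1.0,
                "homozygous": 2.0,
            },
            "consistent": {
                "confirmed_in_trans": 2.0,
                "phase_unknown": 1.0,
                "vus_or_unidentified": 0.5,
                "homozygous": 1.0,
            },
        }
    )
    pm3_strength_breaks: dict[str, float] = Field(
        default_factory=lambda: {
            "very_strong": 4.0,
            "strong": 2.0,
            "moderate": 1.0,
            "supporting": 0.5,
        }
    )
    bp2_point_table: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "clinical_laboratory": {
                "confirmed_in_trans": -1.0,
                "phase_unknown": -0.5,
                "homozygous": -1.0,
            },
            "database": {
                "confirmed_in_trans": -0.5,
                "phase_unknown": -0.25,
                "homozygous": -0.5,
            },
        }
    )
    bp2_strength_breaks: dict[str, float] = Field(
        default_factory=lambda: {"strong": 4.0, "moderate": 2.0, "supporting": 1.0}
    )
    bp2_homozygous_cap: float = -2.0
    bp2_total_cap: float = -4.0

    # NMD prediction
    nmd_window_nt: int = 50

    # point-based cross-check (Tavtigian-style scale)
    strength_points: dict[str, float] = Field(
        default_factory=lambda: {
            "supporting": 1.0,
            "moderate": 2.0,
            "strong": 4.0,
            "very_strong": 8.0,
        }
    )
    point_tier_pathogenic_min: float = 10.0
    point_tier_likely_pathogenic_min: float = 6.0
    point_tier_likely_benign_max: float = -1.0
    point_tier_benign_max: float = -7.0

    @model_validator(mode="after")
    def _ordering(self) -> "RuleConstants":
        if not (self.ba1_af > self.bs1_af > self.pm2_af):
            raise ValueError("require ba1_af > bs1_af > pm2_af")
        return self

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RuleConstants":
        return cls.model_validate_json(text)


def load_default_constants() -> RuleConstants:
    """Packaged rule constants (the ATM defaults)."""
    return RuleConstants.from_json((_DATA_DIR / "rule_constants.json").read_text())


def load_atm_transcript() -> TranscriptModel:
    """Packaged ATM transcript document.

    The exon coding lengths in the packaged document are a synthetic
    stand-in with the correct exon count (62 coding exons), total coding
    length (9171 nt) and protein length (3056 aa); see the document itself.
    """
    return TranscriptModel.model_validate_json(
        (_DATA_DIR / "atm_transcript_synthetic.json").read_text()
    )


def load_atm_domain_map() -> DomainMap:
    return DomainMap()


def make_item(
    code_id: str,
    strength: Optional[StrengthLevel] = None,
    *,
    provenance: str = "",
    rna_flag: bool = False,
) -> EvidenceItem:
    """Build an :class:`EvidenceItem` with family-default direction/strength."""
    return EvidenceItem(
        code_id=code_id.upper(),
        direction=code_direction(code_id),
        strength=strength if strength is not None else default_strength(code_id),
        provenance=provenance,
        rna_flag=rna_flag,
    )


def parse_code_token(token: str) -> EvidenceItem:
    """Parse a curation token like ``PVS1``, ``PM3_very-strong`` or ``BP2_strong``.

    The optional suffix overrides the family-default strength; hyphens and
    case are normalized (``PM3_Very-Strong`` == ``PM3_very_strong``).
    An ``(RNA)`` marker after the code id sets the RNA flag.
    """
    tok = token.strip()
    if not tok:
        raise ValueError("empty evidence-code token")
    rna = False
    if "(RNA)" in tok.upper():
        rna = True
        i = tok.upper().index("(RNA)")
        tok = tok[:i] + tok[i + 5 :]
    parts = tok.split("_", 1)
    code = parts[0].upper()
    strength = None
    if len(parts) == 2:
        suffix = parts[1].lower().replace("-", "_")
        try:
            strength = StrengthLevel(suffix)
        except ValueError as exc:
            raise ValueError(f"unrecognized strength suffix in token {token!r}") from exc
    return make_item(code, strength, rna_flag=rna)


def serialize_json(obj: BaseModel, path: Path | str) -> None:
    Path(path).write_text(obj.model_dump_json(indent=2) + "\n")


def load_json(cls: type[BaseModel], path: Path | str):
    return cls.model_validate(json.loads(Path(path).read_text()))
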