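"""Readers and writers: the packaged pilot fixture, annotation bundles
(JSON / flat TSV / a minimal VCF dialect) and classification reports.

The pilot fixture stores the 33 published pilot variants at the evidence
level (variant id, type, the applied curation codes and the expert panel's
final classification); running it end to end through profile validation and
the combiner is the engine's primary regression surface.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict

from .combiner import RestrictionMatrix, classify, validate_profile
from .insilico import PredictionScores, VariantLocation
from .lof import SpliceSite
from .model import (
    Classification,
    EvidenceItem,
    EvidenceProfile,
    parse_code_token,
)
from .pipeline import AnnotationBundle, Consequence
from .population import PopulationData, Subpopulation

_DATA_DIR = Path(__file__).parent / "data"
PILOT_FIXTURE_PATH = _DATA_DIR / "pilot_variants.tsv"

_CLASSIFICATION_LABELS = {
    "pathogenic": Classification.pathogenic,
    "likely pathogenic": Classification.likely_pathogenic,
    "uncertain significance": Classification.uncertain,
    "likely benign": Classification.likely_benign,
    "benign": Classification.benign,
}

CLASSIFICATION_DISPLAY = {
    Classification.pathogenic: "Pathogenic",
    Classification.likely_pathogenic: "Likely pathogenic",
    Classification.uncertain: "Uncertain significance",
    Classification.likely_benign: "Likely benign",
    Classification.benign: "Benign",
}


def parse_classification_label(label: str) -> Classification:
    key = label.strip().lower()
    if key not in _CLASSIFICATION_LABELS:
        raise ValueError(f"unrecognized classification label {label!r}")
    return _CLASSIFICATION_LABELS[key]


class PilotFixtureRow(BaseModel):
    model_config = ConfigDict(frozen=True)

    variant_id: str
    variant_type: str
    clinvar_classification: str
    applied_codes: tuple[EvidenceItem, ...]
    expected_classification: Classification


def load_pilot_fixture(path: Optional[Path] = None) -> list[PilotFixtureRow]:
    """The packaged pilot table: 33 rows of applied codes and expected tiers."""
    path = path or PILOT_FIXTURE_PATH
    df = pd.read_csv(path, sep="\t", dtype=str)
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(
            PilotFixtureRow(
                variant_id=rec.variant_id,
                variant_type=rec.variant_type,
                clinvar_classification=rec.clinvar_classification,
                applied_codes=tuple(
                    parse_code_token(tok) for tok in rec.applied_codes.split(";")
                ),
                expected_classification=parse_classification_label(
                    rec.expected_classification
                ),
            )
        )
    return rows


def run_pilot(
    matrix: Optional[RestrictionMatrix] = None,
    path: Optional[Path] = None,
) -> pd.DataFrame:
    """Classify every pilot profile; one row per variant with the expected
    and computed tiers."""
    records = []
    for row in load_pilot_fixture(path):
        profile = validate_profile(
            list(row.applied_codes), matrix, variant_id=row.variant_id
        )
        computed = classify(profile)
        records.append(
            {
                "variant_id": row.variant_id,
                "variant_type": row.variant_type,
                "applied_codes": ";".join(i.display for i in row.applied_codes),
                "expected": CLASSIFICATION_DISPLAY[row.expected_classification],
                "computed": CLASSIFICATION_DISPLAY[computed],
                "match": computed is row.expected_classification,
            }
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# annotation bundles


class BundleReadError(BaseModel):
    model_config = ConfigDict(frozen=True)

    record: str
    message: str


def _bundle_from_flat(rec: dict) -> AnnotationBundle:
    """Build a bundle from one flat TSV row (population + scores + location)."""

    def _get(key, cast=str):
        val = rec.get(key)
        if val is None or (isinstance(val, float) and pd.isna(val)) or val == "":
            return None
        return cast(val)

    kwargs: dict = {
        "variant_id": rec["variant_id"],
        "consequence": Consequence(_get("consequence") or "other"),
    }
    af = _get("filtering_af", float)
    point_af = _get("point_af", float)
    if af is not None or point_af is not None:
        kwargs["population"] = PopulationData(
            subpops=[
                Subpopulation(
                    name=_get("subpop") or "pooled",
                    filtering_af=af,
                    point_af=point_af,
                    allele_count=int(_get("allele_count", float) or 0),
                    underrepresented=bool(int(_get("underrepresented", float) or 0)),
                )
            ]
        )
    revel = _get("revel", float)
    spliceai = _get("spliceai", float)
    provean = _get("provean", float)
    if any(s is not None for s in (revel, spliceai, provean)):
        kwargs["scores"] = PredictionScores(revel=revel, spliceai=spliceai, provean=provean)
    if _get("canonical_dinucleotide") is not None:
        kwargs["canonical_dinucleotide"] = bool(int(float(rec["canonical_dinucleotide"])))
    site = _get("splice_site")
    offset = _get("intron_offset", float)
    if kwargs["consequence"] is Consequence.synonymous:
        kwargs["location"] = VariantLocation(synonymous_exonic=True)
    elif site is not None and offset is not None:
        kwargs["location"] = VariantLocation(
            site=SpliceSite(site), offset=int(offset)
        )
    return AnnotationBundle(**kwargs)


# INFO keys of the minimal VCF dialect mapped onto bundle fields
_VCF_INFO_KEYS = ("CONSEQ", "REVEL", "SPLICEAI", "PROVEAN", "FAF", "AC", "SUBPOP")


def _bundles_from_vcf(path: Path) -> Iterable[dict]:
    """Parse the documented VCF dialect into flat records.

    Plain-text, single-sample-free VCF; only the declared INFO keys are
    interpreted, 1-based coordinates are carried as labels only.
    """
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"malformed VCF line: {line[:60]!r}")
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            info = {}
            for entry in fields[7].split(";"):
                if "=" in entry:
                    k, v = entry.split("=", 1)
                    info[k] = v
            rec: dict = {
                "variant_id": vid if vid != "." else f"{chrom}:{pos}{ref}>{alt}",
            }
            if "CONSEQ" in info:
                rec["consequence"] = info["CONSEQ"]
            if "REVEL" in info:
                rec["revel"] = float(info["REVEL"])
            if "SPLICEAI" in info:
                rec["spliceai"] = float(info["SPLICEAI"])
            if "PROVEAN" in info:
                rec["provean"] = float(info["PROVEAN"])
            if "FAF" in info:
                rec["filtering_af"] = float(info["FAF"])
            if "AC" in info:
                rec["allele_count"] = float(info["AC"])
            if "SUBPOP" in info:
                rec["subpop"] = info["SUBPOP"]
            yield rec


def read_bundles(
    path: Path | str,
    format: str = "json",
    fail_fast: bool = False,
) -> tuple[list[AnnotationBundle], list[BundleReadError]]:
    """Read annotation bundles, collecting per-record errors.

    Formats: ``json`` (a list of full bundle objects), ``tsv`` (one flat row
    per variant) and ``vcf_dialect`` (documented INFO keys only).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    bundles: list[AnnotationBundle] = []
    errors: list[BundleReadError] = []

    def _collect(label: str, build):
        try:
            bundles.append(build())
        except Exception as exc:  # noqa: BLE001 - collected per record
            if fail_fast:
                raise
            errors.append(BundleReadError(record=label, message=str(exc)))

    if format == "json":
        text = path.read_text().strip()
        raw = json.loads(text) if text else []
        for i, entry in enumerate(raw):
            _collect(
                str(entry.get("variant_id", f"record {i}")),
                lambda entry=entry: AnnotationBundle.model_validate(entry),
            )
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for rec in df.to_dict(orient="records"):
            _collect(str(rec.get("variant_id", "?")), lambda rec=rec: _bundle_from_flat(rec))
    elif format == "vcf_dialect":
        for rec in _bundles_from_vcf(path):
            _collect(rec["variant_id"], lambda rec=rec: _bundle_from_flat(rec))
    else:
        raise ValueError(f"unknown bundle format {format!r}")
    return bundles, errors


# ---------------------------------------------------------------------------
# reports


def write_report(
    results: list[tuple[EvidenceProfile, Classification]],
    path: Path | str,
    format: str = "tsv",
) -> None:
    """One row per variant: id, applied codes with strengths, warnings,
    classification.  Output is byte-stable for identical inputs."""
    path = Path(path)
    if format == "tsv":
        lines = ["variant_id\tapplied_codes\twarnings\tclassification"]
        for profile, tier in results:
            codes = ";".join(i.display for i in profile.items)
            warnings = "|".join(profile.warnings)
            lines.append(
                f"{profile.variant_id}\t{codes}\t{warnings}\t{CLASSIFICATION_DISPLAY[tier]}"
            )
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        payload = [
            {
                "variant_id": profile.variant_id,
                "items": [
                    {
                        "code_id": i.code_id,
                        "direction": i.direction.value,
                        "strength": i.strength.value,
                        "rna_flag": i.rna_flag,
                        "provenance": i.provenance,
                    }
                    for i in profile.items
                ],
                "warnings": list(profile.warnings),
                "classification": tier.value,
            }
            for profile, tier in results
        ]
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report_json(path: Path | str) -> list[dict]:
    return json.loads(Path(path).read_text())
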