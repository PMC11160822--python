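"""Population-frequency evidence: BA1, BS1, PM2_Supporting.

Also implements the maximum-credible-allele-frequency calculator
(Whiffin/Ware style) that the VCEP used to derive the BA1/BS1 thresholds:

* dominant:  ``prevalence * genetic_het * allelic_het / (2 * penetrance)``
* recessive: ``sqrt(prevalence * genetic_het / penetrance) * allelic_het``

For the operational codes, BA1 (>0.5%) and BS1 (>0.05%) trigger on the
maximum sub-population frequency, strictly greater than the threshold;
PM2_Supporting requires every sub-population at or below 0.001% — or a
single carrier overall in an under-represented sub-population.  The
filtering allele frequency is preferred over the point estimate whenever it
is supplied.
"""

from __future__ import annotations

import enum
import math
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model import Direction, EvidenceItem, RuleConstants, StrengthLevel, make_item


class Inheritance(str, enum.Enum):
    dominant = "dominant"
    recessive = "recessive"


class CredibleAfParams(BaseModel):
    """Inputs to the maximum-credible-allele-frequency calculation."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    inheritance: Inheritance
    prevalence: float = Field(gt=0, lt=1)
    genetic_heterogeneity: float = Field(gt=0, le=1)
    allelic_heterogeneity: float = Field(gt=0, le=1)
    penetrance: float = Field(gt=0, le=1)


def max_credible_af(params: CredibleAfParams) -> float:
    """Maximum credible population allele frequency (a fraction).

    Monotone increasing in prevalence and both heterogeneities, monotone
    decreasing in penetrance, for both inheritance modes.
    """
    if params.inheritance is Inheritance.dominant:
        return (
            params.prevalence
            * params.genetic_heterogeneity
            * params.allelic_heterogeneity
            / (2.0 * params.penetrance)
        )
    return (
        math.sqrt(params.prevalence * params.genetic_heterogeneity / params.penetrance)
        * params.allelic_heterogeneity
    )


class Subpopulation(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    name: str
    filtering_af: Optional[float] = Field(default=None, ge=0, le=1)
    point_af: Optional[float] = Field(default=None, ge=0, le=1)
    allele_count: int = Field(default=0, ge=0)
    underrepresented: bool = False

    @model_validator(mode="after")
    def _af_present_when_observed(self) -> "Subpopulation":
        if self.allele_count > 0 and self.filtering_af is None and self.point_af is None:
            raise ValueError(
                f"subpopulation {self.name!r}: an allele frequency is required "
                "when allele_count > 0"
            )
        return self

    @property
    def frequency(self) -> float:
        """Filtering AF where present, point estimate otherwise, 0 if absent."""
        if self.filtering_af is not None:
            return self.filtering_af
        if self.point_af is not None:
            return self.point_af
        return 0.0


class PopulationData(BaseModel):
    model_config = ConfigDict(extra="forbid")

    subpops: list[Subpopulation]

    @model_validator(mode="after")
    def _non_empty(self) -> "PopulationData":
        if not self.subpops:
            raise ValueError("population data requires at least one subpopulation")
        return self


def evaluate_population_codes(
    pop: PopulationData, constants: RuleConstants
) -> Optional[EvidenceItem]:
    """BA1, BS1 or PM2_Supporting from sub-population frequencies (or None).

    Returns at most one item; BA1 and PM2_Supporting are mutually exclusive
    by construction (a frequency above 0.5% in some subpopulation cannot be
    at or below 0.001% everywhere unless the single-carrier exception fires,
    which requires a total allele count of one).
    """
    freqs = [s.frequency for s in pop.subpops]
    max_af = max(freqs)
    if max_af > constants.ba1_af:
        return make_item("BA1", provenance=f"max subpopulation AF {max_af:g} > {constants.ba1_af:g}")
    if max_af > constants.bs1_af:
        return make_item(
            "BS1", provenance=f"max subpopulation AF {max_af:g} > {constants.bs1_af:g}"
        )
    total_count = sum(s.allele_count for s in pop.subpops)
    if all(f <= constants.pm2_af for f in freqs):
        return make_item(
            "PM2",
            StrengthLevel.supporting,
            provenance=f"all subpopulation AFs <= {constants.pm2_af:g}",
        )
    if total_count == 1 and any(
        s.underrepresented and s.allele_count == 1 for s in pop.subpops
    ):
        return make_item(
            "PM2",
            StrengthLevel.supporting,
            provenance="single carrier in an under-represented subpopulation",
        )
    return None
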