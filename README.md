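# atmcurate

A deterministic rules engine for clinical classification of germline *ATM*
variants under the gene-specific ACMG/AMP criteria defined by the ClinGen
Hereditary Breast, Ovarian and Pancreatic Cancer (HBOP) Variant Curation
Expert Panel (VCEP).

*ATM* is unusual among hereditary-cancer genes: heterozygous loss-of-function
variants confer a roughly two-fold breast-cancer risk (penetrance ~20%),
while biallelic pathogenic variants cause the autosomal recessive disease
Ataxia Telangiectasia (A-T). The VCEP rule set leverages both conditions —
population frequency thresholds from the dominant condition, biallelic
proband/carrier evidence from the recessive one — and `atmcurate` turns that
rule set into testable code for variant curators and clinical-bioinformatics
pipelines.

## What the engine computes

**Evidence-code assignment** from structured per-variant annotations:

- *Population* — BA1 (allele frequency > 0.5%), BS1 (> 0.05%),
  PM2_Supporting (≤ 0.001% in every subpopulation, or a single carrier in an
  under-represented subpopulation). The thresholds derive from the maximum
  credible allele frequency for a dominant condition,

      AF_max = prevalence × g × a / (2 × penetrance),

  and for a recessive condition,

      AF_max = sqrt(prevalence × g / penetrance) × a,

  with genetic heterogeneity *g* and allelic heterogeneity *a*; the
  calculator is included (`max_credible_af`).
- *Loss of function* — the full PVS1 decision tree over five categories
  (initiation codon, nonsense/frameshift, exon deletions, exon duplications,
  canonical ±1,2 and last-nucleotide splice variants), driven by
  reading-frame arithmetic over an exon/phase transcript model,
  nonsense-mediated-decay prediction (50-nt rule), the N-Solenoid (aa
  1–1892) / FATKIN (aa 1893–3056) domain map, the p.Arg3047 eligibility
  boundary, and the *ATM*-specific splice special cases. Observed RNA
  defects enter as PVS1(RNA)/BP7(RNA) and supplant the predictive codes.
  PM5_Supporting co-applies to Very_Strong premature-termination variants
  upstream of p.Arg3047.
- *In silico* — PP3/BP4 from REVEL (≥ 0.733 / ≤ 0.249), SpliceAI
  (≥ 0.2 / ≤ 0.1) and PROVEAN; BP7 for synonymous and deep-intronic
  positions (beyond +7 donor / −40 acceptor, applied only with BP4); the
  PS1 splice-hotspot weight table; PM4 for stop-loss.
- *Clinical* — PM3 additive point scoring over A-T probands
  (confident/consistent phenotype × phase of the second allele, breaks
  0.5/1/2/4 → Supporting/Moderate/Strong/Very Strong); BP2 negative points
  over unaffected adult biallelic carriers with the −2 homozygous and −4
  total caps; PS4 case-control gates (OR ≥ 2, p < 0.05, lower CI > 1.5);
  PS3/BS3 combination of kinase and radiosensitivity assays.

**Combination** — pairwise co-application restrictions (e.g. PVS1 × PP3
forbidden, BP4 × BP7 allowed) repaired with warnings, then the 2015
categorical combining rules plus the two VCEP modifications (PVS1 + one
supporting line → Likely Pathogenic; one strong benign line → Likely
Benign), with the documented non-conflict exemptions (PM2_Supporting never
blocks a benign outcome; BP7 never conflicts with splice-defect evidence).
A Tavtigian-style point tally (Supporting 1 / Moderate 2 / Strong 4 / Very
Strong 8; Pathogenic ≥ 10, Likely Pathogenic 6–9, Likely Benign −1..−6,
Benign ≤ −7) is provided as an independent cross-check.

## Worked example

```python
from atmcurate import (AnnotationBundle, PopulationData, Subpopulation,
                       LofVariant, evaluate_bundle)

bundle = AnnotationBundle(
    variant_id="ATM:c.1442T>G (p.Leu481Ter)",
    consequence="nonsense",
    population=PopulationData(subpops=[Subpopulation(name="pooled", allele_count=0)]),
    lof=LofVariant(category="nonsense", ptc_aa=481),
)
profile, tier = evaluate_bundle(bundle)
print([i.display for i in profile.items], tier.value)
```

prints

```
['PM2_supporting', 'PVS1', 'PM5_supporting'] pathogenic
```

— the nonsense codon at p.Leu481 is NMD-predicted (PVS1 at Very Strong),
sits upstream of p.Arg3047 (PM5_Supporting co-applies), and the variant is
absent from the population data (PM2_Supporting); one very-strong plus two
supporting lines reaches Pathogenic, matching the pilot's treatment of
fully LoF-eligible rare truncating variants.

The same machinery is exposed on the command line:

```bash
atmcurate pilot                      # run the packaged 33-variant pilot set
atmcurate credible-af --inheritance dominant --prevalence 0.125 \
    --genetic-heterogeneity 0.02 --penetrance 0.2
atmcurate synth --seed 7 --n 50 --out bundles.json
atmcurate classify bundles.json --out report.tsv
```

`atmcurate pilot` reports
`12 Pathogenic, 4 Likely pathogenic, 6 Uncertain significance, 2 Likely benign, 9 Benign`
and confirms all 33 classifications match the published pilot curation.

## Layout

- `src/atmcurate/model.py` — domain types, strength algebra, rule constants
- `src/atmcurate/population.py` — BA1/BS1/PM2 and the credible-AF calculator
- `src/atmcurate/lof.py` — the PVS1 decision tree and RNA-assay codes
- `src/atmcurate/insilico.py` — PP3/BP4, BP7, PS1, PM4
- `src/atmcurate/clinical.py` — PM3/BP2 point scoring, PS4, PS3/BS3
- `src/atmcurate/combiner.py` — restriction matrix, classification, points
- `src/atmcurate/pipeline.py`, `io.py`, `synth.py`, `cli.py` — end-to-end
  evaluation, readers/writers, synthetic data, CLI
- `src/atmcurate/data/` — packaged rule constants, restriction matrix,
  pilot fixture and a synthetic *ATM* transcript document

See `docs/methods.md` for the modelling decisions and known limitations.
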