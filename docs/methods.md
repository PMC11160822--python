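# Methods

This note records how the engine models the *ATM*-specific ACMG/AMP rule
set, which parameters matter, where the design was genuinely open, and what
the test suite does and does not demonstrate.

## The model

Each applied criterion is an evidence item: a code id (PVS1, PM3, BP4, ...),
a direction, and a strength on the totally ordered scale
stand-alone > very strong > strong > moderate > supporting. The engine has
three stages:

1. **Assignment** — pure functions per evidence family map structured
   annotations to items. No predictor is executed and no clinical
   adjudication is performed: REVEL/SpliceAI/PROVEAN scores, the A-T
   phenotype tier (confident/consistent), assay verdicts and the
   under-represented-subpopulation flag are caller-supplied inputs.
2. **Validation** — a symmetric pairwise restriction matrix is enforced by
   repair: when a forbidden pair co-occurs the lower-strength member is
   dropped with a warning (ties drop the benign-direction member, then
   break deterministically by code id). An observed RNA splice defect
   (PVS1(RNA)) first supplants all predictive codes (PVS1, PP3, BP4, BP7).
   Validation is idempotent.
3. **Combination** — the 2015 categorical combining rules with two
   modifications: one very-strong line plus one supporting line reaches
   Likely Pathogenic, and a single strong benign line reaches Likely
   Benign. Benign "moderate" items (BS3 at moderate, BP2 at two points)
   count as two supporting benign lines, since the 2015 benign side has no
   moderate level. Evidence in both directions yields Uncertain, with two
   exemptions encoded as code attributes: PM2_Supporting never blocks a
   benign outcome, and BP7 never conflicts with a body of splice-defect
   evidence.

A point-based cross-check (supporting 1, moderate 2, strong 4, very strong
8, benign negative; Pathogenic ≥ 10, Likely Pathogenic 6–9, Likely Benign
−1..−6, Benign ≤ −7, BA1 forcing Benign) runs beside the categorical
combiner. The two systems are intentionally kept separate so each can audit
the other.

## Parameters (all in `RuleConstants`, one versioned JSON document)

| parameter | default | meaning |
|---|---|---|
| `ba1_af` | 0.005 | BA1 stand-alone benign threshold (fraction; strictly greater) |
| `bs1_af` | 0.0005 | BS1 strong benign threshold (strictly greater) |
| `pm2_af` | 1e-5 | PM2_Supporting rarity bound (≤, in every subpopulation) |
| `revel_hi` / `revel_lo` | 0.733 / 0.249 | protein damaging / neutral calls |
| `spliceai_hi` / `spliceai_lo` | 0.2 / 0.1 | splice damaging / neutral calls |
| `provean_deleterious_cutoff` | −2.5 | in-frame indel deleterious call |
| `bp7_donor_min_offset` / `bp7_acceptor_min_offset` | +7 / −40 | deep-intronic eligibility, both exclusive |
| `ps4_or_min`, `ps4_p_max`, `ps4_ci_low_min` | 2.0, 0.05, 1.5 | case-control gates |
| `pm3_point_table`, `pm3_strength_breaks` | see below | biallelic proband scoring |
| `bp2_point_table`, caps | see below | unaffected-carrier scoring |
| `nmd_window_nt` | 50 | NMD escape window upstream of the last junction |

All percent values are converted to fractions at the configuration
boundary; internally everything is a fraction. BA1/BS1 use strictly-greater
comparisons and PM2 less-than-or-equal, following the published inequality
directions; the predictor thresholds are inclusive on the damaging side
(REVEL 0.733 → PP3) and on the neutral side (REVEL 0.249 → BP4).

The operational BA1/BS1 values (0.5%, 0.05%) are set constants, not live
outputs of the credible-allele-frequency calculator: the derivations
(0.625% dominant, 0.527% recessive, then an order-of-magnitude allelic-
heterogeneity reduction for BS1) motivated rounded thresholds, and the
engine keeps derivation and operation separate.

## Open design points and how they were resolved

- **NMD prediction.** A premature stop is NMD-predicted unless it lies in
  the last exon or within 50 nt upstream of the final exon–exon junction —
  the community-standard rule, exposed via `nmd_window_nt` and overridable
  per variant (`LofVariant.nmd_predicted`). For splice-driven frameshifts
  with no exon span, the default is NMD-predicted.
- **PM5_Supporting co-application** is automatic only for PTC-producing
  categories (nonsense, frameshift, NMD-prone exon deletions) at Very
  Strong with the stop strictly upstream of p.Arg3047. Canonical splice
  variants at Very Strong do not auto-receive PM5: their transcript product
  is not a defined premature stop, and adding it would over-call rare
  canonical splice variants (Very Strong + two supporting lines is already
  Pathogenic).
- **PM3 strength breaks** (0.5/1/2/4 points → Supporting/Moderate/Strong/
  Very Strong) follow the published SVI-style scheme the rule set was
  up-weighted from; a single maximum-weight proband (confident phenotype,
  confirmed in trans, 4 points) reaches Very Strong.
- **BP2 per-observation magnitudes** are not published. Defaults (−1
  laboratory in-trans or homozygous, −0.5 phase-unknown; database sources
  at half magnitude) are chosen so the published caps are reachable with
  plausible counts: two independent homozygotes hit the −2 homozygous cap
  and four laboratory in-trans carriers reach the −4 (BP2_Strong) total
  cap. They are explicitly provisional and configurable.
- **PP3/BP4 across mechanisms.** PP3 is one per-variant code whatever the
  mechanism: a damaging call on either the protein or the splice predictor
  yields PP3 (provenance records which); BP4 requires every scored
  mechanism to call neutral, so an intermediate score on one side blocks
  BP4. This keeps protein evidence from being silently counted toward a
  splice mechanism and vice versa.
- **Last-nucleotide donor consensus (Ggtrrgt).** A conforming native donor
  context is recorded as a warning (weaker expected impact) but does not
  change the weight; the weight is anchored to the explicit rule that
  last-nucleotide variants take the matched +1/2 weight reduced one level.
- **Frameshifting duplications** (not covered by the in-frame duplication
  weights): treated like NMD-prone frameshifts when tandem is confirmed
  (Very Strong), Strong when presumed, no weight when tandem status is
  unknown.
- **PS4 gating** is conjunctive (OR ≥ 2 AND p < 0.05 AND lower CI > 1.5);
  a disjunctive effect-size reading (OR ≥ 2 OR CI ≥ 1.5) is available as
  `ps4_disjunctive`.
- **Restriction-matrix symmetry.** Sources disagree on PP3 × BP7; the
  matrix is symmetrized with *forbidden* dominating, which is also the only
  choice consistent with BP7 requiring BP4 while PP3 and BP4 are mutually
  exclusive.
- **Non-adopted codes** (PP1, PP4, ...) appearing in an input profile are
  accepted at their annotated strength with a warning: curated historical
  profiles contain them, and silently dropping evidence would change
  published classifications.

## Categorical vs point classifier

On the 33 packaged pilot profiles the two classifiers never disagree in
direction. Two boundary divergences in tier are expected and documented:
two strong pathogenic lines are Pathogenic categorically but sum to 9
points (Likely Pathogenic), and a lone supporting benign line is Uncertain
categorically but −1 point (Likely Benign). These are intrinsic offsets
between the 2015 categorical grid and the naturally scaled point system,
not implementation artifacts; the acceptance suite pins them to exactly the
two pilot profiles that exercise them.

## Synthetic data

`generate_synthetic_bundles` produces annotation bundles, not variants: it
emulates the *structure* of curated evidence (population frequencies,
predictor scores, LoF annotations, proband/carrier observations, assay
verdicts) rather than sequences. `all_branches` mode deterministically
exercises every decision-tree branch and every adopted code; `random` mode
draws seeded random bundles. What passing tests on synthetic bundles shows
is that the rule logic is implemented as specified; it says nothing about
the accuracy of upstream annotations (predictor scores, phenotype tiers,
phase calls) on real data, which the engine takes on trust.

The packaged *ATM* transcript document is a synthetic stand-in: the exon
count (62 coding exons), total coding length (9171 nt), protein length
(3056 aa) and the domain map are correct, but the per-exon coding lengths
are invented, so reading-frame arithmetic against it is only
structure-realistic. The pilot fixture enters at the evidence level
(applied codes) and never consults the transcript; analyses of real *ATM*
CNVs should supply a transcript document built from the reference
annotation.

## Problem sizes and determinism

Everything is closed-form and deterministic; the full test suite (228
tests, including 1,000-transcript brute-force frame checks and randomized
combiner perturbations) runs in a few seconds on one CPU, and
`scripts/acceptance.py` in well under a second. The `--seed` argument
covers all synthetic sampling.

## Known limitations

- Filtering allele frequencies are inputs; the engine does not compute the
  95%-CI-bounded frequency from raw counts.
- "Under-represented subpopulation" has no quantitative definition; the
  flag is caller-supplied.
- Literature-informed per-site splice overrides (beyond the two encoded
  special cases: +2T>C without predicted impact, and the atypical native
  c.7515+2 site) must be supplied as curator overrides.
- Proband deduplication across laboratories is the caller's responsibility;
  proband ids are assumed unique.
- The hotspot-free PS1 protein route requires the caller to assert that a
  splice defect has been ruled out and that prediction strengths match;
  the engine does not re-derive either.
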