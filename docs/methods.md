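# Methods

## Scope and data model

`wgspanel` models the analysis stages of a familial-cancer WGS programme
downstream of variant calling and annotation: prioritisation of annotated
small-variant and SV/CNV calls, reportability triage with MDT
bookkeeping, cohort-level summary statistics, and a programme-level
cost-consequence model. Variant calling, alignment, VEP annotation and
expert ACMG/AMP classification are out of scope — their outputs (calls,
annotation columns, class labels, MDT verdicts) are inputs here.

Tables are pandas DataFrames; intervals are 0-based half-open internally
(VCF positions converted at the I/O boundary, BED native). VCF v4.2
reading/writing goes through pysam; region queries through an interval
tree; the union-coverage and reciprocal-overlap kernels are small explicit
functions so their semantics (BEDTools-style `-f 0.80` against merged
regions; `min(|a∩b|/|a|, |a∩b|/|b|)`) are visible in one place.

## Small-variant cascade

Gates run in order: panel restriction, frequency, VAF. All inequalities
are strict, so threshold values (AF = 1%, VAF = 30%/20%) are retained.
Missing allele frequencies count as 0 — absence from a population
resource implies rarity. Subpopulation eligibility (the "≥2000
individuals" requirement) is a per-resource flag carried in the
subpopulation map, not recomputed; exome- and genome-derived frequencies
are tested separately.

Two deliberate interpretations, applied consistently in both the cascade
and the generator's ground-truth labels:

* the ClinVar LP/P rescue waives the **frequency** filters only. The VAF
  gate is a call-quality filter and applies unconditionally — a
  pathogenic-annotated call at 25% VAF is still a suspect call.
* dinucleotide substitutions (DNVs) use the SNV threshold, being
  substitution-type calls.

Panel restriction runs first for audit clarity; since all gates are
per-variant this is output-equivalent to any other order. The in-cohort
frequency is interpreted as an allele frequency. Multi-allelic records
must be pre-decomposed to one row per alternate allele.

## SV/CNV cascade

Order of operations: q0 flagging (caller-B calls with q0 < 0 or > 0.5 are
*removed*, unless genotype score < 0.25, before anything else — in
particular before concordance matching, so a q0-failed partner cannot
rescue a call into concordance); greedy one-to-one dual-caller CNV
matching (descending reciprocal overlap, ties broken by smaller record
id; only pairs with RO ≥ 0.80 and identical type/chromosome are
candidates); blacklist exclusion (≥80% of the span covered by the *union*
of regions for DEL/DUP/INV; any breakpoint containment for TRA/INS);
population-frequency exclusion (assigned AF = max over same-type resource
records at RO ≥ 0.80, or breakpoints within 100 bp for TRA/INS on both
ends; strict >5% excludes); gene association (any overlap for CNVs;
breakpoint containment for other SVs) and panel restriction.

Single-caller CNVs are retained with a `MANUAL_REVIEW` flag rather than
dropped — they are review candidates, not exclusions. Only DEL/DUP calls
require dual-caller support; breakpoint-based SV types come from one
caller by design.

Gene footprints extend 2000 bp upstream of the transcription start,
strand-aware by default (`[start−2000, end)` on +, `[start, end+2000)` on
−), clipped at chromosome bounds. A strandless mode
(`strand_aware=False`, always `[start−2000, end)`) is available because
annotation exports differ on this convention.

## Reportability triage

LP/P variants always report. For the rest, three exclusionary patterns
(missense with REVEL < 0.5; synonymous without predicted splice impact;
in-frame indel with PROVEAN > −2.5) suppress the variant unless any
rescue applies: gene–phenotype association (an input boolean — no attempt
is made to operationalise clinical judgement), an alternative
deleteriousness predictor (CADD > 20; additional predictors would slot in
beside it), or an LP/P ClinVar assertion from at least one submitter.
Consequences matching no exclusionary pattern (frameshift, splice,
nonsense, …) always pass. A required score missing for an applicable rule
is a data error, not a silent pass.

MDT verdicts are inputs: `return` (optionally setting the VUS tier and
finding flags), `exclude`, `downgrade_B_LB`. Downgraded variants never
reach a report, and report assembly refuses outright to emit a B/LB
variant (safety invariant). Variants returned without formal MDT review
are modelled as `return` verdicts with a `direct_return` provenance flag
— the downstream effect is identical.

## Synthetic data

Generators use `numpy.random.default_rng` seeded from `(seed, stream)`
pairs: identical parameters give byte-identical tables. The genome is a
configurable linear space (default 10 Mb) split into five
pseudo-chromosomes; the virtual panel is seven real hereditary-cancer
symbols plus deterministic placeholders (G008…), with a few off-panel
symbols (NP…) so panel restriction is exercised.

Small variants default to n=1000 with 30% "common" (the offending >1%
frequency planted in one *eligible* resource; a further 5% of rare
variants get a high frequency in an ineligible subpopulation, which must
not cause a drop), 5% ClinVar LP/P, heterozygous-like VAFs (N(0.5, 0.05))
with a 15% low-VAF artefact tail. SV generation plants ~40% of per-caller
calls as cross-caller DEL/DUP pairs, jittered so some pairs sit above and
some below the 80% reciprocal-overlap threshold; ~12% of single-caller
calls are snapped into blacklist regions; frequency-resource rows are
planted at matching coordinates (common: AF > 5%; decoys: AF ≤ 5% or
breakpoints 150 bp away, outside the 100-bp window).

Every generated filter input carries a `truth_keep` label computed by a
straight-line brute-force restatement of the rules inside `synth.py`,
kept deliberately independent of the filter modules; cascade-vs-label
equality is therefore a genuine dual-route check. The generators do not
emulate real allele-frequency spectra, caller error modes, linkage or
read-level evidence — passing the oracle tests demonstrates that the
implemented rules are applied exactly, not that they are clinically
optimal on real genomes.

The cohort fixture is code-generated, not random: 195 cases and 119
returned variants constructed so that every published-style tally is
exact (31 LP/P in 29 cases with two double-LP/P cases, 88 VUS in a
7/54/27 tier split, report multiplicities 67/23/2, 10 causal / 19
secondary cases, 20 risk-management changes, 9 uninformative LP/P cases
including one somatic structural variant, eligibility counts 28/83/52/29/
42, phenotype-category totals dealt by a greedy exact-multiset
assignment). Summary percentages use half-up rounding to one decimal,
the convention of clinical cohort tables.

## Economic model

An expected-value cohort decision tree over one year, AUD 2020, no
discounting; counts flow as real numbers and are rounded only for display
(`rounded_headline`: totals to $0.1M, cases to integers, yields to 0.1%).

Published parameters are fixed inputs: 13,230 individuals referred
nationally per year (reproducible via `scale_national` from state-level
referrals and jurisdiction populations), 35.04% offered targeted testing,
Scenario-2 WGS uptake 79.6% (96.8% as a sensitivity value), Scenario-3
WGS uptake 96.8% and per-tested yield 38.4% (sensitivity: 28.2%, 17.3%),
WGS price $1750 (sensitivity: $1366).

Parameters *not* published in the main analysis — targeted-testing uptake
(0.85) and per-tested yield (0.1165), the Scenario-2 subgroup yields
(tested-negative 0.155; never-offered 0.1743, both offered WGS at 100%),
the Scenario-3 complex-case fraction (0.54), and the unit costs
(pre-test counselling $200; post-test counselling $400 positive / $150
negative; targeted test $870; MDT $1450 per reviewed case;
administration $500 complex / $150 non-complex; programme overhead
$110 per WGS test) — are placeholder values calibrated once so the base
case reproduces the published headline outputs ($4.9M/459, $45.3M/2081,
$43.9M/4918). The regression tests that pin those six numbers are
therefore **calibration pins, not independent validation**; the
independent content is the tree structure, the flow/cost identities, the
monotonicity behaviour and the derived ratios (yields 3.5%/15.7%/37.2%,
cost per actionable case, marginal costs $8.7k/$24.9k, the ninefold
expenditure ratio), which follow from the published inputs once the
totals are set. In Scenario 2 every WGS case incurs the MDT cost; in
Scenario 3 only the complex fraction does, with a switch
(`mdt_all_cases_s3`) for the all-MDT sensitivity analysis. Pre-test
counselling is charged per test episode, so a Scenario-2 patient tested
twice is counselled twice.

`one_way_sensitivity` clones the config per value and re-evaluates all
scenarios; the 50%/150% referral-volume analysis is expressed by varying
`referred_national`.

## Problem sizes and numerics

Default test/acceptance sizes: 1000 small variants and 2×150 SV calls for
the oracle checks, 100 random instances for the interval-kernel
brute-force comparisons — ample to exercise every rule branch while
keeping the whole suite in seconds. Percentage rounding uses decimal
half-up (banker's rounding would disagree on exact .05 boundaries).
Degenerate inputs: empty tables flow through every stage; zero-length
intervals, missing required scores/q0/VAF, out-of-range frequencies,
unknown verdicts or dangling identifiers raise `ValueError`.

## Known limitations

* The generator's concordance mix and false-positive structure per caller
  are free parameters, not estimates of DELLY/CNVnator behaviour.
* The within-cohort SV frequency is taken from per-record annotation
  columns/resources rather than recomputed across the cohort.
* VUS tiers and ACMG classes are inputs; no evidence scoring is
  performed.
* The economic model's micro-costs are calibrated placeholders (see
  above); conclusions about *absolute* costs inherit their uncertainty,
  while ratio-type outputs are insensitive to the split of the fixed
  per-test cost components.
* The Scenario-3 worst-case cost-per-actionable under the 17.3% yield
  depends on unpublished subgroup internals and is supported as a
  computation but not pinned to a reference value.
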