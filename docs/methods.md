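# Methods

This note documents the models, rules and conventions implemented in
`lsdpanel`, the defaults chosen where the underlying workflow left a choice
open, and what the synthetic validation does and does not demonstrate.

## Filter cascade

The cascade assumes a monogenic, highly penetrant disease model: a causal
variant is rare in reference populations, rare in the study cohort, and
protein-altering. Filter 1 is the conjunction of four criteria per call:

| criterion | rule | default |
|---|---|---|
| af_rare | database NRA frequency ≤ `pop_af_max`, missing passes | 0.01 |
| region_ok | region class ∈ `allowed_regions` | {exonic, splicing} |
| class_ok | function class ∈ `allowed_classes` | {nonsynonymous, stopgain, frameshift_indel, inframe_indel, splicing} |
| cohort_rare | cohort frequency ≤ `cohort_freq_max` | 0.04 |

A missing database frequency passes af_rare: novel variants are exactly the
diagnostically interesting ones and must not be discarded for lacking an
annotation. This is configurable (`missing_pop_af_is_rare`).

Cohort frequency defaults to *carrier samples / cohort samples*, computed
per call table (i.e. per sequencing batch); a carrier is a sample with at
least one call of the site by any caller. An allele-based mode
(`cohort_freq_mode="alleles"`) counts two alleles for calls in the
homozygous NRA band over 2N chromosomes. The carrier interpretation is the
default because it is the one under which typical batch sizes give
integer-feasible cutoffs. Note the structural consequence: a variant
private to one sample has cohort frequency 1/N, so the 4% rule requires
N ≥ 25 before unique variants can pass at all; the synthetic default of 30
samples respects this.

Filter 2 is a vote over four per-call quality conditions (depth ≥ 20,
NRA ≥ 30%, both allele MQVs ≥ 15, MQV difference ≤ 5); a call passes with
`min_votes` (default 3) satisfied conditions. Conventions:

- A condition evaluated on a **missing metric counts as not satisfied** and
  is tallied in `missing_conditions`. Failing open would let unannotated
  artifacts through, defeating the filter's purpose.
- **Borderline** is any evaluated metric within `borderline_margin`
  (relative, default 0.10) of its threshold. The margin quantifies the
  otherwise informal notion of a call "near the limit"; borderline calls are
  reported so they can be prioritized for orthogonal confirmation.
- The implied false-positive rate of the stage is
  `round(100·(n_before − n_after)/n_before)` to the nearest whole percent
  (half rounds up); caller miss rates are instead **truncated** to one
  decimal (3/105 → 2.8, 9/105 → 8.5). The two conventions are kept separate
  deliberately — each matches the reporting convention evident in the
  numbers the respective computation reproduces.

Raising any threshold, or `min_votes` from 3 to 4, can only shrink the
survivor set (monotonicity); both properties are tested.

## Caller concordance

Variant identity across callers uses normalized keys: alleles are reduced
to their minimal representation (shared suffix then prefix trimmed, 
position advanced), so the two callers' indel spellings compare equal.
Sample identity must match exactly. Merging is a key union that records
which caller(s) detected each call; truth annotation is a lookup against a
confirmation table. `confirmation_split` refuses records with unknown
confirmation status rather than silently dropping them, because a
real/false percentage over a partially confirmed set is not interpretable.
Its two percents are constrained to sum to 100, the larger share absorbing
the rounding residue.

## Exon-dosage CNV detection

The method is deliberately simple — ratio thresholding on coverage peak
areas, no segmentation model, no GC regression — because exon-level dosage
at high mean depth separates cleanly: with per-base depth Poisson(λ) and
exon length L, the peak area has coefficient of variation (λL)^(-1/2)
(≈ 0.6% at λ = 200, L = 150), far inside the band widths.

Normalization is median-of-ratios with a geometric-mean reference for the
size factors: size-factor exons are the evaluable exons with positive area
in every sample; k(s) = median over those exons of A(s,e)/g(e) with
g(e) the across-sample geometric mean; the dosage reference is the cohort
median of size-corrected areas. The geometric-mean reference (rather than a
plain median) makes ratios *exactly* invariant to rescaling any one
sample's areas, and the median ratio/median reference keep the few true CNV
carriers from contaminating the reference. If every evaluable exon has a
zero somewhere (pathological), the size factors fall back to plain
median-of-medians.

State bands are centred on the ideal dosage expectations 0.5 / 0 / 1.5:

| state | band (ratio) |
|---|---|
| hom_del | [0, 0.15] |
| het_del | [0.35, 0.65] |
| het_dup | [1.35, 1.65] |
| normal | anything else |

Maximal runs of consecutive same-state exons within a gene are emitted as
single calls (`min_consecutive` = 1); non-evaluable exons and ordinal gaps
break runs, so every call is contiguous. Exons whose cohort-median area is
below `floor_mean_depth` × exon length (default 20× — the same threshold
the QC report uses for coverage gaps) are non-evaluable: dosage cannot be
read from an exon the capture failed to cover. Duplications are included
even though deletions are the common finding, since the same dosage logic
covers both. Breakpoints are resolved to exon level only; sub-exon mapping
requires orthogonal (cDNA) evidence and is out of scope.

## Zygosity and triage

Zygosity bands partition [0, 1] of the NRA fraction: < 0.30 low_fraction,
0.30–0.50 heterozygous, 0.50–0.70 ambiguous, 0.70–1.00 homozygous
(hemizygous on X targets in declared-male samples). The two named bands are
empirical; the gap between them is surfaced as `ambiguous` rather than
silently assigned, and is counted as one allele downstream with a logged
warning. `low_fraction` calls are retained and flagged because real small
indels systematically under-represent in read counts.

The six pathogenicity criteria are emitted as independent flags. The tier
rule — likely_pathogenic needs ≥ 4 evaluable criteria met including c1
(truncating) or c6 (missense predicted deleterious); 2–3 uncertain; ≤ 1
likely_benign — is a package convention, not an external standard: the
source workflow applies its criteria narratively with no combining rule,
and the flags are always available for re-weighting. Criterion evaluability
matters: c3 (cosegregation) only counts when both parents are typed, c6
only for missense with at least one in-silico call (simple majority of
available predictors).

Diagnosis counts qualifying alleles per gene — likely_pathogenic, or
uncertain with a truncating class; homozygous counts two under AR,
hemizygous two under XL. Phase is unknown without trios, so two
heterozygous qualifying variants are counted biallelic unless parental
genotypes prove both came from the same parent (cis), which demotes the
gene to one allele. Synonymous variants in the best gene are flagged for
manual splice-effect review, never auto-promoted. CNV calls are reported
alongside but not auto-counted as alleles; combining a dosage event with a
point mutation remains a review decision.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults define the study
conditions used throughout the test suite and the acceptance script.

| parameter | default | what it emulates |
|---|---|---|
| n_genes × exons | 10 × U{3..8} | miniature version of a ~57-gene, 551-exon panel |
| exon_length | U{100..250} bp | typical coding exon sizes |
| n_samples | 30 | a sequencing batch; ≥ 25 so unique variants clear the 4% rule |
| mean_depth λ | 200× | high-coverage targeted capture |
| cpg_exon_fraction / multiplier | 0.10 / 0.05 | CpG-island enrichment dropout ("even to zero") |
| repeat_edge_fraction / gap | 0.05 / 20 bp | bait-design gaps at repeat boundaries |
| archetypes | 6 biallelic, 5 monoallelic, 19 none | diagnosed / carrier / undiagnosed structure |
| n_polymorphisms, AF | 20, U(0.05, 0.5) | common background variation under Hardy-Weinberg |
| artifact_rate | Poisson(3)/sample/caller | caller-specific false calls in coverage valleys |
| miss_prob per caller | 3/105, 9/105 | observed dual-caller detection failures |
| true_borderline_rate | 0.09 | real calls with one metric just past threshold — the false negatives an all-4 vote creates |

Coverage is per-base Poisson(λ·m), m the product of copy dosage (1, 0.5,
0, 1.5) and the CpG multiplier, with zeroed repeat-edge margins. True
variants appear in both callers with shared quality (both callers see the
same pileup) from the true-variant model: heterozygous NRA ~
Normal(0.5, 0.05) truncated to [0.3, 0.7], homozygous ~ U(0.85, 1.0), MQVs
≥ 15 with difference ≤ 4, depth read off the coverage simulation — at
least three of the four vote conditions hold by construction. Artifacts
are never shared between callers (disjoint position pools), sit
preferentially on low-coverage exons, and violate ≥ 2 vote conditions by
construction. A single global seed drives all stages through independent
`SeedSequence` substreams, so outputs are byte-identical per seed and
changing one stage's model leaves the others untouched.

The manifest's expected diagnosis statuses are computed from the planted
variants *actually emitted by at least one caller* — a caller-miss event is
part of the ground truth, so a sample whose second allele both callers
missed is expected `carrier`, not `diagnosed`.

What the generator does **not** model: read-level errors, alignment and
mapping ambiguity, GC-dependent depth trends, correlated (non-Poisson)
coverage noise, batch effects between platforms, population structure in
the polymorphism model, and artifact quality correlated with the local
depth value. Passing the end-to-end tests therefore shows the pipeline's
logic is correct under its stated statistical assumptions; it does not
certify performance on real capture data, where dosage ratios are noisier
and artifact models richer.

## Problem sizes and numerical choices

The default validation cohort is 30 samples × 10 genes (~55 exons), with
100 replicates for the dosage experiment at 8 samples × 3 genes — sizes
chosen so the full suite and the acceptance script each run in seconds
while exercising every code path (CpG dropout, repeat edges, het/hom/dup
dosage states, compound-het/homozygous/carrier archetypes, caller misses,
artifact rejection). Percent roundings are as described above; dosage
ratios are reported to 4 decimals; TSV round-trips preserve fractions to 6
decimals and integers exactly, with missing values as empty fields.

## Known limitations

- The cascade's 4% cohort rule makes small cohorts (< 25 samples)
  structurally unable to retain sample-unique variants; the CLI does not
  silently adjust this — configure `cohort_freq_max` explicitly if needed.
- Zygosity from a single NRA fraction cannot distinguish a homozygous
  variant from a hemizygous one over an undetected deletion.
- The triage tier rule predates formal classification frameworks and is a
  reporting convention; it should not be read as a clinical classifier.
- VCF ingestion expects allele depths (AD); records without them are kept
  with missing quality and will fail the vote's depth/NRA conditions.
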