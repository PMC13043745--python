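# Methods

This note records the models implemented in `nmdconstraint`, the
conventions and defaults chosen where the underlying rules admit more
than one reading, and what the synthetic-data generator does and does not
emulate.

## Transcript models and coordinates

Transcripts are read from GENCODE-dialect GTF. Coordinates are GTF-native
(1-based, inclusive) everywhere in the public API; any half-open
arithmetic is internal. The in-memory CDS *includes* the stop codon —
convenient because every positional rule and the PTC scan operate on the
full coding frame — so the reader merges GENCODE's separate `stop_codon`
features into the CDS intervals. Exon ranks count 5'→3' in transcription
order; on the minus strand rank 1 is the exon with the highest genomic
coordinates. The CDS↔genome map is an explicit bijection; round-trip
identity is enforced by tests.

Canonical selection takes MANE Select where available, else the APPRIS
principal isoform; genes with neither are dropped and logged, and two
MANE entries for one gene raise an error rather than being resolved
silently. Transcripts whose CDS length is not divisible by 3 are retained
with a warning flag; consequence calling and PTC scanning refuse them,
while region annotation and counting do not need translation and proceed.

## NMD region rules

Final labels are `start_proximal`, `long_exon`, `distal` (the union of
the last-exon and 50-nt rules) and `nmd_target`, resolved with priority
start_proximal > distal > long_exon.

Distance convention: for a CDS position *p* in an exon whose last coding
base has CDS coordinate *J*, define d = J − p. Then

* `start_proximal`: cds position ≤ 150 (the start codon's own bases
  count; "within 150 nt of the start" read as an inclusive window from
  the first coding base);
* `long_exon`: d > 400, strictly — a position exactly 400 nt upstream of
  the donor is *not* long-exon;
* 50-nt rule: d ≤ 49 and the exon is the transcript's penultimate exon,
  covering exactly the last 50 coding bases of that exon. The window size
  is configurable (some descriptions use 50–55 nt; 50 is implemented as
  the default).

"Penultimate" and "last" are counted in full transcript exon space, UTR
exons included. This is what makes 3'UTR introns behave correctly: when
the CDS ends before the last exon, no coding position is in the last
exon, so the last-exon escape region vanishes; the 50-nt rule applies
only if the CDS-bearing exon happens to be penultimate. A final-coding
exon followed by a 3'UTR intron still has a real donor site, so its 5'
positions are evaluated for the long-exon rule. Note that d is measured
in CDS coordinates: for an exon with an internal CDS→UTR transition the
physical donor is farther away by the UTR gap; the CDS-space reading was
chosen because the rules are stated over CDS positions and the affected
positions are a small corner case (~4% of transcripts carry 3'UTR
introns at all).

## Consequence calling and enumeration

A minimal codon-table caller classifies CDS SNVs as synonymous, missense
or nonsense (Biopython's standard table; vectorised over whole
transcripts with integer codon indexing). Substitutions in the reference
stop codon are excluded — stop-lost/stop-retained are out of scope — so
a transcript contributes 3·(CDS length − 3) possible SNVs. Records carry
plus-strand alleles for joining genomic rate tables and coding-strand
alleles for sequence work.

## Scaled mutation rates and expected counts

Raw per-SNV rates (arbitrary positive units) are calibrated to *neutral
observation probabilities*: among background sites (high-quality
synonymous SNVs), the proportion observed in the cohort is computed per
distinct raw-rate value when there are ≤256 of them, else per 100
equal-count quantile bins. Isotonic (pool-adjacent-violators) smoothing,
weighted by bin occupancy, enforces monotonicity — observation
probability cannot decrease with mutability — and is on by default.
Lookup is by nearest bin. The calibration is deliberately
non-parametric: its contract is only that the scaled rate estimates
P(site observed | neutrality) for the cohort at hand.

Expected counts per transcript × region × consequence are Σ scaled_rate
over possible SNVs (equivalently mean scaled rate × number possible).
Sites with median sequencing depth < 20 are excluded from possible and
observed tallies symmetrically, so poor coverage cannot mimic depletion.
A whole-transcript (`full_cds`) group is always appended.

## The depletion test

Observed counts are modelled as Poisson-binomial: one trial per possible
SNV with success probability its scaled rate. The one-sided tail
P(X ≤ x) is computed exactly with a truncated dynamic programme over
states 0..x plus one absorbing state (O(Nx), numerically exact) up to
N_exact = 20,000 trials; above that, a refined normal approximation with
continuity correction and the first Edgeworth (skewness) term is used,
accurate to a few 10⁻³ at the boundary. The branch taken is recorded in
the output. A plain binomial CDF at the mean rate is available as a
sensitivity option (`test="binomial"`), since descriptions of such tests
sometimes name the binomial or a Z test; the Poisson-binomial is the
default and the primary model.

O/E is observed/expected. OE95 is the upper bound of the *two-sided* 95%
binomial confidence interval on the observed proportion (upper bound at
97.5%), times possible/expected. Clopper–Pearson is the default interval
— exact and conservative — with Wilson as an option; whether the
original interval was one- or two-sided is not specified anywhere, and
the two-sided reading was chosen as the more conservative.

BH-FDR is applied across nonsense depletion tests, jointly across all
transcript × region rows by default (a per-region family is available).
Classification: **constrained** iff q < 0.05 AND synonymous depletion
p ≥ 0.05 AND OE95 < 0.6; **unconstrained** iff unadjusted p ≥ 0.05 AND
≥1 nonsense variant observed; else **indeterminate**. Regions with no
synonymous sites cannot be called constrained and are warned about.

## MAPS

Per distinct scaled-rate value, the proportion of singletons
(allele count == 1) among observed synonymous variants is regressed on
the scaled rate by weighted least squares, weighted by the number of
*possible* variants at that rate. The model is first-degree linear — the
minimal form consistent with "PS against the scaled rate" — and
predictions are clipped to [0, 1]. For a variant class, the expected PS
averages predictions over the class's *observed* variants (PS is a
property of observed variants); MAPS = observed PS − expected PS, with a
normal-approximation binomial CI on the observed PS. Pairwise class
comparisons first shift every class onto a common scale (adjusted
PS = MAPS + expected synonymous PS) and then apply two-sided
two-proportion Z tests with Bonferroni correction at the configured
family size.

## PTC localisation

A variant is applied to the CDS string (VCF anchor-base convention for
indels); scanning starts at the codon containing the first edited base,
in the frame anchored at the start codon, and returns the first stop in
{TAA, TAG, TGA}. Mapping back to reference coordinates subtracts the net
inserted length 5' of the stop (deletions add their length). An in-frame
variant whose first downstream stop is the reference stop is "no PTC".
A frameshift that reaches the end of the provided sequence without a
stop is flagged `escape_into_utr` and excluded downstream.

Region anchor: when the edit lies inside the new stop codon (nonsense
SNVs, in-place stop-creating indels) the region is read at the edited
base, which makes the SNV pathway agree exactly with positional
annotation even at region boundaries that are not codon-aligned; for
stops downstream of the edit the codon's first base is the anchor.
Variants spanning the start codon or carrying combined ontologies are
excluded rather than guessed at.

## De novo variant analyses

Filters (population AC ≤ 1, population AF ≤ 1e-4, cohort AC ≤ 5,
consequence in {synonymous, missense, nonsense, frameshift}) are
configurable; missing annotations pass (absence from a population
database is itself evidence of rarity) and are logged. Cross-cohort
deduplication drops a variant key from lower-priority cohorts when seen
in a higher-priority one; within-cohort duplicates from different
probands are distinct de novo events and are kept.

Relative enrichment = (DNV_constrained / E_constrained) /
(DNV_unconstrained / E_unconstrained), where E counts unique SNVs
expected under the mutational model (each possible SNV once, no
allele-count weighting). Nonsense and frameshift DNVs are pooled and
normalised by the *nonsense* expectation, since indel rates are not
modelled. Indeterminate regions are excluded from both arms. Confidence
intervals and two-sided p values come from a percentile bootstrap
resampling individual DNV records (B = 10,000 by default, seeded);
resampling records rather than probands matches the count statistic
being bootstrapped.

Diagnostic odds ratios use 2×2 tables of carrier status × solved status
('yes'/'partially' count as solved; 'no'/'unknown'/absent as unsolved),
with the Woolf log-SE normal interval, a two-sided Z test on the log OR,
and Haldane–Anscombe 0.5 correction on zero cells (flagged).

The candidate-gene screen keeps genes with ≥3 truncating DNVs inside one
constrained region whose nonsense O/E < 0.3 and whose reference-cohort
observed nonsense count is < 20, excluding genes on supplied curated
disease-gene lists.

## The synthetic-data generator

`synthetic_data` emulates the statistical structure the analyses assume,
at desk scale:

* **Transcriptome** — multi-exon transcripts (Poisson exon counts, mean
  5; log-normal coding exon lengths, median ~165 nt, minimum 30 nt), 4%
  with 3'UTR introns, half on the minus strand, CDS = ATG + sense codons
  + one stop; written as GENCODE-dialect GTF (CDS excluding the stop
  codon plus a `stop_codon` feature, as GENCODE does) and a genome FASTA.
* **Mutation rates** — a two-component log-normal mixture per SNV (90%
  baseline, 10% hypermutable), standing in for context/methylation rate
  heterogeneity.
* **Cohort** — each possible SNV observed ~ Bernoulli(min(1, λ·rate) ×
  (1 − s_region) for nonsense), λ = 0.12 giving a mean neutral
  observation probability near 0.15, of the order of the fraction of
  possible coding SNVs segregating in a biobank-scale cohort. Allele
  counts are zero-truncated with singleton probability
  p₁ = 0.45 − 0.5·(neutral probability) + 0.4·s: the singleton fraction
  falls linearly with mutability (exactly the relationship the MAPS
  regression removes) and rises with selection (exactly the signal MAPS
  must detect). 5% of sites are low-depth (10×) and excluded by the
  depth-20 filter.
* **Trios** — SNV DNV counts ~ Poisson(ν·rate·e_region·n_trios) with
  ν = 3e-8, giving ~1e-4 coding DNVs per gene per trio as in large
  rare-disease cohorts; frameshifts are random 1–2 nt indels thinned by
  the enrichment of their downstream-PTC region; case-solved outcomes
  are logistic in carrier status with a configurable odds ratio
  (baseline solved rate 0.3).

All randomness flows from one seeded generator; outputs are
byte-identical across runs. The generator does **not** emulate
demography or linkage (sites are independent), sequence-context mutation
models, genotype-quality artefacts, or multi-gene overlap; passing tests
therefore demonstrate statistical correctness of the estimators under
the assumed observation model, not robustness to the correlated noise of
real cohorts.

## Problem sizes and numerical choices

The simulation studies use: 1,000 neutral regions (expected ≥ 10
nonsense each) for type-I error; 300 regions at true O/E 0.2 with
expected ≥ 20 for power; 500 regions at true O/E 0.5 with expected ≥ 50
for estimation bias; a 150-transcript cohort for MAPS calibration; 100
bootstrap replicates (B = 2,000) at 5-fold enrichment with ≥200 DNVs per
arm; 5,000 trios for odds-ratio recovery; and 120–300 transcripts for
end-to-end O/E recovery. These sizes were chosen so each statistic's
sampling error is several times smaller than the tolerance being
checked, while the full suite runs in minutes on one CPU.

Degenerate inputs: empty probability vectors yield NaN p-values;
expected = 0 yields flagged NaN O/E; empty calibration bins are dropped
with a warning; a zero-transcript simulation writes empty but
parseable files.

## Known limitations

* The long-exon/50-nt distances are CDS-space approximations for exons
  with internal CDS→UTR transitions (above).
* The calibration assumes background sites are neutral and exchangeable
  with the target sites at equal raw rate; systematic depth or call-rate
  differences between classes would bias expected counts.
* The normal-approximation branch of the Poisson-binomial tail is only
  engaged above 20,000 trials; its ~1e-3 absolute error is negligible
  for classification but matters if exact tiny p-values are needed at
  that scale.
* Indel mutation rates are not modelled anywhere; frameshifts enter only
  through DNV counting and PTC localisation, never the constraint model.
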