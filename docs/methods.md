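# Methods

## Problem setting

`ampliseq` implements the bespoke analysis layer of a single-gene targeted
amplicon resequencing assay of the kind used for CFTR molecular diagnosis of
cystic fibrosis: ~9 kb of coding and selected intronic sequence amplified by
33 overlapping primer pairs, sequenced as single-end full-amplicon reads on a
flow-based (semiconductor) platform, and genotyped down to phased complex
alleles.  Standard callers underperform on two specific failure modes of this
design, both of which this package addresses explicitly:

1. **Primer shadowing.** A variant that falls under the primer footprint of
   one of two overlapping amplicons is replaced by synthesized (reference)
   primer sequence in that amplicon's reads.  If those bases feed the pileup,
   the wild-type allele is overestimated and the variant can drop below the
   VAF threshold — a false negative.  The fix is post-alignment *masking* of
   each read's own primer bases.
2. **Homopolymer stutter.** Flow-based chemistry miscounts mononucleotide run
   lengths, so a length variant in a run (e.g. a single-A duplication in an
   (A)7 tract) cannot be called from individual indel observations; it is
   called from the run-length *frequency spectrum* instead.

## Pipeline model

Stage order: read QC → primer masking → pileup → threshold calling →
homopolymer calling → cross-sample artifact filtering → read-backed phasing
→ annotation/severity → cohort statistics.

**Read QC.** A read is kept iff its arithmetic mean Phred score is ≥ 25 and
its length is ≥ 75 bp (both inclusive; Prinseq's convention of averaging
scores, not error probabilities).

**Primer masking.** Each aligned read is assigned to the amplicon with
maximal span overlap (ties: nearer start coordinate, then lexicographic id).
Bases in the assigned amplicon's primer intervals are flagged non-countable
but the alignment span is retained — masking, not clipping, so primers keep
anchoring alignments and indels near read ends stay detectable.  Unassigned
reads are conservatively masked against every primer interval they overlap.
In SAM output, masked bases get base quality 0 and the intervals are recorded
in an `XM` tag.

**Calling.** The caller is threshold-based (no genotype likelihoods),
mirroring the assay's published protocol: an allele is PASS iff usable
(post-mask, post-cap) depth is ≥ 15 reads on *each* strand, VAF ≥ 0.20, and
the allele shows no significant strand bias (two-sided Fisher exact p < 0.01
*and* alt strand ratio outside [1/5, 5] are both required to flag).  The
per-strand depth cap (10,000) is applied deterministically in read-id order.
Indels are left-aligned against the reference before keying.  Sub-threshold
alleles (≥ 2 supporting reads) are emitted with failure flags because the
recurrence filter needs them.

**Recurrent artifacts.** An allele observed in ≥ 75% of samples with median
VAF < 0.20, or an indel flagged homopolymer-adjacent in that many samples, is
blacklisted cohort-wide.  Under the default stutter model, homopolymer
windows blacklist themselves by construction (stutter recurs in every
sample); the interesting content of the blacklist is its non-homopolymer
part, which in simulations recovers exactly the planted artifact set.

**Homopolymer calling.** Sites are maximal runs ≥ 5 bp.  Only reads spanning
the run plus one anchored flank on each side are informative; the observed
run length is the longest run of the site's base between the flanks
(insertions included).  A non-reference length L is called iff freq(L) ≥ 0.10
*and* the observed count is statistically inconsistent with the baseline
stutter rate for the offset L − ref (one-sided exact binomial, α = 10⁻⁶ —
conservative because the rule is applied at every run × sample).  The second
condition matters on both sides: at moderate depth the 4% (+1) background
fluctuates past 10% too often for the threshold alone, and the pervasive
−1 stutter (15% baseline) sits *above* the threshold permanently yet never
reaches significance at its own rate — only an overwhelming deletion excess
calls.  The 0.10 threshold is the midpoint of the observed gap between the
non-carrier maximum (8%) and the carrier minimum (16%); stutter priors
(−2: 6%, −1: 15%, +1: 4%) are configuration.  Generic indel calls inside
run ± 1 bp are suppressed (`hp_adjacent`): the spectrum caller owns those
windows.

**Phasing.** For a pair of PASS variants, co-covering reads are tallied into
both-alt / alt1-only / alt2-only / both-ref.  Cis requires ≥ 5 both-alt reads
with each singleton category < 10% of the co-covering total; trans requires
≥ 5 of each singleton with both-alt < 10%; anything else is unknown.  The
5-read / 10% thresholds are this package's (the assay's write-up states
none); 10% tolerates the default per-base error rate with wide margin.
Variants on non-overlapping amplicons are never read-resolved — no
population phasing is attempted, matching the `(;)` unknown-phase notation.
Assembly builds a phase graph (cis edges merge into complex alleles, trans
edges force separation); a diploid genotype must 2-color the trans graph, so
an odd cycle raises an inconsistency error.  Genotype strings follow HGVS
conventions: `c.[a;b];[c]` when resolved, `(;)` between groups when not;
within a complex allele the causative variant is printed first.

**Annotation and severity.** Mutation classes and in-silico votes are
catalog/fixture inputs, not computed.  Consensus pathogenicity: asserted iff
≥ 5 of the 7 missense tools vote damaging (unavailable verdicts count in the
denominator only); in-frame indels use a 2-tool panel requiring unanimity.
Severity: *mild* iff any allele carries a class IV–V causative variant
(residual function is dominant for the pancreatic phenotype); *severe* iff
at least two alleles are each anchored by classed causative variants, all of
class I–III; otherwise unclassified.  Variants with population frequency
> 5% are excluded from the causative candidate set but retained as
complex-allele annotations.

**Cohort statistics.** Associations are two-sided Fisher exact tests
(scipy; an independent hypergeometric-enumeration oracle backs the test
suite).  Group means are reported with z-based 95% CIs (mean ± 1.96·s/√n,
sample SD) — deliberately *not* t-based: for the 3-carrier weight group
{36, 44, 48} kg the z-CI is (35.8, 49.6), matching the printed 35–49 band,
whereas a t-CI would be (27.5, 57.8).  The two-group location test defaults
to Welch's t; a pooled-variance option exists (with the bundled synthetic
weights the n=3 comparison reaches p < 0.01 only under pooling, as Welch's
df ≈ 2 is very conservative).

## Synthetic data generator

The generator stands in for the raw sequencer output (none was deposited)
and defines the study conditions for all simulation-based checks.

* **Panel fixture.** A synthetic ~8.9 kb reference (not the real CFTR
  sequence; the method is sequence-agnostic) tiled by 33 amplicons of
  172–328 bp with 20 bp primers and 44 bp overlap, so every internal primer
  interval is covered by a neighbouring insert.  Five catalog variants are
  planted: a primer-footprint SNV (the masking showcase), a cis-phaseable
  SNV + 3 bp deletion pair on one amplicon, a 1 bp deletion, and a
  single-base duplication inside a planted (A)7 run.
* **Reads** are full amplicons (two-step amplicon PCR; no fragmentation),
  which is what guarantees same-amplicon pairs are always co-covered.
  Strand labels are Bernoulli(0.5); per-amplicon read counts Poisson.
* **Noise.** Per-base substitutions at 0.002; per-read mean quality
  ~ N(30, 3) with per-base spread 4 (so ≈ 95% of reads survive QC); run
  length stutter offsets drawn from {−2: 6%, −1: 15%, 0: 75%, +1: 4%} at
  every run ≥ 5 bp.  The +1 rate is set so a non-carrier (A)7 site shows the
  (A)8 allele near 4%.
* **Repeat-allele amplification bias.** At a homopolymer site carrying a
  planted length variant, the fraction of reads drawn from the mutant allele
  is sampled once per sample from U(0.25, 0.75).  This reproduces the wide
  observed carrier band (16–42%) while leaving non-repeat heterozygous VAFs
  binomial around 0.5 — which is also what makes perfect PASS recall
  attainable at the 0.20 threshold.  Applying the same imbalance to whole
  amplicons would contradict the observed 100% detection of ordinary
  variants, so it is deliberately repeat-local.
* **Run-resolution mixture.** In cohort simulation, half the samples
  (configurable) have +1 stutter suppressed, emulating run-to-run flow
  resolution variability; pooled non-carrier (A)8 frequencies are then
  bimodal with modes at 0 and ~4%.  Single-sample simulation uses the
  stutter map verbatim so the χ² goodness-of-fit invariant is exact.
* **Primer physics.** A read's bases inside its own amplicon's primer
  intervals always show the reference; template variants there are
  overwritten.  The masking-rescue scenario gives the primer-bearing
  amplicon a 2.5× amplification factor (coverage in this assay class varies
  by orders of magnitude), which puts the unmasked VAF near 0.14 — below
  threshold — while the masked VAF is binomial around 0.5.
* **Artifacts.** Recurrent artifacts are 1 bp deletions injected at
  read level in 85% of samples at per-sample VAF ~ U(0.05, 0.15), at
  positions chosen away from homopolymers and placed variants.
* **Determinism.** One global seed; per-sample streams are derived by
  hashing the sample id, so any subset of samples is reproducible
  independently.  Identical seeds give byte-identical outputs.

What the generator does *not* model: flow-space signal (stutter acts on the
base sequence only), coverage dropout and the orders-of-magnitude
inter-region variance that defeats CNV calling (CNVs enter as an external
table, as in the assay), chimeric reads, alignment error (placements are
truth), and index hopping.  Passing simulation-based tests therefore shows
the *logic* of masking/thresholding/phasing is correct under the declared
noise model, not that the thresholds are optimal for any particular
instrument run.

## Problem sizes used in tests and the acceptance script

Cohort-table statistics run on the bundled 84-patient table.  The masking
mechanism uses 20 replicate simulations at 200 reads/amplicon; homopolymer
discrimination uses depth-500 spectra (500 non-carrier + 20 carrier samples
in the test suite; 200 + 10 in the acceptance script) — depth 500 is where
the assay's median coverage region operates, and the test suite also checks
that discrimination degrades honestly at depth 50.  Caller/phasing
correctness uses 20-sample cohorts with 6 shared het SNVs, one cis and one
trans same-amplicon pair, 4 duplication carriers and 37 planted artifacts at
150 reads/amplicon (10 seeds in the test suite, 3 seeds of 12 samples in the
acceptance script).

## Numerical choices and degenerate inputs

Fisher tests on tables with a zero margin return p = 1 (flag never set).
VAF denominators are usable depth (both strands, post-mask, post-cap).
Multi-allelic columns report every emittable allele, ordered by descending
support then allele string.  Spectrum calling requires total informative
depth ≥ 2 × 15; below that the site is an explicit no-call.  CI with n = 1
is undefined and flagged rather than NaN-propagated.  Empty inputs produce
empty outputs plus zero-count manifests, never errors.

## Known limitations

* Mutation classes, vote grids beyond the explicitly reported rows, and
  per-patient numeric phenotypes are synthetic reconstructions constrained
  to published aggregates; only the genotype table itself is transcribed.
* The recurrence definition (75% of samples + median VAF, or recurrent
  hp-adjacency) is this package's operationalization of a filter whose
  original criterion was not published.
* Deletion-side homopolymer carriers are only callable when their excess
  over the 15% deletion-stutter baseline is overwhelming; weak deletion
  signals are surfaced explicitly as non-discriminable rather than silently
  miscalled.
* BAQ-style quality recalibration is not reimplemented; masked-quality
  pileups stand in.
* No genotype likelihoods, no CNV calling from coverage, no multi-gene
  panels, no population phasing.
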