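# Methods

This note documents the models and procedures implemented in
`exitron_scan`, the assumptions behind them, the tunable parameters and
their defaults, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate model

All internal coordinates are 0-based half-open on the forward genomic
strand; conversion to the 1-based closed conventions of GFF3/VCF happens
only in the readers/writers. A splice-junction interval spans exactly the
intronic bases, so the donor dinucleotide occupies `[start, start+2)` and
the acceptor `[end-2, end)` on the coding strand; this matches common
junction-extractor output and makes dinucleotide checks index-free.
Transcript models store exons and CDS in transcription order. When a gene
has several isoforms, analysis uses the longest-CDS transcript
(`gio.select_transcripts`), ties broken by transcript id; the choice is a
package convention, configurable by passing a different model list.
Transcripts whose spliced CDS length is not a multiple of 3, or whose
annotated CDS phase disagrees with the cumulative frame, are flagged in
`TranscriptModel.flags` rather than dropped.

## Exitron discovery

A junction becomes a candidate only if its interval lies strictly inside
the CDS portion of exactly one exon of the selected transcript, with at
least 1 nt of margin at both ends. The margin is a deliberate design
choice: a 0-margin event shares a splice site with the exon boundary and
is by definition an alternative 5'/3' splice-site event, not an exitron.
Junctions identical to annotated introns are intron-retention evidence and
are excluded (`annotated_intron`), as are boundary-sharing
(`shares_boundary`), multi-exon-spanning (`multi_exon_span`) and
strand-conflicting junctions.

Signal validation requires donor `GT` (a `{GT, GC}` set is available
behind `allowed_donors`) and acceptor `AG` in transcription orientation,
plus stop-freedom of the host reading frame inside the interval (codons
wholly contained in the interval, frame taken from the CDS offset of the
5' end). Evidence thresholds default to `min_junction = 3` reads in at
least one sample and `min_inclusion = 3` mean coverage in at least one
sample; these are package defaults, not published cutoffs, and are
surfaced as configuration. Inclusion evidence is the mean per-base
coverage over the first and last 10 intronic bases: exclusion reads jump
the interval entirely, so coverage there isolates the unspliced isoform.
The window is configurable and is shrunk (with a warning) for exitrons
shorter than two windows. Candidates with junction support but no
inclusion anywhere are reported separately as unannotated constitutive
introns rather than silently dropped. Overlapping distinct exitrons in one
exon are all reported; there is no winner-takes-all. Called exitrons get
deterministic ids in (contig, start, end) order, making calls invariant
under permutation of input rows.

## PSI and differential splicing

PSI measures exitron inclusion: `100 · I / (I + E)` with `I` the
boundary-interior coverage mean and `E` the exact-interval junction count.
Records with `I + E < min_total` (default 10) carry a value but are marked
non-informative and are ignored by the differential step. ΔPSI is max −
min over informative samples (a pairwise mode would be equivalent for the
max; the max–min form needs no reference sample), with the differential
flag at ΔPSI ≥ 15 and detection defined as PSI ≤ 90 in a sample. The
estimator is a documented stand-in for read-level quantification: it is
unbiased under the generator's evidence model (binomial exclusion counts,
uniform coverage) and recovers planted PSI to < 3 percentage points mean
absolute error at depth 500 (verified by the acceptance script), but real
coverage is not uniform and real junction extraction has its own biases.

## Consequence classification

Splicing an EIx3 exitron removes `length/3` codons; the record carries the
1-based deleted-aa interval and partial-codon flags for boundaries that
split codons. For frame-aligned EIx3 (the generator's planting mode) the
full-length protein minus the deleted interval equals the spliced-isoform
protein exactly. For non-EIx3 exitrons the spliced CDS is translated and
the first stop at/after the new junction is located. NMD candidacy uses
the 50-nt rule — the PTC must lie strictly more than 50 nt upstream of the
final exon–exon junction of the spliced transcript — with two documented
choices: the exitron's own splice junction counts as a junction (it is
one, post-splicing), and the distance is measured from the 3' end of the
stop codon. The rule is a standard, testable criterion for NMD
sensitivity, not a decay measurement; the category is named
`ptc_nmd_candidate` to avoid overclaiming. Frameshifts that reach the end
of the CDS without a stop are reported as `altered_cterm` with a
`stop_loss` flag.

## Splice-site PWMs and SNP impact

Donor and acceptor models are additive log₂-odds PWMs trained on the
windows of annotated constitutive introns: donor −3..+10 (3 exonic, 10
intronic bases), acceptor −14..+3. These windows follow common
splice-model practice and are configurable. The background is the
training windows' marginal base frequencies by default (uniform
available); pseudocount 1. The normalised score is min–max scaled,
`(s − s_min)/(s_max − s_min)`, which is bounded in [0, 1] and assigns the
training consensus exactly 1; plain `s/s_max` is not bounded when
log-odds are negative. Branch-point scoring is a descriptive best-match
scan for the CTRAY consensus in the acceptor −50..−10 window and is never
used as a filter.

SNP impact on a splice signal is the column log-odds difference
alt − ref at the variant's window offset (strand-aware, complementing
alleles on minus-strand genes). Because the model is additive this equals
the full-rescore difference exactly — a property the tests assert to
1e-12, the residue being float summation order. Direction is thresholded
at 0.1 bits (`neutral` below). Codon positions of coding SNPs are
(CDS offset mod 3) + 1, strand-aware, tested against the uniform null
with a chi-square goodness-of-fit.

## Motif and protein-feature enrichment

Motif scanning reports every matching start offset on the sense strand
(exitrons are mRNA-resident; antisense scanning is off by default), with
IUPAC degeneracy expanded positionally. Enrichment uses a per-position
Bernoulli null: the background per-position hit rate `q` feeds an exact
binomial upper tail for the target hit count. The approximation ignores
overlap dependence between nearby positions; a per-sequence (≥ 1 hit)
unit is available as an alternative. Zero background hits floor `q` at
`1/(2·positions)` with a flag. Calibration is part of the acceptance
suite: with target and background drawn i.i.d., the p-values pass a KS
test against Uniform(0, 1) over 200 seeds at α = 0.01 — note this
requires a background substantially larger than the target, since the
null treats the estimated `q` as known.

Protein-feature tables (domains, disordered regions, SLiMs, PTM sites)
are consumed as precomputed TSVs; the predictors that make them (HMMER,
disorder/SLiM predictors) run upstream and are out of scope. Exitrons map
to the amino-acid interval covering every codon with at least one
exitron nucleotide. Enrichment between exitron-coded and exon-coded
residues uses per-residue rates (feature-covered aa / total aa) — the
length-corrected unit — with an exact binomial and BH correction across
feature kinds. Domain-border coincidence uses a ±5 aa tolerance by
default; the tolerance is a package choice (related intron-position
analyses in the literature use "exact or ≤ 10 nt").

## The synthetic-data generator

`synthio` emulates the statistical structure the analysis assumes, not
sequencing itself. Genes are laid on one contig with alternating strands
and intergenic spacers; each is a valid ORF (ATG..stop, no internal
stops) built codon-wise with GC targeting by nucleotide sampling
(defaults: exons 0.44, exitrons 0.38, introns 0.32 — exitron GC between
intron and exon GC, the contrast the feature statistics rely on).
Planted exitrons start `GT`, end `AG`, carry no in-frame stop (a
single-pass patcher replaces any stop's free base with `C`, which no stop
codon contains), and are placed codon-aligned with ≥ 12 nt margins.
Codon alignment is a deliberate planting choice: it makes the EIx3
internal-deletion equivalence exact, which the acceptance suite asserts;
mid-codon EIx3 events are still handled by the classifier (partial-codon
flags) but are not planted by default. The EIx3 share (default 0.458)
and intronless-host share (default 0.189) are hit exactly after rounding
— these defaults are the catalog composition reported for Arabidopsis,
so the generated study reproduces that composition by construction, not
by measurement. PSI defaults are high ((60, 95) per tissue sample),
reflecting that exitron-containing isoforms are the major transcripts.

Evidence per sample: exclusion junction counts are
`Binomial(depth, 1 − PSI/100)`; coverage is `depth` over exons, the
inclusion count inside the exitron, and annotated introns get full
junction support so the caller can train PWMs. Every draw flows from the
study seed (per-sample seeds derive from it via a CRC of the sample
name, kept below 2³¹), and regeneration is byte-identical. SNP planting
fixes the codon-position distribution exactly after rounding and places
a configurable fraction inside the 6-nt donor/acceptor signal spans;
colliding positions are deduplicated deterministically with a warning.

What the generator does **not** model: read-level artefacts (FASTQ,
sequencing error, mapping bias), library normalisation, overdispersion
beyond binomial counting noise, non-uniform coverage, multiple isoforms
per gene, UTRs (CDS equals exons), multiple exitrons per exon (a test
fixture, not a default), and GC-content covariation with coverage.
Passing tests therefore demonstrate correctness of the *logic* under a
clean evidence model — perfect recall/precision on noiseless evidence is
a property of the caller's definition matching the generator's, and says
nothing about sensitivity on real libraries with ragged coverage.

## Problem sizes and numerical choices

The shipped study runs at 200 genes / 100 planted exitrons / depth
100–500 with two or three samples — sizes chosen so a full pipeline run
and the entire test suite complete in well under a minute while leaving
≥ 100 events per statistical check. Ties in catalog ordering break by
(contig, start, end, id). Degenerate inputs are errors, not silent
results: empty sequences for GC, zero-evidence PSI records, features
with inverted coordinates, out-of-bounds genome access. Chi-square and
MWW tests come from scipy, binomial tests from `scipy.stats.binomtest`
(exact tail summation; the unit tests compare against an independent
exact-rational enumeration), BH correction from statsmodels.

## Known limitations

- The PSI estimator conflates coverage units with read counts; it is
  consistent under the generator's model but is not a read-resampling
  estimator.
- NMD candidacy is a rule, not a measurement; true decay depends on
  factors the 50-nt rule ignores.
- The per-position motif null understates variance when the background
  is small relative to the target.
- Discovery assumes one analysis transcript per gene; exitron calls on
  minor isoforms require passing those models explicitly.
- Branch-point scoring is descriptive; no lariat model is implemented.
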