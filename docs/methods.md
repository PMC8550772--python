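# Methods

## The read model

A rolling-circular-reverse-transcription (RCRT) library turns each circular
RNA into amplicons of the form

```
second strand:  P2 + T24 + (rolling copies of the circle, starting anywhere) + rc(N6) + rc(P1)
first strand:   reverse complement of the above (begins with P1)
```

with P1 = `GTCGACGGCGCGCCGGATCCATA` (23 nt), P2 =
`ATATCTCGAGGGCGCGCCGGATCC` (24 nt), and a 24-T anchor tract after P2. The
number of rolling copies is a real number >= ~0.5; the terminal copy is
truncated mid-sequence. The simulator reproduces this architecture exactly
and corrupts reads with an indel-dominated error model (default 3%
substitutions, 3% insertions, 2% deletions, ~8% total — mid-accuracy
nanopore reads; per-base qualities are emitted so the mean read qscore
reflects the simulated accuracy). Copy numbers are drawn geometric with
mean ~2.5, giving reads of roughly one to a few kilobases for typical
circle sizes; this distribution is a simulator parameter, not a fitted
quantity. A configurable fraction of reads carries truncated terminal
primers (default 5%) to exercise the strand classifier's hard cases, and a
small fraction (default 2%) is drawn at ~25% error to fall below the
quality cutoff.

## Detection

**Cleaning.** Reads with mean qscore below 7.0 are discarded (mean qscore is
the Phred transform of the mean per-base error probability, the basecaller
convention). Terminal primer matches (edlib infix alignment, identity >=
0.75 over the primer length, within 150 nt of a read end) are trimmed
together with the adjacent poly-T/poly-A tract; an internal
reverse-oriented/forward-oriented primer pair within 50 nt marks a chimeric
junction and splits the read. P1 and P2 share a restriction-site core, so
overlapping hits are resolved to the highest-identity one. The untrimmed
read is kept alongside because the strand features are defined on the raw
100-nt flanking windows.

**Alignment.** The built-in spliced aligner uses exact 11-mer seeds over a
hash index (k-mers occurring more than 60 times are masked), banded
collinear chaining (indel band 40 nt; splice jumps up to 50 kb cost 2.5 k so
that no single chance seed can extend a chain; query gaps > 200 nt break
chains), and exon-block construction with junction placement by match-count
scan: every split of the inter-anchor query bases between the two reference
sides is scored, with a bonus for a canonical splice motif (GT/AG, or CT/AC
for minus-strand genes) and a +/-6 nt slack window because anchors can
overrun a junction when the flanking bases are coincidentally homologous.
Terminal blocks with edlib identity < 55% are trimmed. Query-overlapping
secondary chains are kept down to 0.5x the overlapped chain's score;
query-disjoint pieces (the rolling copies) are all kept. A SAM text adaptor
(pysam) round-trips these alignments so an external spliced aligner can be
substituted at scale.

**CCR detection.** Segments of one read are clustered into loci (same
chromosome within 1 Mbp). A chiastic pair — a later-in-query segment
restarting at or before an earlier segment's reference start, with
overlapping spans — marks a candidate circRNA read; the pair boundaries give
the rough BSJ (acceptor = downstream-in-query segment start, donor =
upstream-in-query segment end), and copy count = aligned query length /
circle span, so sub-two-copy chiastic reads still register. Reads visiting
two distant loci in an A-B-A pattern become fusion candidates; more than two
loci is an unresolvable chimera.

**Junction correction.** Per read, every chiastic crossing is re-placed at
base resolution with the junction scan above (motif bonus 2.5 — equivalent
to realigning the read across the seam of a pseudo-reference built from the
candidate). Candidates are clustered (tolerance 20 nt on both ends) and each
cluster corrected by priority: annotated exon boundaries on both ends within
10 nt of the evidence mode, else the motif-bearing position pair that the
most reads voted for exactly, else the mode itself. Clusters containing two
distinct well-supported junctions (e.g. an annotated and a novel acceptor 15
nt apart) are sub-split by snapping each exact position with >= 2 reads and
regrouping members to the nearest representative; clusters that correct onto
the same junction merge. The correction is idempotent. FSJs (inter-block
gaps >= 30 nt inside the span) snap to annotated splice sites within 10 nt,
else to the cohort's modal junction; annotation is never overridden by the
cohort vote.

**Isoform construction.** Each read's rolling copies vote per corrected
junction; a junction is accepted when strictly more than half of the copies
that fully contain its position show it (ties keep the exon — the
conservative choice). Partial terminal copies vote only on junctions inside
their extent. Isoforms identical in BSJ and exon chain aggregate across
reads; cRG-derived detections merge with RG detections, counting each read
once.

**cRG mode.** Reads without an RG detection go through self-correction: the
tandem period is the dominant spacing of repeated 9-mers (histogram smoothed
over +/-3 nt to absorb indel drift, harmonics reduced, refined by
self-overlap identity), copies are segmented by successive alignment of the
first copy, and the monomer is the per-column majority base across copies
(ties resolved by summed base quality), with insertion runs seen in more
than half the copies spliced in. Monomers failing the internal-repeat screen
(+2/-5/-7 repeat alignment score > 40, or repeat span > half the monomer)
are removed; survivors are triplicated and re-fed to RG detection.

## Strand

An FSJ whose genomic motif reads GT..AG implies a plus-strand transcript
(CT..AC minus); combined with the read's aligned strand this labels the read
first- or second-strand (`second_strand` = read is transcript-sense — the
convention used throughout). A 100-tree random forest on the twelve
primer-identity features (Smith–Waterman, match +2 / mismatch -4 / gap open
-4 / extend -2) is trained on a stratified 75/25 split of the labelled CCRs
and applied to all reads. Isoforms with canonical BSJ motifs keep the
motif-derived strand; non-canonical isoforms take the majority predicted
transcript strand of their reads, with ties flagged ambiguous.

## Filters

* **Unsplicing ratio** — back-spliced reads / (back-spliced + reads whose
  single exon block runs continuously across either BSJ boundary with >= 10
  nt on each side); below 0.1 the locus is a linear-residual artifact and is
  dropped (0.1 itself is kept). This reading — back-splice share of the
  locus-informative reads — is the implemented default; an alternative
  reading (fraction of supporting reads without splice motif) is noted but
  not default.
* **Junction fidelity** — for every junction of an isoform, strictly more
  than half of its reads must align edit-free within +/-4 bases. A read
  passes a junction if at least one of its rolling passes does (each pass is
  an independent observation); each crossing is checked separately against a
  junction context built from the *spliced* circle sequence (genomic flanks
  would diverge inside short terminal exons), clipped to the context the
  read can actually cover so crossings near read ends stay measurable.
* **Repeat proximity** — dropped only when *both* BSJ ends are within 30 bp
  (inclusive) of a repeat-track interval.
* **Genomic tandem filter** — the circle span is scanned for internal
  tandemness (k-mer spacing candidates verified by match-run coverage); a
  period >= 30 nt with >= 1.2 copies covering >= 80% of the span means the
  rolling signature could come from reference repeats, and the isoform is
  dropped.

The three read-evidence filters are pure predicates and commute.

## Classification, AS events, quantification

Type ladder (first match wins, strand-concordant where applicable):
read-through (BSJ ends in two distinct same-strand genes) > exonic (both
ends at annotated exon boundaries within one gene) > intronic (inside a
single intron) > novel splice site (inside a gene, >= 1 novel boundary) >
novel UTR (gene overlap but extension past the terminal exon) > antisense
(opposite-strand overlap only) > intergenic. "Novel UTR" is defined by
extension past the annotated terminal exon, not by annotated UTR records.

AS events are pairwise comparisons of exon chains sharing a BSJ: ES (an
internal exon absent from the partner, flanking junctions shared), A3SS /
A5SS (one intron boundary shared, the other shifted; 3'/5' assigned on the
transcript strand), IR (an intron of the spliced form exonic in the partner
whose block spans exactly the two flanking exons — the "identical outer
boundaries" reading). Events deduplicate by (type, coordinates).

Isoform count = full-length supporting reads; BSJ count = sum over its
isoforms; transcript ratio = isoform count / BSJ count (sums to 1 exactly);
the high-quality flag requires >= 5 reads. Count matrices are exported for
external differential testing, which is out of scope here.

## Fusion circRNAs

Candidates require the full A-B-A alternation (>= 1.5 monomer copies) and
locus separation of different chromosomes or strictly more than 1,000,000 bp.
Both junctions are re-placed per read by the two-reference junction scan,
snapped per read to annotated exon boundaries, clustered (tolerance 20 nt)
and corrected to the annotation/cohort mode. Loci are reported in canonical
genomic order regardless of which locus a read entered first. Isoforms
sharing a junction pair but differing in internal structure are kept
separate; internal junctions that are neither annotated nor present in a
majority of cluster members are treated as alignment noise and merged away —
novel (unannotated) internal fusion splices supported by a minority of reads
are therefore not separated, a known limitation. Which junction is the
genomic fusion and which the back-splice is not decidable from reads alone;
both are reported symmetrically. Transcript ratios are computed within each
junction pair.

## What the simulator does and does not emulate

It reproduces the amplicon architecture, fractional rolling copies, both
cDNA orientations, primer truncation, chimeric read concatenation, linear
residual reads, low-quality reads, planted canonical splice motifs for
every truth class, tandem repeats in the genome, and an indel-dominated
error model. It does not emulate basecaller-specific error structure
(homopolymer compression), PCR duplicates, expression-linked length biases,
or genomes with realistic repeat families; passing tests therefore
demonstrate the algorithmic correctness of each stage under controlled
conditions, not performance on any particular instrument's error profile.
Truth classes that plant novel splice motifs reserve their spans so that
later truths cannot mutate an earlier truth's frozen sequence.

## Numerical choices and degenerate inputs

All internal coordinates are 0-based half-open; BSJs are stored
genome-ordered with the strand carried separately. Correction ties break
toward annotation, then the modal read position, then leftmost. Circles
shorter than the 150-nt pseudo-reference flank use the circle span as the
flank (the read context around the junction of a short circle is circle
sequence, not genomic flank). The spec alternative pseudo-reference
construction (whole span +/- flank) is not implemented; the donor-flank +
acceptor-flank form is used throughout. Empty inputs return empty results;
an empty alignment query, a consensus on an empty monomer, and invalid
generator sizes raise `ValueError` with a message. One global seed fans out
to per-stage seeds by CRC-32 hashing of the stage name, so stages are
reproducible independently; simulation is byte-deterministic for a fixed
seed.

## Benchmark problem sizes

The evaluation module runs the pipeline at desk scale: a 2 x 250 kb genome
with 40 genes and 200 mixed-class truths at 20x mean depth for end-to-end
recovery (~4,600 reads); a quarter-size error-free library for the
exactness check; 1,000 synthetic tandem reads for the consensus/oracle
comparison; a 2.6 Mb + 200 kb genome for inter- and intra-chromosomal
fusion sets. These sizes exercise every code path while a full benchmark
run stays within minutes on one CPU. Recovery is measured over truths with
at least 5 usable reads and mean rolling copies >= 1.5 — circles below that
support level are not expected to be reliably reconstructable by any
method reading single-pass evidence.

## Known limitations

Junction placement is ambiguous when the bases after the donor equal the
bases at the acceptor start (the junction can shift by the homology length
with identical alignment score); annotation resolves this for annotated
boundaries, but a few percent of novel-boundary circles land on a shifted
position carrying a chance motif. Low-copy reads (< 1.5 rolling copies)
provide a single junction observation, so the strict +/-4 bp fidelity
majority can drop genuinely present but weakly covered circles. The
unsplicing ratio's definition is an interpretation (see above). The strand
of circRNAs without FSJs, canonical motifs, or intact primers remains
ambiguous and is flagged rather than guessed.
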