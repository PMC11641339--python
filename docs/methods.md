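# Methods

This note documents the models, defaults and design choices behind the
package, what the synthetic generators do and do not emulate, and the known
limitations. All internal coordinates are 0-based half-open; conversion to
the 1-based conventions of SAM/GTF happens only at the I/O boundary.

## Locus model and packaged architectures

A locus is an ordered set of non-overlapping exons with a domain label per
exon (`leader`, `VNAR`, `hinge`, `C1`..`C5`, `tail`). The two packaged
architectures follow the expressed nurse-shark IgNAR loci: a ten-exon locus
(leader, VNAR at exon 2, a short hinge connector at exon 3, one exon per
constant domain C1–C5 at exons 4–8, two tail exons) and a nine-exon locus
identical except for the missing hinge (C1–C5 at exons 3–7). Exactly one
exon carries the VNAR and each constant domain maps to at most one exon.
The `hinge` label exists because the ten-exon architecture requires a
connector exon between the VNAR and C1 that is neither leader nor constant
domain.

Exon and intron lengths are not architectural constants, so they are
declared defaults rather than inferred: constant-domain exons are 99 codons
(105 for C3, which carries the six-residue C3–C4 linker at its 3' end), the
VNAR exon is 110 codons (330 bp), and introns are drawn uniformly from
300–2000 bp unless configured explicitly. Coding exon lengths are all
multiples of three (phase 0), which is what makes every exon-skipping chain
— including the C4+C5-skipping short form — preserve the reading frame; a
configured constant-domain exon length that is not a multiple of three is
rejected as an inconsistent architecture.

The synthetic locus is built protein-first: leader, VNAR (framework
templates below), constant domains with planted cysteines (offsets 21 and
87 in each domain, plus a middle cysteine at offset 54 in C1, plus an
optional linker cysteine), and tail are designed as amino-acid strings and
back-translated with random synonymous codons, so the designed frame
translates without internal stops by construction. Introns receive GT/AG
dinucleotide ends. Leader structure, tail exon content and UTR lengths are
declared defaults (20-residue leader, 30/24-residue tail exons, 30/60 nt
UTRs, 500 bp flanks).

## Isoform fixtures

Isoform identity here is the junction chain — the ordered list of
(donor end, acceptor start) pairs of a transcript. The ten-exon fixture
packages eleven distinct chains: six full-constant-domain variants (hinge
exon included or skipped, crossed with three tail-exon usages) and five
short forms skipping exactly the C4 and C5 exons. The nine-exon fixture
packages four chains (full length, tail-exon variants, one short form).
The specific exon combinations beyond "short forms lack exactly C4+C5" are
package choices; what is fixed is the chain count (11 and 4), the exon
counts (10 and 9), and the short-form rule.

## Spliced-read simulation: full-length-capture evidence model

`simulate_spliced_reads` emits one spliced alignment per fragment running
from a random offset inside the chain's first exon to a random offset
inside its last exon, covering every splice junction of the isoform —
full-length cDNA-like evidence rather than short random transcript windows.
This is deliberate: the collapse step groups fragments by *identical*
junction chain, so the isoform count is recoverable exactly only when each
fragment carries its isoform's complete junction signature. Fragment counts
per isoform are multinomial in the abundances; `read_len` acts as the
minimum fragment span and must not exceed the shortest isoform. The
simulator does not model short-read fragmentation, sequencing errors in
transcripts, intron retention or novel junctions; recovering isoforms from
partial junction evidence (transcript assembly proper) is out of scope.
Consequences for interpretation: passing the planted-recovery tests shows
the collapse/assignment machinery is exact on clean full-span evidence, not
that it would assemble isoforms from real short-read RNA-seq.

## Genomic read simulation and gap assembly

Paired-end reads are sampled uniformly with pair count
coverage × L / (2 × read length); the forward mate starts at the fragment's
left end and the reverse mate is the reverse complement of its right end
(insert size fixed by default, optionally normal with a configured sd).
Errors are substitutions only, at a flat per-base rate; base qualities are
constant maximum, and indel errors are not modelled. Alignments are emitted
against the ungapped truth so that pairs straddling a masked gap exist.

The gap assembler seeds a contig with up to 50 bp of known left-flank
sequence, then repeatedly gathers all reads whose prefix overlaps the
contig suffix by at least `min_overlap` (default 30 bp) with at most
`max_mismatch` (default 1) mismatches; appended bases are decided by
majority vote among the candidates, with ties resolved toward the candidate
with the longest overlap, then the lexicographically smallest read name,
then the lexicographically largest base — fully deterministic. Extension
stops when the first `min_overlap` bases of the right flank appear in the
contig (success), when no candidate exists (unfillable on the first step,
unjoined later), or when the contig has grown past
gap length + 4 × read length (unjoined). Defaults (`min_run` 10,
`flank_window` 500 bp) scale with the synthetic read length. SAM stores
sequences in scaffold orientation, so reverse-strand mates need no
re-complementing. The assembler is for localized N-gaps with unique
flanking sequence; repeat resolution and de novo assembly are non-goals.

## Translated search

Each of the six frames is translated with the standard code (codons
containing non-ACGT become X, stops are kept as `*`) and split at stop
codons; every stop-free segment of at least 12 residues is aligned locally
against the protein query. Stops naturally fragment intergenic sequence, so
this replaces heuristic seeding while keeping the search exhaustive at desk
scale. Scoring is BLOSUM62 with BLAST-convention affine gaps (a gap of
length k costs 11 + k, i.e. open 11 / extend 1); the aligner backend
charges open on the first gapped position, so the mapping is
open_gap_score = −12, extend_gap_score = −1. Residues outside the matrix
alphabet are treated as X. Hits at or above `min_score` (default 60) are
single-linkage clustered along the genome with `max_cluster_gap` (default
50 kb, chosen so intron-fragmented hits of one locus merge while separate
loci stay apart); clusters are labelled left to right. E-value statistics
and nucleotide-level search are non-goals.

## Isoform reconstruction and FPKM

CIGAR M/D consume reference into the current block, N closes a block, S/I
consume none; junction chains are compared exactly (0 bp boundary
tolerance — exactness is testable on synthetic data; a tolerance would be
needed for noisy aligners). Fragments grouped by identical chain with
support below `min_support` (default 2, filtering singleton chimeras) are
dropped; junction-free fragments form a single unspliced class. Junctions
internal to the VNAR exon would appear as novel junctions rather than
isoform signatures, matching the treatment of the variable region as a
single exon. FPKM is fragment-level: fpkm = fragments × 10⁹ /
(total fragments × exonic length). The short-form call requires C4 and C5
both absent with C1–C3 present; skipping only one of C4/C5 is flagged
atypical instead. Probabilistic multi-mapping quantification is a non-goal.

## VNAR scheme, repertoire generator and typing

The positional scheme fixes region lengths FR1 25, CDR1 8, FR2 10, HV2 8,
FR3a 16, HV4 6, FR3b 15 (total 88 residues from FR1 through FR3b), with
canonical cysteines at FR1 offset 21 and FR3b offset 10, and locates FR4 by
the anchor pattern `[YW]G.G` (FR4 length 10). These per-region lengths are
package defaults — what is structurally fixed is only the constancy of the
FR1→FR3b total — so schemes are fully configurable and every annotation
records its scheme. A sequence without an anchor match keeps CDR3 to the
terminus and is flagged; missing canonical cysteines downgrade the call to
unclassified with diagnostics.

The repertoire generator mutates only CDR1/HV2/HV4, substituting uniformly
over the non-identical amino acids but never introducing cysteine, and
protects the configured noncanonical cysteine positions (FR2 offset 7 or
CDR1 offset 3) so the cysteine census stays controlled by configuration.
CDR3 length and cysteine count are drawn from configured discrete
distributions; CDR3s that would create a premature FR4-anchor match are
redrawn, since the anchor is a framework motif and a chance match would
shift the planted CDR3/FR4 boundary. The generator emulates repertoire
diversity as independent per-position substitution; it does not model
somatic lineage structure, indels, or biased amino-acid usage, so census
tests demonstrate estimator correctness, not biological realism.

Typing is a pure function of cysteine placement: type I = FR2 cysteine plus
≥2 CDR3 cysteines (bonds FR1–FR3b, FR2–first CDR3 cysteine, last CDR3
cysteine–FR4; if FR4 lacks a cysteine the third bond's partner is the FR4
anchor position, flagged unconfirmed, keeping the type-I bond count at
three); type II = CDR1 cysteine plus ≥1 CDR3 cysteine (bonds FR1–FR3b,
CDR1–CDR3); exactly the two canonical cysteines = canonical-only (one
bond). Cysteines in both FR2 and CDR1 are ambiguous and left unclassified
with both candidates listed. Only types I and II are computed; other
patterns map to canonical-only or unclassified rather than guessing
definitions for further types.

## Disulfide geometry

Bond detection collects cysteine SG atoms (PDB fixed-column records via
Bio.PDB; insertion codes are preserved in the residue key) and applies
greedy nearest-pair matching among all pairs within the threshold (default
2.5 Å on the SG–SG distance; a formed disulfide is ~2.05 Å), ties broken by
chain then residue number, each sulfur in at most one bond, distances
reported to 0.01 Å. Classification against per-chain residue-interval
domain maps yields intra-domain, inter-domain (flagged) or inter-chain
classes; expectation flags fire when a constant domain lacks an internal
bond or a linker cysteine's bond is not inter-chain. Energy evaluation,
structure prediction and confidence-score handling are non-goals.

## Problem sizes and tolerances

The test and acceptance workloads use 10,000 spliced fragments per fixture
(isoform recovery), 20 random 3 kb scaffolds with a planted 200 bp gap at
30× error-free coverage (gap recovery), 200 random peptide pairs of length
≤25 against an independently written quadratic Gotoh dynamic program
(alignment oracle), 2000-sequence repertoires with a ±0.03 tolerance on
census fractions (binomial sd at n = 2000 and p = 0.7 is ≈0.010, so ±0.03 is
a ≈3σ band), and random sulfur clouds of up to 50 atoms against an
all-pairs brute-force matcher. Determinism throughout comes from
numpy.random.default_rng seeded explicitly; identical seeds reproduce
byte-identical FASTQ/SAM output.
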