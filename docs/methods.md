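# Methods

This note documents the models and procedures implemented in `unitrans`, the
choices made where the design was genuinely open, and what the synthetic data
does and does not establish about real data.

## Problem setting

PacBio Iso-Seq yields full-length cDNA consensus transcripts without assembly,
which makes transcriptome analysis possible for species with no reference
genome. The catch is that nothing plays the role of the genome: isoforms of
one gene arrive as independent sequences, redundancy is high, and splice
junctions have no coordinate system to live in. The pipeline rebuilds that
coordinate system from the reads themselves: a *UniTransModel* is a
pseudo-reference reconstructed per transcript family, containing the ordered
union of all sequence segments observed across the family's isoforms.
Isoforms and alternative-splicing (AS) events are then defined in model
coordinates, not genomic ones.

Transcripts are assumed oriented (full-length long-read protocols orient by
primer and polyA), so all k-mer work downstream of the corrector is
sense-strand only. All coordinates are 0-based half-open.

## Stage by stage

### Hybrid error correction (`unitrans.correct`)

Long transcripts are corrected against a canonical k-mer spectrum of
high-accuracy short reads. A k-mer is *solid* when its canonical form (the
lexicographic minimum of itself and its reverse complement) occurs at least
`solid_threshold` times. Correction is a greedy left-to-right scan: from the
first solid anchor, the first non-solid window implicates the window's last
base; all single-base substitutions, deletions and insertions are tried and
the edit maximizing the downstream run of solid windows wins (ties prefer
substitution over deletion over insertion, then alphabetic order). An edit is
committed only when it restores a solid run of at least three windows, which
is what keeps correction conservative: on simulated data it never increased
the edit distance to the true isoform in any seeded trial, because an
uncertain position is simply left alone. A second pass over the reverse
complement (valid because the spectrum is canonical) covers errors within the
first k-1 bases, which a forward scan cannot anchor. Defaults: k=17,
solid_threshold=3, at most 5 edits per 100 nt window. The stage is pluggable;
externally corrected FASTA can be supplied instead.

### Redundancy removal (`unitrans.dedup`)

Greedy longest-first clustering with the classic nucleotide-clustering
thresholds: a transcript joins the first representative against which its
best local alignment reaches identity ≥ 0.99 (matches over alignment
columns), covers ≥ 0.99 of the shorter sequence, and leaves ≤ 30 nt of the
shorter sequence unaligned; otherwise it founds a new cluster. Visiting
transcripts by descending length (ties: ascending id) makes every
representative the longest member and the output invariant to input order.
The alignment scheme is fixed and documented (match +1, mismatch −2, gap open
−5, gap extend −1, Biopython `PairwiseAligner` in local mode); the contract
is the threshold test, not any particular tool's banded heuristics. An
infix-edit-distance prescreen (edlib, budget `3(1−c)·len + AS + 5`) skips
pairs that provably cannot qualify; the test suite re-runs the same greedy
rule without the prescreen as an independent oracle.

### Family partitioning (`unitrans.families`)

Isoforms of one gene share exons, so their sets of distinct sense-strand
24-mers overlap heavily, while unrelated transcripts share essentially no
24-mer by chance (collision probability ≈ 4⁻²⁴ per pair of positions).
Similarity is the overlap coefficient |A ∩ B| / min(|A|, |B|) and families
are connected components of the graph thresholded at 0.05. The exact k,
metric and threshold are this package's choices: with k=24 a single shared
exon of ~500 nt between two ~1 kb isoforms already gives similarity ≈ 0.49,
while random collisions stay below 10⁻³, so the band between the threshold
and real signal is wide. Because the canonical (all-exon) isoform shares
sequence with every variant of its gene, gene families are connected through
it even when two variants overlap little with each other.

### De Bruijn reconstruction (`unitrans.reconstruct`)

Each family is built into a compacted De Bruijn graph (nodes (k−1)-mers,
edges k-mers, k=31 by default, odd k in [21, 63]); unitigs are maximal
non-branching node paths and every transcript is re-expressed as a walk over
unitigs. A precedence relation — u before v when u precedes v in some walk —
orders the unitigs.

The model sequence is the **maximum-weight directed path** through the walked
unitig DAG, where a unitig entered along an edge contributes its spelled
length minus the k−2 overlap with its predecessor. The rationale: a
transcript that skips model sequence contributes junction-spanning k-mers,
and those form short "shortcut" unitigs that bypass real content while
contributing at most k−2 novel bases; the content they bypass always
contributes more (the simulator draws every retained segment at ≥ 25 nt), so
the heaviest path walks every retained segment in order and spells the
segment union exactly. Ties break to the lexicographically smallest
unitig-id sequence, and unitig ids themselves are assigned in discovery
order along id-sorted transcript walks, so emission is deterministic and
invariant to input permutation.

When two transcripts imply contradictory segment orders (…AB… vs …BA…), the
precedence graph is cyclic and no single model exists. The largest transcript
subset whose combined walks stay acyclic is peeled off greedily (descending
transcript length, then id), emitted as one model, and the remainder is
recursed — yielding "one or several" models per family.

Known limitation: if the segment union is *not* covered by the observed
walks (some adjacent pair of retained segments is never contiguous in any
transcript), no path spells the union and the heaviest path is the best
available approximation; transcripts outside it still map, but with lower
coverage. The simulator's event realizations are constructed so this does
not arise (see below).

### Spliced mapping (`unitrans.spliced_map`)

Models are built from the very transcripts being mapped, so exact matches
dominate and a full splice-site-aware aligner is unnecessary. Maximal exact
matches ≥ 18 nt (seeded from a 15-mer index of the model) are chained by
sparse dynamic programming (gap penalties: 1.0 per read-gap base, 0.01 per
model-gap base, 0.5 per join), merged into blocks, and model gaps below
25 nt are absorbed as indels. A model gap ≥ 25 nt with a read gap ≤ 10 nt is
a splice junction. No GT–AG motif is required: model "introns" are merely
unaligned model segments, and canonical splice motifs need not appear in
transcript space.

Junction placement is ambiguous when the base before the donor equals the
base before the acceptor; all junctions are therefore **left-normalized**
(shifted to their leftmost equivalent placement), the same convention the
simulator uses for truth chains. Alignments below 50% transcript coverage
are reported unmapped. Identity is matches over alignment columns, computed
per block with edlib.

### Isoform collapsing and AS classification (`unitrans.isoforms`)

Transcripts of one model collapse into one isoform when their junction
chains are identical; coordinate tolerance ε defaults to 0 (exact), with
ε > 0 resolved by single linkage and re-anchoring to the highest-support
member's chain. End differences never create isoforms; chainless
(single-block) transcripts collapse into one "unspliced" isoform per model.

Events between isoform pairs of one model, deduplicated per model by
(type, coordinates):

* **RI** — one chain has junction (d, a); the other has no junction
  intersecting [d, a] and its span covers it.
* **SE** — one chain has (d1, a1),(d2, a2) with a1 < d2; the other has
  (d1, a2).
* **A5 / A3** — two junctions share an acceptor (resp. donor) and differ on
  the other side.
* **AF / AL** — the A5/A3 pattern at the chains' first (resp. last)
  junctions with non-overlapping upstream (resp. downstream) spans.
* Precedence when several rules fire on the same coordinates:
  SE > RI > AF > AL > A5 > A3.

A consequence worth stating plainly: with no genome, an exon skipped between
exonic neighbours produces exactly the RI pattern — one isoform covers, the
other jumps. RI is therefore structurally the most common model-based event
call, which is consistent with what reference-free long-read studies report.
Mutually-exclusive-exon events are not emitted as a separate type; they
decompose into SE/RI-like differences.

### lncRNA identification (`unitrans.orf_lncrna`)

The three-step cascade: (a) remove transcripts with any protein homology hit
at E ≤ 10⁻³ in a user-supplied BLAST-outfmt-6-style table; (b) remove
transcripts whose ORF content suggests unannotated coding potential — any
complete (ATG…stop) ORF > 100 aa, or any open-ended ORF > 50 aa at a
transcript end; (c) remove transcripts the coding-potential scorer labels
coding. The cascade is order-respecting and records per-step provenance.

ORF conventions: `complete` = first ATG of a stop-terminated codon region to
its stop; `open5` = the leading stop-terminated region of a frame (no ATG
required — the start may be lost upstream), emitted unless it begins with
ATG; `open3` = first ATG after a frame's last stop, running off the 3' end;
`open_both` = a frame with no stop at all. "> 50 aa at ends" is interpreted
as any of the three open-ended kinds exceeding 50 aa. Forward frames only by
default (transcripts are oriented); `both_strands` is available.

The scorer is a transparent stand-in for an external coding-potential
classifier, with the same role and a pluggable interface (precomputed labels
can be supplied). It combines four features with fixed z-scaling and unit
weights, labelling *coding* when the sum is ≥ 0:

| feature | center | scale |
|---|---|---|
| ORF coverage of transcript | 0.40 | 0.25 |
| log10(longest ORF aa + 1) | 1.78 (~60 aa) | 0.40 |
| Fickett TESTCODE score | 0.95 | 0.17 |
| in-frame hexamer log-likelihood ratio | 0.05 | 0.20 |

The hexamer table is trained from user-supplied coding/noncoding FASTA
(≥ 10 kb each, in-frame hexamers at codon step, add-one smoothing). The
centers sit near the classic decision region of each statistic (0.95 is the
traditional TESTCODE cut); the scales are fixed design constants, not fit to
any dataset.

### Statistics (`unitrans.stats`)

N50 follows the standard definition (first length, in descending order, at
which the cumulative sum reaches half the total). Full-length ORF coverage
classes over a best-hit-per-query table: *full* = 100% of the curated
protein covered, *near-full* = > 80%, plus a cumulative density on a 0.01
grid. Tissue-specific model matching declares a model *shared* when some
model of the other set aligns at ≥ 90% identity over ≥ 80% of the shorter
sequence (the similarity threshold is this package's choice, surfaced as
flags); alignment machinery is shared with dedup.

## The simulator and what passing tests mean

`unitrans.sim` generates gene regions (random uniform A/C/G/T segments;
defaults: 4–7 exons of 100–300 nt, introns of 150–300 nt), isoform sets
realized by the six event types, substitution/indel noise, and uniform
substitution-only short reads, together with truth tables. Design points:

* The gene's concatenated sequence is rejection-sampled to contain no
  repeated 31-mer, so default-k reconstruction has a unique answer and
  algorithm testing is separated from repeat resolution.
* The union model contains exactly the segments present in ≥ 1 isoform — a
  reconstruction from the transcripts can contain nothing else.
* Event realizations keep the union walk-covered and create genuine
  model-space patterns: SE drops an internal exon (one variant); RI retains
  an intron (one variant); A5/A3 split an intron and emit two variants with
  nested retained prefixes/suffixes of ≥ 25 nt each (so two junctions share
  an acceptor/donor); AF/AL use two variants with alternative first/last
  exons spliced to a common exon, requiring ≥ 4 exons.
* Truth chains are left-normalized, and segment-final bases are recolored
  (a 4-colorable inequality graph) so that no junction placement is
  ambiguous — otherwise chance base equality at boundaries would blur
  shared donors/acceptors.
* Truth *event tables* are computed by applying the classification rules to
  the truth chains. The generative tag (e.g. "SE" for a dropped exon) is
  kept as per-isoform provenance, but the model-space truth for a dropped
  exon between exonic neighbours is RI, and the truth table says so. The
  end-to-end tests therefore validate that the pipeline recovers chains and
  applies the rules through reconstruction and mapping; the correctness of
  the rules themselves is established by hand-derived unit cases.
* Coding/noncoding emulation: `random_coding_mrna` draws a codon-biased
  ATG…stop CDS with short UTRs; `random_noncoding_rna` breaks every
  stop-free run > 30 codons in *all three frames*, making it genuinely
  ORF-poor.

What the simulator does **not** emulate: base-quality structure, 5'
degradation, polyA tails, fusion transcripts, sequence repeats, antisense
transcripts, realistic codon usage of any particular organism, or expression
levels (each isoform appears once unless duplicates are added explicitly).
Passing tests show the algorithms are correct under clean, identifiability-
friendly conditions; they do not show robustness to repeat-rich genes or
degraded reads.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: 50 genes (~130
transcripts, ~1–2.5 kb) for end-to-end recovery, three replicates of the
same size for noise robustness with 50× short-read coverage, 100 + 100
sequences for the lncRNA cascade, and 1000-case oracle sweeps for the
elementary operations. Every stochastic step is seeded; regenerating with
identical arguments yields byte-identical outputs, and pipeline reruns are
byte-identical file for file.

## Known limitations

* Junction-placement ambiguity is resolved by convention (left-normalize);
  real data with repetitive boundary contexts can still merge distinct
  nearby junctions at ε > 0.
* Residual long-read errors that survive correction fork the De Bruijn
  graph; with one transcript per isoform after dedup there is no abundance
  signal to clean them, so an imperfectly corrected transcript can inflate
  its family's model. Mapping absorbs most such cases (observed ≥ 99% exact
  chain recovery at 1% substitution noise), but model byte-exactness is
  only guaranteed for error-free input.
* Greedy acyclic peeling is a heuristic for contradictory segment orders;
  it guarantees determinism and termination, not a minimum model count.
* The dedup prescreen is conservative by a wide margin but is part of the
  implementation, not the contract; the oracle equivalence test is the
  guard.
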