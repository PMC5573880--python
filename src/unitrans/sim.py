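"""Synthetic transcriptome simulator with machine-readable ground truth.

Generates gene regions with exon/intron structure, isoform sets realized by
the six alternative-splicing event types (SE, RI, A5, A3, AF, AL), noisy long
transcripts, and short reads for hybrid correction — together with truth
tables (family membership, union-model sequences, junction chains, event
types) that every downstream stage is tested against.

Two conventions matter:

* The *union model* of a gene contains exactly the segments present in at
  least one emitted isoform, in gene order.  A reconstruction built from the
  transcripts themselves can never contain sequence no transcript carries, so
  pure introns retained by nobody do not exist in model space.
* Truth event tables are computed by applying the model-space classification
  rules to the truth chains.  A generative operation tag (e.g. "SE" for a
  dropped exon) is kept per isoform as provenance, but on a pseudo-reference
  a skipped exon between exonic neighbours *is* a retained-intron pattern,
  and the truth table says so.

All coordinates are 0-based half-open; transcripts are always in sense
orientation.  Every operation is deterministic for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .isoforms import classify_chain_pair

BASES = "ACGT"
UNIQUE_K = 31  # k-mer uniqueness enforced at generation time (default DBG k)
MIN_OFFSET = 25  # A5/A3 boundary offsets exceed the junction-gap threshold
MAX_OFFSET = 50


@dataclass
class GeneRegion:
    id: str
    #: ordered (kind in {"exon", "intron"}, sequence) pairs
    segments: List[Tuple[str, str]]
    rng_seed: int

    @property
    def exon_indices(self) -> List[int]:
        return [i for i, (kind, _) in enumerate(self.segments) if kind == "exon"]

    @property
    def n_exons(self) -> int:
        return len(self.exon_indices)

    @property
    def n_introns(self) -> int:
        return len(self.segments) - self.n_exons


@dataclass
class SimulatedIsoform:
    id: str
    gene_id: str
    included_segments: Tuple[int, ...]
    sequence: str
    truth_chain: Tuple[Tuple[int, int], ...]
    truth_span: Tuple[int, int]
    event_labels: List[str] = field(default_factory=list)


@dataclass
class TruthTable:
    family_of: Dict[str, str] = field(default_factory=dict)
    model_sequence_of: Dict[str, str] = field(default_factory=dict)
    chain_of: Dict[str, Tuple[Tuple[int, int], ...]] = field(default_factory=dict)
    span_of: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    events_of: Dict[str, List[Tuple[str, Tuple[int, ...]]]] = field(default_factory=dict)

    def update(self, other: "TruthTable") -> None:
        for tid in other.family_of:
            if tid in self.family_of:
                raise ValueError(f"transcript {tid} appears twice in truth table")
        self.family_of.update(other.family_of)
        self.model_sequence_of.update(other.model_sequence_of)
        self.chain_of.update(other.chain_of)
        self.span_of.update(other.span_of)
        self.events_of.update(other.events_of)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def make_gene(
    n_exons: int,
    exon_len_range: Tuple[int, int],
    intron_len_range: Tuple[int, int],
    seed: int,
    gene_id: Optional[str] = None,
    max_retries: int = 50,
) -> GeneRegion:
    """Random gene region whose concatenated sequence has no repeated 31-mer.

    The uniqueness guarantee makes De Bruijn reconstruction at the default k
    unambiguous, separating algorithm testing from repeat resolution.
    """
    if n_exons < 1:
        raise ValueError("n_exons must be >= 1")
    for lo, hi in (exon_len_range, intron_len_range):
        if lo < 1 or hi < lo:
            raise ValueError("length ranges must be positive with min <= max")
    rng = np.random.default_rng(seed)
    gid = gene_id or f"gene{seed}"
    for _ in range(max_retries):
        segments: List[Tuple[str, str]] = []
        for i in range(n_exons):
            if i > 0:
                ilen = int(rng.integers(intron_len_range[0], intron_len_range[1] + 1))
                segments.append(("intron", _random_seq(rng, ilen)))
            elen = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
            segments.append(("exon", _random_seq(rng, elen)))
        full = "".join(s for _, s in segments)
        kmers = {full[i : i + UNIQUE_K] for i in range(len(full) - UNIQUE_K + 1)}
        if len(full) < UNIQUE_K or len(kmers) == len(full) - UNIQUE_K + 1:
            return GeneRegion(id=gid, segments=segments, rng_seed=seed)
    raise RuntimeError(
        f"could not generate a gene with unique {UNIQUE_K}-mers after {max_retries} tries "
        "(segments too short or too many exons)"
    )


def _require(cond: bool, event: str, why: str) -> None:
    if not cond:
        raise ValueError(f"cannot realize {event} event: {why}")


def make_isoforms(
    gene: GeneRegion,
    event_spec: Optional[Dict[str, int]] = None,
    seed: int = 0,
) -> Tuple[List[SimulatedIsoform], GeneRegion, TruthTable]:
    """Emit the canonical isoform plus variants realizing the requested events.

    Realizations (per event):

    * SE — drop one internal exon (one variant).
    * RI — retain one intron (one variant).
    * A5 — split an intron into prefix pieces of >= 25 nt; two variants retain
      nested prefixes, so two junctions share an acceptor with distinct donors.
    * A3 — mirror of A5 with nested suffix pieces (shared donor).
    * AF — two variants use alternative first exons (exon 1 vs exon 2) spliced
      to a common downstream exon; needs >= 4 exons.
    * AL — mirror of AF at the last exon; needs >= 4 exons.

    A5/A3 refine the gene's segmentation, so the (possibly re-segmented) gene
    is returned alongside the isoforms and the per-gene truth table.  Every
    adjacent pair of union-model segments is contiguous in at least one
    isoform, keeping the union model reconstructable from the transcripts.
    """
    spec = dict(event_spec or {})
    unknown = set(spec) - {"SE", "RI", "A5", "A3", "AF", "AL"}
    if unknown:
        raise ValueError(f"unknown event types: {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    n = gene.n_exons
    _require(spec.get("SE", 0) <= max(0, n - 2), "SE", f"needs an internal exon ({n} exons)")
    _require(spec.get("AF", 0) <= 1 and spec.get("AL", 0) <= 1, "AF/AL", "at most one each")
    if spec.get("AF"):
        _require(n >= 4, "AF", "needs >= 4 exons")
    if spec.get("AL"):
        _require(n >= 4, "AL", "needs >= 4 exons")
    n_intron_events = spec.get("RI", 0) + spec.get("A5", 0) + spec.get("A3", 0)
    _require(n_intron_events <= gene.n_introns, "RI/A5/A3", "needs one distinct intron each")

    # --- choose disjoint targets -------------------------------------------
    internal_exons = list(range(1, n - 1))  # exon ordinals, 0-based
    if spec.get("AF"):
        internal_exons = [e for e in internal_exons if e >= 3]
    if spec.get("AL"):
        internal_exons = [e for e in internal_exons if e <= n - 4]
    _require(spec.get("SE", 0) <= len(internal_exons), "SE", "not enough free internal exons")
    se_targets = sorted(rng.choice(internal_exons, size=spec.get("SE", 0), replace=False).tolist()) if spec.get("SE") else []

    intron_ordinals = list(range(gene.n_introns))
    chosen = sorted(rng.choice(intron_ordinals, size=n_intron_events, replace=False).tolist()) if n_intron_events else []
    ri_targets = chosen[: spec.get("RI", 0)]
    a5_targets = chosen[spec.get("RI", 0) : spec.get("RI", 0) + spec.get("A5", 0)]
    a3_targets = chosen[spec.get("RI", 0) + spec.get("A5", 0) :]

    # --- refine segmentation for A5/A3 -------------------------------------
    # work on a mutable copy; remember each original segment's new global span
    segments: List[Tuple[str, str]] = list(gene.segments)
    a5_pieces: Dict[int, Tuple[int, int]] = {}  # intron ordinal -> (idx i_a, idx i_b)
    a3_pieces: Dict[int, Tuple[int, int]] = {}

    def intron_global_index(ordinal: int) -> int:
        count = -1
        for gi, (kind, _) in enumerate(segments):
            if kind == "intron":
                count += 1
                if count == ordinal:
                    return gi
        raise IndexError(ordinal)

    for t in sorted(a5_targets + a3_targets):
        gi = intron_global_index(t)
        kind, seq = segments[gi]
        d1 = int(rng.integers(MIN_OFFSET, MAX_OFFSET + 1))
        d2 = int(rng.integers(MIN_OFFSET, MAX_OFFSET + 1))
        _require(len(seq) >= d1 + d2 + 1, "A5" if t in a5_targets else "A3", "intron too short to split")
        if t in a5_targets:
            parts = [seq[:d1], seq[d1 : d1 + d2], seq[d1 + d2 :]]
            segments[gi : gi + 1] = [("intron", p) for p in parts]
            a5_pieces[t] = (gi, gi + 1)
        else:
            parts = [seq[: -(d1 + d2)], seq[-(d1 + d2) : -d1], seq[-d1:]]
            segments[gi : gi + 1] = [("intron", p) for p in parts]
            a3_pieces[t] = (gi + 1, gi + 2)

    refined = GeneRegion(id=gene.id, segments=segments, rng_seed=gene.rng_seed)
    exon_gi = refined.exon_indices  # global indices of exons, in order
    # ordinal of each (possibly split) original intron -> its pieces' indices
    intron_gi: Dict[int, List[int]] = {}
    ordinal = -1
    prev_exon_boundary = True
    for gi, (kind, _) in enumerate(segments):
        if kind == "exon":
            prev_exon_boundary = True
        else:
            if prev_exon_boundary:
                ordinal += 1
                intron_gi[ordinal] = []
                prev_exon_boundary = False
            intron_gi[ordinal].append(gi)

    # --- emit isoforms ------------------------------------------------------
    variants: List[Tuple[List[int], List[str]]] = []
    all_exons = list(exon_gi)
    for t in se_targets:
        variants.append(([g for j, g in enumerate(exon_gi) if j != t], ["SE"]))
    for t in ri_targets:
        variants.append((sorted(all_exons + intron_gi[t]), ["RI"]))
    for t in a5_targets:
        ia, ib = a5_pieces[t]
        variants.append((sorted(all_exons + [ia, ib]), ["A5"]))
        variants.append((sorted(all_exons + [ia]), ["A5"]))
    for t in a3_targets:
        im, it = a3_pieces[t]
        variants.append((sorted(all_exons + [im, it]), ["A3"]))
        variants.append((sorted(all_exons + [it]), ["A3"]))
    if spec.get("AF"):
        variants.append(([exon_gi[0]] + exon_gi[3:], ["AF"]))
        variants.append(([exon_gi[1]] + exon_gi[3:], ["AF"]))
    if spec.get("AL"):
        variants.append((exon_gi[: n - 3] + [exon_gi[-1]], ["AL"]))
        variants.append((exon_gi[: n - 3] + [exon_gi[-2]], ["AL"]))

    included_sets = [tuple(all_exons)] + [tuple(v) for v, _ in variants]
    labels = [[]] + [lab for _, lab in variants]

    # --- union model and truth chains --------------------------------------
    in_union = sorted({g for inc in included_sets for g in inc})

    # Break junction-placement ambiguity: a junction (d, a) can slide left
    # when the base before the donor equals the base before the acceptor,
    # which would blur shared donors/acceptors between isoforms.  Recolor the
    # final base of the affected segments (a 4-colorable inequality graph) so
    # every junction boundary is unambiguous.
    pos_in_union = {g: i for i, g in enumerate(in_union)}
    constraints: set[Tuple[int, int]] = set()
    for inc in included_sets:
        for g1, g2 in zip(inc, inc[1:]):
            if pos_in_union[g2] - pos_in_union[g1] > 1:  # junction, not adjacency
                pre_acceptor = in_union[pos_in_union[g2] - 1]
                constraints.add(tuple(sorted((g1, pre_acceptor))))
    neighbours: Dict[int, set] = {}
    for x, y in constraints:
        neighbours.setdefault(x, set()).add(y)
        neighbours.setdefault(y, set()).add(x)
    for g in sorted(neighbours):
        kind, seq = segments[g]
        taken = {segments[h][1][-1] for h in neighbours[g] if h < g}
        if seq[-1] in taken:
            free = [b for b in BASES if b not in taken and b != seq[-1]]
            if free:
                segments[g] = (kind, seq[:-1] + free[0])

    offsets: Dict[int, Tuple[int, int]] = {}
    pos = 0
    for g in in_union:
        length = len(segments[g][1])
        offsets[g] = (pos, pos + length)
        pos += length
    union_seq = "".join(segments[g][1] for g in in_union)

    isoforms: List[SimulatedIsoform] = []
    for i, (inc, lab) in enumerate(zip(included_sets, labels), start=1):
        seq = "".join(segments[g][1] for g in inc)
        span_start = offsets[inc[0]][0]
        chain: List[Tuple[int, int]] = []
        for g1, g2 in zip(inc, inc[1:]):
            donor, acceptor = offsets[g1][1], offsets[g2][0]
            if acceptor > donor:
                # left-normalize: (d, a) and (d-1, a-1) delete the same model
                # sequence when the preceding bases match
                floor = chain[-1][1] + 1 if chain else span_start + 1
                while donor > floor and union_seq[donor - 1] == union_seq[acceptor - 1]:
                    donor -= 1
                    acceptor -= 1
                chain.append((donor, acceptor))
            elif acceptor < donor:
                raise AssertionError("included segments out of union order")
        isoforms.append(
            SimulatedIsoform(
                id=f"{gene.id}.iso{i}",
                gene_id=gene.id,
                included_segments=tuple(inc),
                sequence=seq,
                truth_chain=tuple(chain),
                truth_span=(offsets[inc[0]][0], offsets[inc[-1]][1]),
                event_labels=list(lab),
            )
        )

    truth = TruthTable()
    truth.model_sequence_of[gene.id] = union_seq
    seen_events: Dict[Tuple[str, Tuple[int, ...]], None] = {}
    for iso in isoforms:
        truth.family_of[iso.id] = gene.id
        truth.chain_of[iso.id] = iso.truth_chain
        truth.span_of[iso.id] = iso.truth_span
    for i, a in enumerate(isoforms):
        for b in isoforms[i + 1 :]:
            for ev in classify_chain_pair(a.truth_chain, a.truth_span, b.truth_chain, b.truth_span):
                seen_events.setdefault(ev)
    truth.events_of[gene.id] = sorted(seen_events, key=lambda e: (e[1], e[0]))
    return isoforms, refined, truth


def add_noise(seq: str, sub_rate: float, ins_rate: float, del_rate: float, seed: int) -> str:
    """Apply substitution/insertion/deletion noise, deterministic per seed."""
    for name, r in (("sub_rate", sub_rate), ("ins_rate", ins_rate), ("del_rate", del_rate)):
        if not 0.0 <= r <= 0.2:
            raise ValueError(f"{name} must be in [0, 0.2], got {r}")
    if sub_rate == ins_rate == del_rate == 0.0:
        return seq
    rng = np.random.default_rng(seed)
    out: List[str] = []
    for ch in seq:
        u = rng.random()
        if u < del_rate:
            continue
        if u < del_rate + ins_rate:
            out.append(BASES[rng.integers(0, 4)])
        if u < del_rate + ins_rate + sub_rate and u >= del_rate + ins_rate:
            out.append(BASES[(BASES.index(ch) + 1 + rng.integers(0, 3)) % 4])
        else:
            out.append(ch)
    return "".join(out)


def make_short_reads(
    isoforms: Sequence[Tuple[str, str]],
    read_len: int,
    coverage: float,
    err_rate: float,
    seed: int,
) -> List[Tuple[str, str]]:
    """Uniformly positioned substitution-only short reads per isoform.

    Read count per isoform is ``ceil(len * coverage / read_len)``.
    """
    if coverage < 0 or err_rate < 0:
        raise ValueError("coverage and err_rate must be non-negative")
    rng = np.random.default_rng(seed)
    reads: List[Tuple[str, str]] = []
    for name, seq in isoforms:
        if read_len > len(seq):
            raise ValueError(f"read_len {read_len} exceeds isoform {name} length {len(seq)}")
        n_reads = math.ceil(len(seq) * coverage / read_len)
        for i in range(n_reads):
            start = int(rng.integers(0, len(seq) - read_len + 1))
            r = list(seq[start : start + read_len])
            if err_rate > 0:
                errs = rng.random(read_len) < err_rate
                for j in np.flatnonzero(errs):
                    r[j] = BASES[(BASES.index(r[j]) + 1 + rng.integers(0, 3)) % 4]
            reads.append((f"{name}.r{i}", "".join(r)))
    return reads


# ---------------------------------------------------------------------------
# coding / noncoding sequence emulation (for the lncRNA cascade)

#: codons over-represented in the simulated coding class (a generic
#: plant-like usage bias; the point is in-frame hexamer structure, not any
#: particular organism's table)
_PREFERRED_CODONS = (
    "GCT GGT GAT GAA GAG AAG AAA CTT TTG GTT GTG TCT TCC ACT ACC "
    "ATT ATG CCT CCA CAA CAG CGT AGA AAC AAT GAC TTC TAC CAC TGG"
).split()
_ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
_SENSE_CODONS = [c for c in _ALL_CODONS if c not in ("TAA", "TAG", "TGA")]


def random_coding_mrna(
    seed: int,
    n_codons: int = 200,
    utr5: int = 50,
    utr3: int = 80,
) -> str:
    """A codon-biased mRNA: short UTRs around an ATG..stop CDS of n_codons aa."""
    rng = np.random.default_rng(seed)
    weights = np.array([3.0 if c in _PREFERRED_CODONS else 1.0 for c in _SENSE_CODONS])
    weights /= weights.sum()
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 1, p=weights)
    cds = "ATG" + "".join(_SENSE_CODONS[i] for i in body) + str(rng.choice(["TAA", "TAG", "TGA"]))
    return _random_seq(rng, utr5) + cds + _random_seq(rng, utr3)


def random_noncoding_rna(seed: int, length: int = 600, max_run_codons: int = 30) -> str:
    """An ORF-poor noncoding sequence.

    Starts from uniform random sequence, then breaks every stop-free run
    longer than ``max_run_codons`` codons — in all three reading frames — by
    overwriting a codon with a random stop, iterating until no frame sustains
    a long run.  The result has no reading frame with an open ORF anywhere
    near coding length.
    """
    rng = np.random.default_rng(seed)
    seq = list(_random_seq(rng, length))
    stops = ("TAA", "TAG", "TGA")
    for _ in range(20):
        dirty = False
        for frame in range(3):
            run = 0
            for i in range(frame, length - 2, 3):
                if "".join(seq[i : i + 3]) in stops:
                    run = 0
                    continue
                run += 1
                if run > max_run_codons:
                    seq[i : i + 3] = stops[rng.integers(0, 3)]
                    run = 0
                    dirty = True
        if not dirty:
            break
    return "".join(seq)


# ---------------------------------------------------------------------------
# whole-dataset convenience (the study conditions for end-to-end testing)

#: event-spec menu keeping every gene at <= 4 isoforms
EVENT_MENU: List[Dict[str, int]] = [
    {},
    {"SE": 1},
    {"RI": 1},
    {"SE": 1, "RI": 1},
    {"A5": 1},
    {"A3": 1},
    {"AF": 1},
    {"AL": 1},
]


@dataclass
class SimulatedDataset:
    genes: List[GeneRegion]
    isoforms: List[SimulatedIsoform]
    transcripts: Dict[str, str]  # possibly noisy
    clean_transcripts: Dict[str, str]
    short_reads: List[Tuple[str, str]]
    truth: TruthTable


def simulate_dataset(
    n_genes: int,
    seed: int,
    exon_len_range: Tuple[int, int] = (100, 300),
    intron_len_range: Tuple[int, int] = (150, 300),
    n_exon_range: Tuple[int, int] = (4, 7),
    sub_rate: float = 0.0,
    ins_rate: float = 0.0,
    del_rate: float = 0.0,
    short_read_len: int = 100,
    short_read_coverage: float = 0.0,
    short_read_err: float = 0.0,
) -> SimulatedDataset:
    """Simulate ``n_genes`` genes with event specs drawn from ``EVENT_MENU``."""
    rng = np.random.default_rng(seed)
    genes: List[GeneRegion] = []
    all_iso: List[SimulatedIsoform] = []
    truth = TruthTable()
    for g in range(n_genes):
        gseed = int(rng.integers(0, 2**31 - 1))
        n_exons = int(rng.integers(n_exon_range[0], n_exon_range[1] + 1))
        gene = make_gene(n_exons, exon_len_range, intron_len_range, gseed, gene_id=f"g{g:04d}")
        spec = EVENT_MENU[int(rng.integers(0, len(EVENT_MENU)))]
        isos, refined, gt = make_isoforms(gene, spec, seed=gseed + 1)
        genes.append(refined)
        all_iso.extend(isos)
        truth.update(gt)

    clean = {iso.id: iso.sequence for iso in all_iso}
    noisy: Dict[str, str] = {}
    for iso in all_iso:
        nseed = int(rng.integers(0, 2**31 - 1))
        noisy[iso.id] = add_noise(iso.sequence, sub_rate, ins_rate, del_rate, nseed)
    reads: List[Tuple[str, str]] = []
    if short_read_coverage > 0:
        rseed = int(rng.integers(0, 2**31 - 1))
        reads = make_short_reads(
            [(i, s) for i, s in clean.items()], short_read_len, short_read_coverage, short_read_err, rseed
        )
    return SimulatedDataset(
        genes=genes,
        isoforms=all_iso,
        transcripts=noisy,
        clean_transcripts=clean,
        short_reads=reads,
        truth=truth,
    )
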