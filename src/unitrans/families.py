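"""Partition non-redundant transcripts into families by k-mer similarity.

Putative isoforms of one gene share exonic sequence, so their sets of distinct
sense-strand k-mers overlap heavily, while unrelated transcripts share
essentially no 24-mer by chance.  Similarity is the overlap coefficient
|A & B| / min(|A|, |B|); families are the connected components of the graph
with an edge wherever similarity reaches ``min_similarity``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import networkx as nx

DEFAULT_K = 24
DEFAULT_MIN_SIMILARITY = 0.05


@dataclass
class KmerProfile:
    k: int
    kmer_set: Set[str]


@dataclass
class FamilyPartition:
    #: family id -> member transcript ids (descending size, then smallest id)
    families: Dict[str, List[str]]
    #: (id_a, id_b, similarity) for every edge at or above the threshold
    similarity_graph: List[Tuple[str, str, float]] = field(default_factory=list)

    def family_of(self) -> Dict[str, str]:
        return {tid: fid for fid, members in self.families.items() for tid in members}


def kmer_profile(seq: str, k: int = DEFAULT_K) -> KmerProfile:
    """Distinct sense-strand k-mers; k-mers containing N are skipped."""
    seq = seq.upper()
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    kmers = {
        seq[i : i + k]
        for i in range(len(seq) - k + 1)
        if "N" not in seq[i : i + k]
    }
    return KmerProfile(k=k, kmer_set=kmers)


def profile_similarity(a: KmerProfile, b: KmerProfile) -> float:
    """Overlap coefficient |A & B| / min(|A|, |B|); symmetric, in [0, 1]."""
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} vs {b.k}")
    if not a.kmer_set or not b.kmer_set:
        return 0.0
    return len(a.kmer_set & b.kmer_set) / min(len(a.kmer_set), len(b.kmer_set))


def partition_families(
    transcripts: Dict[str, str],
    k: int = DEFAULT_K,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
) -> FamilyPartition:
    """Families = connected components of the thresholded similarity graph.

    Candidate pairs come from an inverted k-mer index (pairs sharing no k-mer
    cannot reach any positive threshold), then exact similarities are computed.
    Family ids are assigned by descending member count, then smallest member id.
    """
    if not transcripts:
        raise ValueError("no transcripts to partition")
    profiles = {tid: kmer_profile(seq, k) for tid, seq in transcripts.items()}

    index: Dict[str, List[str]] = defaultdict(list)
    for tid in sorted(profiles):
        for kmer in profiles[tid].kmer_set:
            index[kmer].append(tid)
    candidate_pairs: Set[Tuple[str, str]] = set()
    for tids in index.values():
        if len(tids) > 1:
            for i, a in enumerate(tids):
                for b in tids[i + 1 :]:
                    candidate_pairs.add((a, b))

    g = nx.Graph()
    g.add_nodes_from(transcripts)
    edges: List[Tuple[str, str, float]] = []
    for a, b in sorted(candidate_pairs):
        s = profile_similarity(profiles[a], profiles[b])
        if s >= min_similarity:
            g.add_edge(a, b)
            edges.append((a, b, s))

    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    families = {f"F{i + 1:05d}": members for i, members in enumerate(comps)}
    return FamilyPartition(families=families, similarity_graph=edges)
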