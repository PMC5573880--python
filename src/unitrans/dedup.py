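"""Redundancy removal by greedy sequence-identity clustering.

Mirrors the threshold semantics of cd-hit-est as used for merged long-read
transcript sets: global clustering off (local-alignment identity), no
constraint on the longer sequence, and two simultaneous constraints on the
shorter one — aligned coverage at least ``aS`` and at most ``AS`` unaligned
nucleotides.  Defaults are identity c=0.99, aS=0.99, AS=30.

The contract is the threshold test, not cd-hit's banded heuristics: candidate
pairs are ranked by a fixed local-alignment scheme (match +1, mismatch -2,
gap open -5, gap extend -1).  An edlib infix-distance prescreen skips pairs
that cannot possibly meet the thresholds; the brute-force oracle used in the
test suite runs the same greedy rule without the prescreen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import edlib
from Bio import Align

DEFAULT_C = 0.99
DEFAULT_AS_COV = 0.99
DEFAULT_AS_NT = 30


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -2
    a.open_gap_score = -5
    a.extend_gap_score = -1
    return a


_ALIGNER = _aligner()


@dataclass
class RedundancyCluster:
    representative_id: str
    member_ids: List[str] = field(default_factory=list)
    #: member id -> (identity, shorter_coverage, shorter_unaligned)
    metrics: Dict[str, Tuple[float, float, int]] = field(default_factory=dict)


def pairwise_redundancy(a: str, b: str) -> Tuple[float, float, int]:
    """(identity, shorter_coverage, shorter_unaligned) of the best local alignment.

    identity = matches / alignment columns; shorter_coverage = extent of the
    aligned span on the shorter sequence / shorter length; shorter_unaligned =
    shorter length minus that span.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    shorter_len = min(len(a), len(b))
    shorter_is_a = len(a) <= len(b)
    try:
        aln = _ALIGNER.align(a, b)[0]
    except IndexError:  # no positive-scoring local alignment
        return 0.0, 0.0, shorter_len
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    blocks = aln.aligned[0] if shorter_is_a else aln.aligned[1]
    if len(blocks) == 0:
        return 0.0, 0.0, shorter_len
    span = int(blocks[-1][1] - blocks[0][0])
    return identity, span / shorter_len, shorter_len - span


def _prescreen_reject(a: str, b: str, c: float, AS: int) -> bool:
    """True when the pair provably cannot satisfy identity >= c with near-full
    coverage of the shorter sequence.  Infix edit distance of the shorter in
    the longer lower-bounds the mismatches+gaps of any qualifying alignment."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    budget = int(3 * (1 - c) * len(short)) + AS + 5
    res = edlib.align(short, long_, mode="HW", task="distance", k=budget)
    return res["editDistance"] == -1


def cluster_redundant(
    transcripts: Dict[str, str],
    c: float = DEFAULT_C,
    aS: float = DEFAULT_AS_COV,
    AS: int = DEFAULT_AS_NT,
    prescreen: bool = True,
) -> List[RedundancyCluster]:
    """Greedy clustering: longest-first, join the first qualifying representative.

    Transcripts are visited by descending length (ties: ascending id), so every
    representative is the longest member of its cluster.  Output order is
    founding order, which makes the clustering invariant to input order.
    """
    if not transcripts:
        raise ValueError("no transcripts to cluster")
    if len(set(transcripts)) != len(transcripts):
        raise ValueError("duplicate transcript ids")
    order = sorted(transcripts, key=lambda t: (-len(transcripts[t]), t))
    clusters: List[RedundancyCluster] = []
    for tid in order:
        seq = transcripts[tid]
        placed = False
        for cl in clusters:
            rep_seq = transcripts[cl.representative_id]
            if prescreen and _prescreen_reject(seq, rep_seq, c, AS):
                continue
            ident, cov, unaligned = pairwise_redundancy(seq, rep_seq)
            if ident >= c and cov >= aS and unaligned <= AS:
                cl.member_ids.append(tid)
                cl.metrics[tid] = (ident, cov, unaligned)
                placed = True
                break
        if not placed:
            clusters.append(
                RedundancyCluster(representative_id=tid, member_ids=[tid], metrics={tid: (1.0, 1.0, 0)})
            )
    return clusters


def nonredundant(transcripts: Dict[str, str], **kwargs) -> Dict[str, str]:
    """Representative sequences after clustering, in founding order."""
    return {cl.representative_id: transcripts[cl.representative_id] for cl in cluster_redundant(transcripts, **kwargs)}
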