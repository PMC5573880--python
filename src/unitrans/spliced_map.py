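"""Spliced alignment of transcripts onto UniTransModels.

Models are reconstructed from the very transcripts being mapped, so exact
anchors dominate and a full splice-site-aware aligner is unnecessary: maximal
exact matches seeded from a k-mer index of the model are chained colinearly by
sparse dynamic programming, chained anchors are merged into blocks (small model
gaps are absorbed as indels), and the remaining model gaps are the splice
junctions.  Coordinates are transcript-space model coordinates, 0-based
half-open; no GT-AG motif is required because "introns" on a model are merely
model segments a transcript skips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib

DEFAULT_ANCHOR_K = 15
DEFAULT_MIN_ANCHOR = 18
DEFAULT_MIN_JUNCTION_GAP = 25
DEFAULT_MAX_READ_SLOP = 10


@dataclass(frozen=True)
class JunctionChain:
    """Ordered (donor, acceptor) model coordinates skipped by a transcript."""

    model_id: str
    junctions: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev = -1
        for d, a in self.junctions:
            if not d < a:
                raise ValueError(f"junction donor must precede acceptor: ({d}, {a})")
            if d <= prev:
                raise ValueError("junctions must be strictly increasing")
            prev = a


@dataclass
class SplicedAlignment:
    transcript_id: str
    model_id: str
    #: ordered (model_start, model_end, read_start, read_end), 0-based half-open
    blocks: List[Tuple[int, int, int, int]] = field(default_factory=list)
    identity: float = 0.0
    coverage: float = 0.0

    @property
    def mapped(self) -> bool:
        return bool(self.blocks)

    @property
    def span(self) -> Tuple[int, int]:
        if not self.blocks:
            raise ValueError("unmapped alignment has no span")
        return self.blocks[0][0], self.blocks[-1][1]

    def validate(self) -> None:
        prev_m = prev_r = -1
        for ms, me, rs, re_ in self.blocks:
            if not (ms < me and rs < re_):
                raise AssertionError("empty or inverted block")
            if ms < prev_m or rs < prev_r:
                raise AssertionError("blocks overlap or are unsorted")
            prev_m, prev_r = me, re_


def _find_anchors(read: str, model: str, anchor_k: int, min_anchor: int) -> List[Tuple[int, int, int]]:
    """Maximal exact matches >= min_anchor as (read_start, model_start, length)."""
    index: Dict[str, List[int]] = {}
    for i in range(len(model) - anchor_k + 1):
        index.setdefault(model[i : i + anchor_k], []).append(i)
    seen: set[Tuple[int, int]] = set()
    anchors: List[Tuple[int, int, int]] = []
    for q in range(len(read) - anchor_k + 1):
        hits = index.get(read[q : q + anchor_k])
        if not hits:
            continue
        for r in hits:
            # extend to a maximal match; skip seeds interior to one already found
            if (q - r) in {d for (d, e) in seen if e > q}:
                continue
            qs, rs = q, r
            while qs > 0 and rs > 0 and read[qs - 1] == model[rs - 1]:
                qs -= 1
                rs -= 1
            qe, re_ = q + anchor_k, r + anchor_k
            n, m = len(read), len(model)
            while qe < n and re_ < m and read[qe] == model[re_]:
                qe += 1
                re_ += 1
            if qe - qs >= min_anchor:
                key = (qs - rs, qe)
                if key not in seen:
                    seen.add(key)
                    anchors.append((qs, rs, qe - qs))
    anchors.sort()
    return anchors


def _chain_anchors(anchors: List[Tuple[int, int, int]]) -> List[Tuple[int, int, int]]:
    """Colinear chaining maximizing anchored length minus gap penalties."""
    if not anchors:
        return []
    n = len(anchors)
    score = [0.0] * n
    back: List[Optional[int]] = [None] * n
    for j in range(n):
        qj, rj, lj = anchors[j]
        score[j] = float(lj)
        for i in range(j):
            qi, ri, li = anchors[i]
            if qi + li > qj + lj or ri + li > rj + lj:
                continue
            # overlap on either axis is trimmed from the gain
            overlap = max(0, qi + li - qj, ri + li - rj)
            qgap = max(0, qj - (qi + li))
            rgap = max(0, rj - (ri + li))
            gain = lj - overlap - 1.0 * qgap - 0.01 * rgap - 0.5
            if qgap > 0 and rgap > 0:
                gain -= 0.5  # discourage spurious double-gap joins
            if score[i] + gain > score[j]:
                score[j] = score[i] + gain
                back[j] = i
    best = max(range(n), key=lambda j: (score[j], -(anchors[j][0])))
    chain = []
    k: Optional[int] = best
    while k is not None:
        chain.append(anchors[k])
        k = back[k]
    chain.reverse()
    return chain


def _block_identity(read: str, model: str, blocks: List[Tuple[int, int, int, int]]) -> float:
    """Matches over alignment columns, summed over blocks (edlib NW per block)."""
    cols = 0
    matches = 0
    for ms, me, rs, re_ in blocks:
        sub_r, sub_m = read[rs:re_], model[ms:me]
        if sub_r == sub_m:
            matches += len(sub_r)
            cols += len(sub_r)
            continue
        res = edlib.align(sub_r, sub_m, task="path", mode="NW")
        length = max(len(sub_r), len(sub_m))
        cols += length
        matches += length - res["editDistance"]
    return matches / cols if cols else 0.0


def _left_normalize(
    blocks: List[Tuple[int, int, int, int]], read: str, model: str
) -> List[Tuple[int, int, int, int]]:
    """Shift ambiguous junctions to their leftmost equivalent placement.

    A junction (d, a) deletes the same model sequence as (d-1, a-1) whenever
    model[d-1] == model[a-1]; the leftmost placement is the canonical one
    (the convention used for truth chains as well).
    """
    out = list(blocks)
    for i in range(len(out) - 1):
        ms1, me1, rs1, re1 = out[i]
        ms2, me2, rs2, re2 = out[i + 1]
        while (
            me1 - 1 > ms1
            and re1 - 1 > rs1
            and model[me1 - 1] == model[ms2 - 1]
            and read[re1 - 1] == model[ms2 - 1]
        ):
            me1 -= 1
            ms2 -= 1
            re1 -= 1
            rs2 -= 1
        out[i] = (ms1, me1, rs1, re1)
        out[i + 1] = (ms2, me2, rs2, re2)
    return out


def splice_align(
    transcript_id: str,
    transcript: str,
    model_id: str,
    model: str,
    anchor_k: int = DEFAULT_ANCHOR_K,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    min_junction_gap: int = DEFAULT_MIN_JUNCTION_GAP,
    max_read_slop: int = DEFAULT_MAX_READ_SLOP,
) -> SplicedAlignment:
    """Anchor-and-chain spliced alignment of one transcript onto one model.

    Returns an unmapped result (empty blocks, coverage 0) when no chain covers
    at least half of the transcript.
    """
    if not transcript or not model:
        raise ValueError("transcript and model must be non-empty")
    aln = SplicedAlignment(transcript_id=transcript_id, model_id=model_id)
    anchors = _find_anchors(transcript, model, anchor_k, min_anchor)
    chain = _chain_anchors(anchors)
    if not chain:
        return aln

    # resolve residual overlaps between consecutive chained anchors
    clean: List[Tuple[int, int, int]] = []
    for q, r, l in chain:
        if clean:
            pq, pr, pl = clean[-1]
            cut = max(0, pq + pl - q, pr + pl - r)
            if cut >= l:
                continue
            q, r, l = q + cut, r + cut, l - cut
        clean.append((q, r, l))

    # merge anchors into blocks; model gaps below min_junction_gap are indels
    blocks: List[Tuple[int, int, int, int]] = []
    for q, r, l in clean:
        if blocks:
            ms, me, rs, re_ = blocks[-1]
            mgap = r - me
            qgap = q - re_
            if mgap < min_junction_gap or qgap > max_read_slop:
                blocks[-1] = (ms, max(me, r + l), rs, max(re_, q + l))
                continue
        blocks.append((r, r + l, q, q + l))

    blocks = _left_normalize(blocks, transcript, model)
    covered = sum(re_ - rs for _, _, rs, re_ in blocks)
    if covered < 0.5 * len(transcript):
        return aln
    aln.blocks = blocks
    aln.coverage = covered / len(transcript)
    aln.identity = _block_identity(transcript, model, blocks)
    aln.validate()
    return aln


def best_alignment(
    transcript_id: str,
    transcript: str,
    models: Dict[str, str],
    **kwargs,
) -> SplicedAlignment:
    """One best alignment across candidate models.

    Ties break to the longest aligned span, then the smallest model id.
    """
    best: Optional[SplicedAlignment] = None
    for mid in sorted(models):
        aln = splice_align(transcript_id, transcript, mid, models[mid], **kwargs)
        if not aln.mapped:
            continue
        key = (aln.coverage * aln.identity, sum(me - ms for ms, me, _, _ in aln.blocks), mid)
        if best is None:
            best, best_key = aln, key
        elif (key[0], key[1]) > (best_key[0], best_key[1]):
            best, best_key = aln, key
    return best if best is not None else SplicedAlignment(transcript_id, "*")


def extract_chain(aln: SplicedAlignment, min_junction_gap: int = DEFAULT_MIN_JUNCTION_GAP) -> JunctionChain:
    """Junctions are model gaps >= min_junction_gap between consecutive blocks."""
    if not aln.mapped:
        raise ValueError(f"cannot extract a chain from unmapped transcript {aln.transcript_id}")
    junctions: List[Tuple[int, int]] = []
    for (ms1, me1, _, _), (ms2, _, _, _) in zip(aln.blocks, aln.blocks[1:]):
        gap = ms2 - me1
        if gap >= min_junction_gap:
            junctions.append((me1, ms2))
    return JunctionChain(model_id=aln.model_id, junctions=tuple(junctions))


def splice_model_by_chain(model: str, chain: JunctionChain) -> str:
    """Delete the chain's junction intervals from the model sequence.

    On error-free data this reproduces the transcript sequence exactly
    (restricted to the aligned span).
    """
    out = []
    pos = 0
    for d, a in chain.junctions:
        out.append(model[pos:d])
        pos = a
    out.append(model[pos:])
    return "".join(out)


def map_all(
    transcripts: Dict[str, str],
    models: Dict[str, str],
    model_of: Optional[Dict[str, Sequence[str]]] = None,
    **kwargs,
) -> List[SplicedAlignment]:
    """Map every transcript to its best model.

    ``model_of`` optionally restricts each transcript to candidate model ids
    (e.g. the models of its own family); otherwise all models are tried.
    """
    out = []
    for tid in sorted(transcripts):
        if model_of is not None and tid in model_of:
            cand = {m: models[m] for m in model_of[tid]}
        else:
            cand = models
        out.append(best_alignment(tid, transcripts[tid], cand, **kwargs))
    return out
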