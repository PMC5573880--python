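"""Isoform collapsing and model-based alternative-splicing classification.

Transcripts mapped to the same model collapse into one isoform when their
junction chains are identical (within a coordinate tolerance, default exact).
Splicing differences between isoform pairs of one model are classified into
the six event types SE, RI, A5, A3, AF and AL — in *model* coordinates, which
is what a reference-free analysis can offer: a model "intron" is simply model
sequence some isoform skips.  Note a consequence worth spelling out: an exon
skipped between exonic neighbours is indistinguishable from a retained intron
on the model, so RI is structurally the most common call on this kind of data.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .spliced_map import JunctionChain, SplicedAlignment

EVENT_TYPES = ("SE", "RI", "A5", "A3", "AF", "AL")
#: precedence when several rules could fire on the same coordinates
EVENT_PRECEDENCE = {t: i for i, t in enumerate(("SE", "RI", "AF", "AL", "A5", "A3"))}


@dataclass
class Isoform:
    isoform_id: str
    model_id: str
    chain: JunctionChain
    support: int
    per_tissue: Dict[str, int] = field(default_factory=dict)
    representative_id: str = ""
    member_ids: List[str] = field(default_factory=list)
    span: Tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class ASEvent:
    model_id: str
    type: str
    coordinates: Tuple[int, ...]
    isoform_pair: Tuple[str, str]

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown AS event type {self.type}")
        if list(self.coordinates) != sorted(set(self.coordinates)):
            raise ValueError(f"event coordinates must be strictly increasing: {self.coordinates}")


def _chains_equal(a: Tuple[Tuple[int, int], ...], b: Tuple[Tuple[int, int], ...], eps: int) -> bool:
    if len(a) != len(b):
        return False
    return all(abs(d1 - d2) <= eps and abs(a1 - a2) <= eps for (d1, a1), (d2, a2) in zip(a, b))


def collapse_isoforms(
    alignments: Sequence[SplicedAlignment],
    eps: int = 0,
    tissue_of: Optional[Dict[str, str]] = None,
) -> List[Isoform]:
    """Collapse mapped alignments with identical junction chains into isoforms.

    Chainless (single-block) transcripts of a model collapse into one
    "unspliced" isoform regardless of end coordinates.  At ``eps > 0`` chain
    equality is resolved by single linkage and the group re-anchors to the
    chain of its highest-support member.  Isoform ids are ``<model>.I1..In``
    ordered by descending support, then chain.
    """
    from .spliced_map import extract_chain

    by_model: Dict[str, List[SplicedAlignment]] = defaultdict(list)
    for aln in alignments:
        if not aln.mapped:
            raise ValueError(f"cannot collapse unmapped transcript {aln.transcript_id}")
        by_model[aln.model_id].append(aln)

    isoforms: List[Isoform] = []
    for model_id in sorted(by_model):
        alns = sorted(by_model[model_id], key=lambda a: a.transcript_id)
        chains = {a.transcript_id: extract_chain(a) for a in alns}
        # single-linkage grouping over chain equality (exact when eps == 0)
        groups: List[List[SplicedAlignment]] = []
        for aln in alns:
            c = chains[aln.transcript_id].junctions
            merged = None
            for g in groups:
                if any(_chains_equal(c, chains[x.transcript_id].junctions, eps) for x in g):
                    if merged is None:
                        g.append(aln)
                        merged = g
                    else:  # eps-linkage can bridge two existing groups
                        merged.extend(g)
                        g.clear()
            if merged is None:
                groups.append([aln])
        groups = [g for g in groups if g]

        built = []
        for g in groups:
            counts = Counter(chains[x.transcript_id].junctions for x in g)
            anchor_chain = counts.most_common(1)[0][0]
            rep = max(g, key=lambda a: (sum(re_ - rs for _, _, rs, re_ in a.blocks), a.transcript_id))
            tissues: Dict[str, int] = defaultdict(int)
            for x in g:
                tissues[(tissue_of or {}).get(x.transcript_id, "all")] += 1
            built.append(
                Isoform(
                    isoform_id="",
                    model_id=model_id,
                    chain=JunctionChain(model_id, anchor_chain),
                    support=len(g),
                    per_tissue=dict(tissues),
                    representative_id=rep.transcript_id,
                    member_ids=sorted(x.transcript_id for x in g),
                    span=(min(x.span[0] for x in g), max(x.span[1] for x in g)),
                )
            )
        built.sort(key=lambda iso: (-iso.support, iso.chain.junctions))
        for i, iso in enumerate(built, start=1):
            iso.isoform_id = f"{model_id}.I{i}"
        isoforms.extend(built)
    return isoforms


def classify_chain_pair(
    chain_a: Tuple[Tuple[int, int], ...],
    span_a: Tuple[int, int],
    chain_b: Tuple[Tuple[int, int], ...],
    span_b: Tuple[int, int],
) -> List[Tuple[str, Tuple[int, ...]]]:
    """Local AS events between two junction chains of one model.

    Pure function over (chain, span) pairs; also used to derive ground-truth
    event tables from simulated truth chains.
    """
    events: List[Tuple[str, Tuple[int, ...]]] = []

    def one_way(ja, sa, jb, sb):
        found = []
        set_b = set(jb)
        # SE: (d1,a1),(d2,a2) in A vs single (d1,a2) in B
        for (d1, a1), (d2, a2) in zip(ja, ja[1:]):
            if a1 < d2 and (d1, a2) in set_b:
                found.append(("SE", (d1, a1, d2, a2)))
        # RI: junction in A, B covers the interval with no intersecting junction
        for d, a in ja:
            if sb[0] <= d and sb[1] >= a and not any(db < a and ab > d for db, ab in jb):
                found.append(("RI", (d, a)))
        return found

    events += one_way(chain_a, span_a, chain_b, span_b)
    events += one_way(chain_b, span_b, chain_a, span_a)

    claimed: set[Tuple[str, Tuple[int, ...]]] = set()
    # AF / AL on the terminal junctions
    if chain_a and chain_b:
        (d1, a1), (d2, a2) = chain_a[0], chain_b[0]
        if a1 == a2 and d1 != d2:
            up_a, up_b = (span_a[0], d1), (span_b[0], d2)
            if up_a[1] <= up_b[0] or up_b[1] <= up_a[0]:
                events.append(("AF", (min(d1, d2), max(d1, d2), a1)))
                claimed.add(("A5", (min(d1, d2), max(d1, d2), a1)))
        (d1, a1), (d2, a2) = chain_a[-1], chain_b[-1]
        if d1 == d2 and a1 != a2:
            dn_a, dn_b = (a1, span_a[1]), (a2, span_b[1])
            if dn_a[1] <= dn_b[0] or dn_b[1] <= dn_a[0]:
                events.append(("AL", (d1, min(a1, a2), max(a1, a2))))
                claimed.add(("A3", (d1, min(a1, a2), max(a1, a2))))
    # A5: junctions sharing an acceptor; A3: junctions sharing a donor
    for da, aa in chain_a:
        for db, ab in chain_b:
            if aa == ab and da != db:
                ev = ("A5", (min(da, db), max(da, db), aa))
                if ev not in claimed:
                    events.append(ev)
            if da == db and aa != ab:
                ev = ("A3", (da, min(aa, ab), max(aa, ab)))
                if ev not in claimed:
                    events.append(ev)
    # deduplicate within the pair, highest precedence first
    out: Dict[Tuple[int, ...], Tuple[str, Tuple[int, ...]]] = {}
    for typ, coords in sorted(events, key=lambda e: EVENT_PRECEDENCE[e[0]]):
        out.setdefault(coords, (typ, coords))
    return sorted(out.values(), key=lambda e: (e[1], e[0]))


def classify_events(isoforms_of_model: Sequence[Isoform]) -> List[ASEvent]:
    """Classify AS events between every isoform pair of one model.

    Events are deduplicated by (type, coordinates) per model; the reported
    pair is the first (lowest isoform ids) that exhibits the event.
    """
    if len({iso.model_id for iso in isoforms_of_model}) > 1:
        raise ValueError("classify_events expects isoforms of a single model")
    seen: Dict[Tuple[str, Tuple[int, ...]], ASEvent] = {}
    isos = sorted(isoforms_of_model, key=lambda i: i.isoform_id)
    for i, a in enumerate(isos):
        for b in isos[i + 1 :]:
            for typ, coords in classify_chain_pair(a.chain.junctions, a.span, b.chain.junctions, b.span):
                key = (typ, coords)
                if key not in seen:
                    seen[key] = ASEvent(a.model_id, typ, coords, (a.isoform_id, b.isoform_id))
    return sorted(seen.values(), key=lambda e: (e.coordinates, e.type))


def isoform_summary(isoforms: Iterable[Isoform]) -> Dict[str, object]:
    """Per-model isoform-count distribution, binned 1..10 and ">10".

    Also reports the fraction of models with more than one isoform.
    """
    per_model = Counter(iso.model_id for iso in isoforms)
    bins: Dict[str, int] = {str(i): 0 for i in range(1, 11)}
    bins[">10"] = 0
    for n in per_model.values():
        bins[str(n) if n <= 10 else ">10"] += 1
    n_models = len(per_model)
    multi = sum(1 for n in per_model.values() if n > 1)
    return {
        "bins": bins,
        "n_models": n_models,
        "multi_isoform_fraction": (multi / n_models) if n_models else 0.0,
    }
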