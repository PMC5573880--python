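"""De Bruijn graph reconstruction of unique transcript models (UniTransModels).

Each transcript family is re-expressed as walks over the compacted De Bruijn
graph of its sequences (nodes are (k-1)-mers, edges k-mers, unitigs maximal
non-branching paths).  A precedence relation over unitigs — u before v when u
precedes v in some transcript walk — orders the unitigs; when it is acyclic
the family yields ONE model, otherwise the largest transcript subset with an
acyclic union is peeled off greedily and the remainder recursed, yielding
several models.

Splice junctions leave their mark on the graph: a transcript that skips
model sequence contributes k-mers spanning the skip, and those k-mers form
short "shortcut" unitigs that bypass real content — because of them, a naive
concatenation of *all* unitigs could never reproduce the union of observed
segments.  The model is therefore the maximum-weight directed path through
the unitig DAG, where a unitig's weight is the novel sequence it contributes
beyond the k-2 overlap with its predecessor.  Skip-junction unitigs
contribute at most k-2 novel bases while the content they bypass contributes
strictly more, so the heaviest path walks every retained segment in order;
for error-free families whose segment union is covered by the transcript
walks, the emitted sequence equals the union exactly.  Ties break to the
lexicographically smallest unitig-id sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx

DEFAULT_K = 31


@dataclass
class Unitig:
    uid: str
    sequence: str
    first_node: str
    last_node: str


@dataclass
class DeBruijnGraph:
    k: int
    unitigs: Dict[str, Unitig]
    #: unitig adjacency: uid -> successor uids (edge = observed boundary k-mer)
    adjacency: Dict[str, Set[str]]
    #: transcript id -> ordered unitig ids of its walk
    transcript_paths: Dict[str, List[str]]
    #: k-mer -> multiplicity over all transcripts
    edge_counts: Dict[str, int] = field(default_factory=dict)


@dataclass
class UniTransModel:
    id: str
    family_id: str
    sequence: str
    unitig_order: List[str]
    assigned_transcripts: List[str]


def _fragments(seq: str) -> List[str]:
    """N splits a sequence into N-free fragments."""
    return [f for f in seq.upper().split("N") if f]


def build_graph(family_seqs: Dict[str, str], k: int = DEFAULT_K) -> DeBruijnGraph:
    """Compacted De Bruijn graph of one family, with per-transcript unitig walks."""
    if k % 2 == 0 or not 21 <= k <= 63:
        raise ValueError(f"k must be odd and in [21, 63], got {k}")
    for tid, seq in family_seqs.items():
        if max((len(f) for f in _fragments(seq)), default=0) < k:
            raise ValueError(f"transcript {tid} is shorter than k={k}")

    succ: Dict[str, Set[str]] = {}
    pred: Dict[str, Set[str]] = {}
    edge_counts: Dict[str, int] = {}
    for seq in family_seqs.values():
        for frag in _fragments(seq):
            for i in range(len(frag) - k + 1):
                kmer = frag[i : i + k]
                u, v = kmer[:-1], kmer[1:]
                succ.setdefault(u, set()).add(v)
                succ.setdefault(v, set())
                pred.setdefault(v, set()).add(u)
                pred.setdefault(u, set())
                edge_counts[kmer] = edge_counts.get(kmer, 0) + 1

    # unitig starts: nodes that cannot extend a linear path backwards
    def is_start(node: str) -> bool:
        ps = pred[node]
        if len(ps) != 1:
            return True
        return len(succ[next(iter(ps))]) != 1

    node_unitig: Dict[str, Tuple[int, int]] = {}  # node -> (unitig index, offset)
    raw_unitigs: List[List[str]] = []
    for node in sorted(succ):
        if not is_start(node) or node in node_unitig:
            continue
        path = [node]
        node_unitig[node] = (len(raw_unitigs), 0)
        cur = node
        while len(succ[cur]) == 1:
            nxt = next(iter(succ[cur]))
            if len(pred[nxt]) != 1 or nxt in node_unitig:
                break
            node_unitig[nxt] = (len(raw_unitigs), len(path))
            path.append(nxt)
            cur = nxt
        raw_unitigs.append(path)
    # leftover nodes belong to isolated cycles; break each at its minimum node
    for node in sorted(succ):
        if node in node_unitig:
            continue
        path = [node]
        node_unitig[node] = (len(raw_unitigs), 0)
        cur = node
        while True:
            nxt = next(iter(succ[cur]))
            if nxt in node_unitig:
                break
            node_unitig[nxt] = (len(raw_unitigs), len(path))
            path.append(nxt)
            cur = nxt
        raw_unitigs.append(path)

    # deterministic ids: discovery order along sorted transcript walks
    order: List[int] = []
    seen: Set[int] = set()
    walks: Dict[str, List[int]] = {}
    for tid in sorted(family_seqs):
        walk: List[int] = []
        for frag in _fragments(family_seqs[tid]):
            for i in range(len(frag) - k + 2):
                node = frag[i : i + k - 1]
                idx = node_unitig[node][0]
                if not walk or walk[-1] != idx:
                    walk.append(idx)
                if idx not in seen:
                    seen.add(idx)
                    order.append(idx)
        walks[tid] = walk
    for idx in range(len(raw_unitigs)):  # unreachable only if input empty
        if idx not in seen:
            seen.add(idx)
            order.append(idx)
    rank = {idx: i for i, idx in enumerate(order)}
    width = max(4, len(str(len(raw_unitigs))))

    def uid_of(idx: int) -> str:
        return f"u{rank[idx]:0{width}d}"

    unitigs: Dict[str, Unitig] = {}
    for idx, path in enumerate(raw_unitigs):
        seq = path[0] + "".join(n[-1] for n in path[1:])
        unitigs[uid_of(idx)] = Unitig(uid_of(idx), seq, path[0], path[-1])

    adjacency: Dict[str, Set[str]] = {u: set() for u in unitigs}
    for u in unitigs.values():
        for v_node in succ[u.last_node]:
            vidx, voff = node_unitig[v_node]
            if voff == 0:
                adjacency[u.uid].add(uid_of(vidx))

    transcript_paths = {tid: [uid_of(i) for i in walk] for tid, walk in walks.items()}
    return DeBruijnGraph(
        k=k,
        unitigs=unitigs,
        adjacency=adjacency,
        transcript_paths=transcript_paths,
        edge_counts=edge_counts,
    )


def _precedence_graph(graph: DeBruijnGraph, tids: Sequence[str]) -> nx.DiGraph:
    g = nx.DiGraph()
    for tid in tids:
        path = graph.transcript_paths[tid]
        g.add_nodes_from(path)
        g.add_edges_from(zip(path, path[1:]))
    return g


def _heaviest_path(g: nx.DiGraph, graph: DeBruijnGraph) -> List[str]:
    """Maximum-weight source-to-sink path through the walked unitig DAG.

    A unitig entered along an edge contributes its spelled length minus the
    k-2 overlap; a path's weight is the length of the sequence it spells.
    Every contribution is positive, so the optimum always extends to a source
    and a sink.  Ties break to the lexicographically smallest unitig-id
    sequence, making the emission deterministic.
    """
    k = graph.k
    contrib = {u: len(graph.unitigs[u].sequence) - (k - 2) for u in g.nodes}
    best: Dict[str, int] = {}
    back: Dict[str, Optional[str]] = {}
    for u in nx.topological_sort(g):
        preds = sorted(g.predecessors(u))
        if not preds:
            best[u], back[u] = contrib[u], None
            continue
        p = max(preds, key=lambda x: (best[x], x))
        # prefer the smallest-uid predecessor among equal weights
        p = min(x for x in preds if best[x] == best[p])
        best[u], back[u] = best[p] + contrib[u], p
    endpoints = [u for u in g.nodes if g.out_degree(u) == 0]
    tail = max(endpoints, key=lambda x: best[x])
    tail = min(x for x in endpoints if best[x] == best[tail])
    path: List[str] = []
    cur: Optional[str] = tail
    while cur is not None:
        path.append(cur)
        cur = back[cur]
    path.reverse()
    return path


def _spell(order: List[str], graph: DeBruijnGraph) -> str:
    k = graph.k
    pieces: List[str] = []
    for i, uid in enumerate(order):
        seq = graph.unitigs[uid].sequence
        if i > 0 and uid in graph.adjacency[order[i - 1]]:
            pieces.append(seq[k - 2 :])
        else:  # unitig pairs never walked consecutively join without overlap
            pieces.append(seq)
    return "".join(pieces)


def reconstruct_models(
    graph: DeBruijnGraph,
    family_id: str = "F",
    transcript_ids: Optional[Sequence[str]] = None,
    transcript_lengths: Optional[Dict[str, int]] = None,
) -> List[UniTransModel]:
    """Emit one model per acyclic transcript subset (usually one per family).

    Cyclic precedence (contradictory segment orders between transcripts) is
    resolved by greedily peeling the largest transcript subset — by descending
    transcript length, then id — whose union stays acyclic, then recursing on
    the remainder.
    """
    remaining = sorted(
        transcript_ids if transcript_ids is not None else graph.transcript_paths,
        key=lambda t: (-(transcript_lengths or {}).get(t, len(graph.transcript_paths[t])), t),
    )
    models: List[UniTransModel] = []
    n = 0
    while remaining:
        subset: List[str] = []
        g = nx.DiGraph()
        leftover: List[str] = []
        for tid in remaining:
            path = graph.transcript_paths[tid]
            trial = g.copy()
            trial.add_nodes_from(path)
            trial.add_edges_from(zip(path, path[1:]))
            if nx.is_directed_acyclic_graph(trial):
                g = trial
                subset.append(tid)
            else:
                leftover.append(tid)
        if not subset:  # a single self-contradictory transcript: emit as-is
            tid = remaining[0]
            path = graph.transcript_paths[tid]
            n += 1
            models.append(UniTransModel(f"UTM.{family_id}.{n}", family_id, _spell(path, graph), path, [tid]))
            remaining = remaining[1:]
            continue
        order = _heaviest_path(g, graph)
        n += 1
        models.append(
            UniTransModel(
                id=f"UTM.{family_id}.{n}",
                family_id=family_id,
                sequence=_spell(order, graph),
                unitig_order=order,
                assigned_transcripts=sorted(subset),
            )
        )
        remaining = leftover
    return models


def reconstruct_family(family_seqs: Dict[str, str], family_id: str = "F", k: int = DEFAULT_K) -> List[UniTransModel]:
    """Convenience: graph construction plus model emission for one family."""
    graph = build_graph(family_seqs, k=k)
    lengths = {tid: len(s) for tid, s in family_seqs.items()}
    return reconstruct_models(graph, family_id=family_id, transcript_lengths=lengths)
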