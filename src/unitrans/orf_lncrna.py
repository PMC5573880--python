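"""ORF discovery, ORF-length filtering, coding-potential scoring, and the
three-step lncRNA cascade.

The cascade mirrors the classic reference-free lncRNA screen: (a) drop
transcripts with a protein homology hit (E <= 1e-3 against the user-supplied
hit table); (b) drop transcripts whose ORF content suggests unannotated
coding potential — any complete (ATG..stop) ORF longer than 100 aa, or any
open-ended ORF longer than 50 aa at a transcript end; (c) drop transcripts a
transparent coding-potential scorer still labels coding.  Survivors are
lncRNA calls with per-step provenance.

ORF conventions (0-based half-open nt coordinates on the transcript, forward
frames by default since transcripts are oriented):

* ``complete`` — first ATG of a stop-terminated codon region to the stop;
  ``end`` includes the stop codon, ``length_aa`` excludes it.
* ``open5`` — the leading codon region of a frame, truncated at the 5' end
  (no ATG required); only emitted when it does not itself start with ATG.
* ``open3`` — first ATG after the last stop, running off the 3' end.
* ``open_both`` — a frame with no stop codon at all.

The coding-potential scorer combines ORF coverage, ORF length, the Fickett
TESTCODE statistic and an in-frame hexamer log-likelihood ratio with fixed,
documented z-scaling; it replaces an external classifier with the same role
and is pluggable (precomputed labels may be supplied to the cascade).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

DEFAULT_INTERNAL_MAX_AA = 100
DEFAULT_END_MAX_AA = 50
DEFAULT_EVALUE_MAX = 1e-3

STOPS = {"TAA", "TAG", "TGA"}

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Orf:
    frame: int
    start: int
    end: int
    length_aa: int
    completeness: str  # complete | open5 | open3 | open_both
    strand: str = "+"


@dataclass
class CodingPotential:
    orf_coverage: float
    longest_orf_aa: int
    fickett: float
    hexamer_llr: float
    combined: float
    label: str  # coding | noncoding


@dataclass
class LncRNACall:
    transcript_id: str
    passed_steps: Set[str] = field(default_factory=set)
    is_lncRNA: bool = False
    longest_orf_aa: int = 0
    combined_score: float = float("nan")


def _frame_orfs(seq: str, frame: int, strand: str) -> List[Orf]:
    codons = [(i, seq[i : i + 3]) for i in range(frame, len(seq) - 2, 3)]
    if not codons:
        return []
    orfs: List[Orf] = []
    stop_idx = [j for j, (_, c) in enumerate(codons) if c in STOPS]
    if not stop_idx:
        start, end = codons[0][0], codons[-1][0] + 3
        return [Orf(frame, start, end, len(codons), "open_both", strand)]
    # leading region up to the first stop
    first = stop_idx[0]
    if first > 0:
        region = codons[:first]
        stop_end = codons[first][0] + 3
        if region[0][1] != "ATG":
            orfs.append(Orf(frame, region[0][0], stop_end, first, "open5", strand))
    # complete ORFs in every stop-terminated region
    bounds = [(0, stop_idx[0])] + [(a + 1, b) for a, b in zip(stop_idx, stop_idx[1:])]
    for lo, hi in bounds:
        for j in range(lo, hi):
            if codons[j][1] == "ATG":
                orfs.append(Orf(frame, codons[j][0], codons[hi][0] + 3, hi - j, "complete", strand))
                break
    # trailing region after the last stop
    last = stop_idx[-1]
    tail = codons[last + 1 :]
    for j, (pos, c) in enumerate(tail):
        if c == "ATG":
            orfs.append(Orf(frame, pos, tail[-1][0] + 3, len(tail) - j, "open3", strand))
            break
    return orfs


def find_orfs(seq: str, both_strands: bool = False) -> List[Orf]:
    """All complete and open-ended ORFs per frame (forward strand by default)."""
    seq = seq.upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    orfs: List[Orf] = []
    for frame in range(3):
        orfs.extend(_frame_orfs(seq, frame, "+"))
    if both_strands:
        rc = seq.translate(_COMP)[::-1]
        for frame in range(3):
            orfs.extend(_frame_orfs(rc, frame, "-"))
    return orfs


def orf_filter(
    orfs: Sequence[Orf],
    internal_max: int = DEFAULT_INTERNAL_MAX_AA,
    end_max: int = DEFAULT_END_MAX_AA,
) -> bool:
    """True when the transcript PASSES (stays a lncRNA candidate).

    Fails — potentially coding — when any complete ORF exceeds ``internal_max``
    aa or any open-ended ORF exceeds ``end_max`` aa.
    """
    for orf in orfs:
        limit = internal_max if orf.completeness == "complete" else end_max
        if orf.length_aa > limit:
            return False
    return True


# ---------------------------------------------------------------------------
# Fickett TESTCODE statistic (position asymmetry + base composition)

_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


def fickett_score(seq: str) -> float:
    """TESTCODE score from codon-position asymmetry and base content."""
    seq = seq.upper()
    if len(seq) < 2:
        return 0.0
    score = 0.0
    for base in "ACGT":
        counts = [seq[i::3].count(base) for i in range(3)]
        pos_val = max(counts) / (min(counts) + 1.0)
        idx = next(i for i, t in enumerate(_POSITION_PARA) if pos_val >= t)
        score += _POSITION_PROB[base][idx] * _POSITION_WEIGHT[base]
        pct = seq.count(base) / len(seq)
        idx = next(i for i, t in enumerate(_CONTENT_PARA) if pct >= t)
        score += _CONTENT_PROB[base][idx] * _CONTENT_WEIGHT[base]
    return score


# ---------------------------------------------------------------------------
# in-frame hexamer log-likelihood ratio

@dataclass
class HexamerTable:
    log_ratio: Dict[str, float]

    def llr(self, seq: str) -> float:
        """Mean log-likelihood ratio over in-frame hexamers (step 3)."""
        vals = [
            self.log_ratio[seq[i : i + 6]]
            for i in range(0, len(seq) - 5, 3)
            if seq[i : i + 6] in self.log_ratio
        ]
        return sum(vals) / len(vals) if vals else 0.0


def train_hexamer_tables(coding_seqs: Iterable[str], noncoding_seqs: Iterable[str]) -> HexamerTable:
    """In-frame hexamer frequencies of each class, add-one smoothed.

    Coding sequences should be in-frame CDS.  Requires at least 10 kb of
    sequence per class.
    """

    def freqs(seqs: Iterable[str]) -> Tuple[Dict[str, int], int]:
        counts: Dict[str, int] = {}
        total_nt = 0
        for s in seqs:
            s = s.upper()
            total_nt += len(s)
            for i in range(0, len(s) - 5, 3):
                h = s[i : i + 6]
                if all(c in "ACGT" for c in h):
                    counts[h] = counts.get(h, 0) + 1
        return counts, total_nt

    c_counts, c_nt = freqs(coding_seqs)
    n_counts, n_nt = freqs(noncoding_seqs)
    if c_nt < 10_000 or n_nt < 10_000:
        raise ValueError(f"need >= 10 kb of training sequence per class (got {c_nt} coding, {n_nt} noncoding)")
    from itertools import product

    all_hex = ["".join(p) for p in product("ACGT", repeat=6)]
    c_total = sum(c_counts.values()) + len(all_hex)
    n_total = sum(n_counts.values()) + len(all_hex)
    table = {
        h: math.log(((c_counts.get(h, 0) + 1) / c_total) / ((n_counts.get(h, 0) + 1) / n_total))
        for h in all_hex
    }
    return HexamerTable(log_ratio=table)


# ---------------------------------------------------------------------------
# combined coding-potential score

#: fixed z-scaling (center, scale) and weights of the combined score
CODING_FEATURE_SCALING = {
    "orf_coverage": (0.40, 0.25),
    "log_orf_aa": (1.78, 0.40),  # log10(aa + 1); 1.78 ~ 60 aa
    "fickett": (0.95, 0.17),
    "hexamer_llr": (0.05, 0.20),
}
CODING_FEATURE_WEIGHTS = {"orf_coverage": 1.0, "log_orf_aa": 1.0, "fickett": 1.0, "hexamer_llr": 1.0}


def coding_potential(
    seq: str,
    orfs: Sequence[Orf],
    hexamer_table: HexamerTable,
    threshold: float = 0.0,
) -> CodingPotential:
    """Combined coding-potential score and label for one transcript."""
    seq = seq.upper()
    longest = max(orfs, key=lambda o: o.length_aa, default=None)
    longest_aa = longest.length_aa if longest else 0
    coverage = ((longest.end - longest.start) / len(seq)) if longest else 0.0
    orf_seq = seq[longest.start : longest.end] if longest else seq
    feats = {
        "orf_coverage": coverage,
        "log_orf_aa": math.log10(longest_aa + 1),
        "fickett": fickett_score(seq),
        "hexamer_llr": hexamer_table.llr(orf_seq),
    }
    combined = sum(
        CODING_FEATURE_WEIGHTS[f] * (feats[f] - CODING_FEATURE_SCALING[f][0]) / CODING_FEATURE_SCALING[f][1]
        for f in feats
    )
    return CodingPotential(
        orf_coverage=coverage,
        longest_orf_aa=longest_aa,
        fickett=feats["fickett"],
        hexamer_llr=feats["hexamer_llr"],
        combined=combined,
        label="noncoding" if combined < threshold else "coding",
    )


# ---------------------------------------------------------------------------
# three-step cascade

def lncrna_pipeline(
    transcripts: Dict[str, str],
    hit_table: Sequence[Tuple[str, float]],
    hexamer_table: Optional[HexamerTable] = None,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    internal_max: int = DEFAULT_INTERNAL_MAX_AA,
    end_max: int = DEFAULT_END_MAX_AA,
    coding_labels: Optional[Dict[str, str]] = None,
    threshold: float = 0.0,
) -> List[LncRNACall]:
    """Run the (a) homology, (b) ORF-length, (c) coding-potential cascade.

    ``hit_table`` rows are (transcript_id, evalue); rows for unknown ids are
    ignored with a warning.  ``coding_labels`` may supply external step-(c)
    labels keyed by transcript id, replacing the built-in scorer.  The cascade
    is order-respecting: a transcript eliminated at one step is not evaluated
    at later steps.
    """
    if hexamer_table is None and coding_labels is None:
        raise ValueError("need a hexamer table or precomputed coding labels for step (c)")
    with_hit: Set[str] = set()
    for tid, evalue in hit_table:
        if tid not in transcripts:
            warnings.warn(f"hit table references unknown transcript {tid}; row ignored")
            continue
        if evalue <= evalue_max:
            with_hit.add(tid)

    calls: List[LncRNACall] = []
    for tid in sorted(transcripts):
        call = LncRNACall(transcript_id=tid)
        if tid in with_hit:
            calls.append(call)
            continue
        call.passed_steps.add("no_protein_hit")
        orfs = find_orfs(transcripts[tid]) if len(transcripts[tid]) >= 3 else []
        call.longest_orf_aa = max((o.length_aa for o in orfs), default=0)
        if not orf_filter(orfs, internal_max=internal_max, end_max=end_max):
            calls.append(call)
            continue
        call.passed_steps.add("orf_filter")
        if coding_labels is not None:
            label = coding_labels.get(tid, "coding")
        else:
            cp = coding_potential(transcripts[tid], orfs, hexamer_table, threshold=threshold)
            call.combined_score = cp.combined
            label = cp.label
        if label == "noncoding":
            call.passed_steps.add("coding_potential")
            call.is_lncRNA = True
        calls.append(call)
    return calls
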