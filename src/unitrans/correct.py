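"""Hybrid error correction of long transcripts from a short-read k-mer spectrum.

A k-mer of the short-read set is *solid* when its canonical form (the
lexicographic minimum of the k-mer and its reverse complement) occurs at least
``solid_threshold`` times.  Long transcripts are corrected by a greedy
left-to-right scan: at the first position whose k-mer is not solid, all
single-base substitutions, deletions and insertions are tried and the edit
that maximizes the downstream run of solid k-mers is kept (ties prefer
substitution over deletion over insertion, then alphabetic order).  A second
pass over the reverse complement covers errors in the first k-1 bases, which
a forward scan cannot anchor.

The corrector is a pluggable stage: externally corrected FASTA may be supplied
to the pipeline instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

DEFAULT_K = 17
DEFAULT_SOLID_THRESHOLD = 3
DEFAULT_MAX_EDITS_PER_100NT = 5

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerSpectrum:
    k: int
    counts: Dict[str, int]
    solid_threshold: int

    def __post_init__(self) -> None:
        # practical correction uses k in [11, 31]; smaller odd k is allowed
        # for enumerable desk checks
        if self.k % 2 == 0 or not 3 <= self.k <= 31:
            raise ValueError(f"k must be odd and in [3, 31], got {self.k}")

    @property
    def empty(self) -> bool:
        return not self.counts

    def is_solid(self, kmer: str) -> bool:
        return self.counts.get(canonical(kmer), 0) >= self.solid_threshold

    def n_solid(self) -> int:
        return sum(1 for c in self.counts.values() if c >= self.solid_threshold)


def build_spectrum(
    short_reads: Iterable[str],
    k: int = DEFAULT_K,
    solid_threshold: int = DEFAULT_SOLID_THRESHOLD,
) -> KmerSpectrum:
    """Canonical k-mer counts of a short-read set.

    An empty read set yields a valid, empty spectrum (``spectrum.empty``).
    k-mers containing characters outside ACGT are skipped.
    """
    counts: Dict[str, int] = {}
    for read in short_reads:
        read = read.upper()
        for i in range(len(read) - k + 1):
            kmer = read[i : i + k]
            if any(c not in "ACGT" for c in kmer):
                continue
            c = canonical(kmer)
            counts[c] = counts.get(c, 0) + 1
    return KmerSpectrum(k=k, counts=counts, solid_threshold=solid_threshold)


def _solid_run(seq: str, start: int, spectrum: KmerSpectrum, cap: int = 64) -> int:
    """Number of consecutive solid k-mers at windows start, start+1, ..."""
    k = spectrum.k
    run = 0
    for i in range(start, min(len(seq) - k + 1, start + cap)):
        if not spectrum.is_solid(seq[i : i + k]):
            break
        run += 1
    return run


def _forward_pass(read: str, spectrum: KmerSpectrum, max_edits_per_100nt: int) -> Tuple[str, int]:
    k = spectrum.k
    seq = list(read)
    n_edits = 0
    edit_positions: List[int] = []
    i = 0
    # anchor: first solid window; the prefix is handled by the reverse pass
    while i <= len(seq) - k and not spectrum.is_solid("".join(seq[i : i + k])):
        i += 1
    while i <= len(seq) - k:
        window = "".join(seq[i : i + k])
        if spectrum.is_solid(window):
            i += 1
            continue
        # previous window was solid, so the suspect base is the window's last
        pos = i + k - 1
        recent = [p for p in edit_positions if pos - p < 100]
        if len(recent) >= max_edits_per_100nt:
            i += 1  # budget exhausted in this window: advance without editing
            continue
        candidates: List[Tuple[int, int, int, str, List[str]]] = []
        cur = seq[pos]
        for rank, (tag, variants) in enumerate(
            (
                ("sub", [[b] for b in "ACGT" if b != cur]),
                ("del", [[]]),
                ("ins", [[b, cur] for b in "ACGT"]),
            )
        ):
            for var in variants:
                trial = seq[:pos] + var + seq[pos + 1 :]
                if i > len(trial) - k:
                    continue
                if not spectrum.is_solid("".join(trial[i : i + k])):
                    continue
                run = _solid_run("".join(trial), i, spectrum)
                candidates.append((-run, rank, 0, "".join(var), trial))
        if candidates:
            candidates.sort(key=lambda c: (c[0], c[1], c[3]))
            best_run = -candidates[0][0]
            # only commit when the edit restores a convincing solid run
            if best_run >= min(3, len(seq) - k - i + 1):
                seq = candidates[0][4]
                n_edits += 1
                edit_positions.append(pos)
                i += 1
                continue
        i += 1
    return "".join(seq), n_edits


def correct_read(
    read: str,
    spectrum: KmerSpectrum,
    max_edits_per_100nt: int = DEFAULT_MAX_EDITS_PER_100NT,
) -> Tuple[str, int]:
    """Greedy spectrum-based correction of one long read.

    Returns ``(corrected, n_edits)``.  With an empty spectrum, or a read from
    a transcript absent from the short reads (no solid anchor), the input is
    returned unchanged with ``n_edits = 0``.
    """
    if spectrum.empty or len(read) < spectrum.k:
        return read, 0
    corrected, n1 = _forward_pass(read, spectrum, max_edits_per_100nt)
    # the spectrum is canonical, so a pass over the reverse complement fixes
    # errors inside the first k-1 bases
    rc, n2 = _forward_pass(revcomp(corrected), spectrum, max_edits_per_100nt)
    return revcomp(rc), n1 + n2


def correct_all(
    transcripts: Dict[str, str],
    spectrum: KmerSpectrum,
    max_edits_per_100nt: int = DEFAULT_MAX_EDITS_PER_100NT,
) -> Tuple[Dict[str, str], Dict[str, int]]:
    out: Dict[str, str] = {}
    edits: Dict[str, int] = {}
    for tid in transcripts:
        out[tid], edits[tid] = correct_read(transcripts[tid], spectrum, max_edits_per_100nt)
    return out, edits
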