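"""Summary statistics and cross-set comparisons.

N50, length histograms, full-length-ORF coverage classes over a user-supplied
protein hit table, and tissue-specific model matching by sequence similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .dedup import _prescreen_reject, pairwise_redundancy

DEFAULT_IDENTITY_MIN = 0.90
DEFAULT_COVERAGE_MIN = 0.80


@dataclass(frozen=True)
class CoverageRecord:
    """Best-hit coverage of a curated full-length protein by one query."""

    query_id: str
    subject_id: str
    subject_length: int
    aligned_subject_span: int

    @property
    def coverage(self) -> float:
        cov = self.aligned_subject_span / self.subject_length
        if not 0 < cov <= 1:
            raise ValueError(f"coverage out of (0, 1]: {cov}")
        return cov


def n50(lengths: Sequence[int]) -> int:
    """Length N such that sequences of length >= N hold half of all bases."""
    if not lengths:
        raise ValueError("n50 of an empty set is undefined")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for l in ordered:
        acc += l
        if acc >= half:
            return l
    raise AssertionError("unreachable")


def coverage_classes(
    records: Sequence[CoverageRecord],
) -> Tuple[float, float, pd.DataFrame]:
    """Full (coverage == 1.0) and near-full (> 0.8) fractions, plus the
    cumulative density of best-hit coverage on a 0..1 grid (step 0.01).

    When a query has several records only its highest coverage counts.
    """
    best: Dict[str, float] = {}
    for r in records:
        cov = r.coverage
        if cov > best.get(r.query_id, 0.0):
            best[r.query_id] = cov
    if not best:
        return 0.0, 0.0, pd.DataFrame({"coverage": [], "cumulative_fraction": []})
    covs = np.array(sorted(best.values()))
    full = float(np.mean(covs == 1.0))
    near_full = float(np.mean(covs > 0.8))
    grid = np.round(np.arange(0, 1.01, 0.01), 2)
    cdf = [float(np.mean(covs <= g)) for g in grid]
    table = pd.DataFrame({"coverage": grid, "cumulative_fraction": cdf})
    return full, near_full, table


def _matches_any(seq: str, others: Dict[str, str], identity_min: float, coverage_min: float) -> bool:
    for oid in sorted(others):
        other = others[oid]
        if _prescreen_reject(seq, other, identity_min, AS=int((1 - coverage_min) * min(len(seq), len(other)))):
            continue
        ident, cov, _ = pairwise_redundancy(seq, other)
        if ident >= identity_min and cov >= coverage_min:
            return True
    return False


def cross_set_matching(
    models_a: Dict[str, str],
    models_b: Dict[str, str],
    identity_min: float = DEFAULT_IDENTITY_MIN,
    coverage_min: float = DEFAULT_COVERAGE_MIN,
) -> Tuple[List[str], List[str], List[str], List[str]]:
    """Shared vs set-specific models between two tissues.

    A model is *shared* when some model of the other set aligns to it at
    identity >= identity_min over >= coverage_min of the shorter sequence.
    Returns (shared_a, specific_a, shared_b, specific_b).
    """
    if not models_a or not models_b:
        raise ValueError("both model sets must be non-empty")
    shared_a = [m for m in sorted(models_a) if _matches_any(models_a[m], models_b, identity_min, coverage_min)]
    shared_b = [m for m in sorted(models_b) if _matches_any(models_b[m], models_a, identity_min, coverage_min)]
    specific_a = [m for m in sorted(models_a) if m not in set(shared_a)]
    specific_b = [m for m in sorted(models_b) if m not in set(shared_b)]
    return shared_a, specific_a, shared_b, specific_b


def length_histogram(seqs: Dict[str, str] | Sequence[str], bin_size: int = 100) -> pd.DataFrame:
    """Counts of sequence lengths per half-open bin [i*bin, (i+1)*bin)."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    lengths = [len(s) for s in (seqs.values() if isinstance(seqs, dict) else seqs)]
    if not lengths:
        return pd.DataFrame({"bin_start": [], "bin_end": [], "count": []})
    counts: Dict[int, int] = {}
    for l in lengths:
        counts[l // bin_size] = counts.get(l // bin_size, 0) + 1
    bins = sorted(counts)
    return pd.DataFrame(
        {
            "bin_start": [b * bin_size for b in bins],
            "bin_end": [(b + 1) * bin_size for b in bins],
            "count": [counts[b] for b in bins],
        }
    )
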