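"""Genuine-barcode calling: Levenshtein-1 error clustering + knee-point threshold.

Sequencing errors scatter reads from each true clone barcode onto a halo of
near-identical sequences.  Two steps separate genuine clone barcodes from this
background:

1. greedy error clustering — each low-count barcode is absorbed into its
   highest-count neighbor within a small Levenshtein distance (default 1)
   provided the neighbor is at least ``merge_ratio`` times more abundant;
2. an unbiased knee-point threshold on the clustered rank/count curve in
   log10-log10 space; barcodes strictly above the threshold are genuine.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Set, Tuple

import edlib
import numpy as np

from .reads import CountTable


@dataclass(frozen=True)
class ClusteringParams:
    """max_distance: Levenshtein radius; merge_ratio: min parent:child count ratio."""

    max_distance: int = 1
    merge_ratio: float = 5.0

    def __post_init__(self) -> None:
        if self.max_distance < 0:
            raise ValueError("max_distance must be >= 0")
        if self.merge_ratio < 1:
            raise ValueError("merge_ratio must be >= 1")


def levenshtein_within(a: str, b: str, k: int) -> bool:
    """True iff Levenshtein(a, b) <= k."""
    if a == b:
        return k >= 0
    if abs(len(a) - len(b)) > k:
        return False
    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"] != -1


def _deletion_keys(seq: str) -> List[str]:
    # seq plus every single-deletion variant: two sequences are within
    # Levenshtein distance 1 only if they share one of these keys (sharing a
    # key is necessary, not sufficient, so candidates are verified).
    keys = [seq]
    keys.extend(seq[:i] + seq[i + 1 :] for i in range(len(seq)))
    return keys


def _neighbor_candidates(seqs: Sequence[str]) -> Dict[str, Set[str]]:
    index: Dict[str, List[str]] = defaultdict(list)
    for s in seqs:
        for key in set(_deletion_keys(s)):
            index[key].append(s)
    cand: Dict[str, Set[str]] = {s: set() for s in seqs}
    for bucket in index.values():
        if len(bucket) < 2:
            continue
        for s in bucket:
            cand[s].update(bucket)
    for s in seqs:
        cand[s].discard(s)
    return cand


def cluster_counts(table: CountTable, params: ClusteringParams = ClusteringParams()) -> CountTable:
    """Absorb error barcodes into abundant neighbors; total count is conserved.

    Barcodes are processed smallest count first; each is merged into the
    highest-count surviving barcode within ``max_distance`` whose current
    count is at least ``merge_ratio`` times its own (ties broken by
    lexicographically smallest sequence).  Surviving keys are cluster
    centroids.
    """
    if not table.counts:
        raise ValueError("empty count table")
    counts = dict(table.counts)
    seqs = list(counts)
    if params.max_distance == 1:
        candidates = _neighbor_candidates(seqs)
    else:
        candidates = {s: set(o for o in seqs if o != s) for s in seqs}

    order = sorted(seqs, key=lambda s: (table.counts[s], s))
    alive = set(seqs)
    for s in order:
        if s not in alive:
            continue
        best: Optional[str] = None
        for other in candidates[s]:
            if other not in alive:
                continue
            if counts[other] < params.merge_ratio * counts[s]:
                continue
            if not levenshtein_within(s, other, params.max_distance):
                continue
            if best is None or (counts[other], ) > (counts[best], ) or (
                counts[other] == counts[best] and other < best
            ):
                best = other
        if best is not None:
            counts[best] += counts[s]
            del counts[s]
            alive.discard(s)
    return CountTable(
        counts=counts,
        sample_id=table.sample_id,
        total_reads_in=table.total_reads_in,
        reads_extracted=table.reads_extracted,
    )


# ---------------------------------------------------------------------------
# knee point


class KneeResult(NamedTuple):
    threshold: int
    knee_rank: int        # 1-based rank of the max-distance point
    max_distance: float   # perpendicular distance in log10 units
    degenerate: bool


#: minimum perpendicular distance (decades) for a knee to count as real
MIN_CURVATURE = 0.1


def knee_point_threshold(counts: Sequence[int]) -> KneeResult:
    """Knee of the descending rank/count curve in log10-log10 space.

    The knee is the point of maximum perpendicular distance from the chord
    joining the first and last points.  When that point lies above the chord
    (the bulge of genuine barcodes) the threshold is the count at the next
    rank; when it lies below (start of the error tail) it is the count at the
    knee itself.  Genuine barcodes are those with count strictly greater than
    the threshold, so the knee-rank barcode is kept in the first case and
    dropped in the second.  Curves deviating less than ``MIN_CURVATURE``
    decades from the chord carry no knee and are flagged degenerate
    (threshold 0: keep everything).
    """
    c = sorted((int(v) for v in counts), reverse=True)
    if any(v <= 0 for v in c):
        raise ValueError("counts must be positive")
    n = len(c)
    if n < 3:
        return KneeResult(0, 0, 0.0, True)
    x = np.log10(np.arange(1, n + 1, dtype=float))
    y = np.log10(np.asarray(c, dtype=float))
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = math.hypot(dx, dy)
    if norm == 0:
        return KneeResult(0, 0, 0.0, True)
    # signed distance: positive = below the chord (count lower than chord)
    d = ((x - x[0]) * dy - (y - y[0]) * dx) / norm
    i = int(np.argmax(np.abs(d)))
    dist = float(abs(d[i]))
    if dist < MIN_CURVATURE:
        return KneeResult(0, 0, dist, True)
    if d[i] < 0:  # knee above chord: last genuine point
        threshold = c[i + 1] if i + 1 < n else 0
    else:  # knee below chord: first noise point
        threshold = c[i]
    return KneeResult(int(threshold), i + 1, dist, False)


# ---------------------------------------------------------------------------
# calling


@dataclass
class CallResult:
    genuine: Set[str]
    threshold: int
    clustered_counts: CountTable
    knee_rank: int
    degenerate_knee: bool = False


def call_genuine(
    table: CountTable, params: ClusteringParams = ClusteringParams()
) -> CallResult:
    """Cluster then threshold; genuine = clustered count strictly above knee."""
    clustered = cluster_counts(table, params)
    knee = knee_point_threshold(list(clustered.counts.values()))
    genuine = {s for s, c in clustered.counts.items() if c > knee.threshold}
    return CallResult(
        genuine=genuine,
        threshold=knee.threshold,
        clustered_counts=clustered,
        knee_rank=knee.knee_rank,
        degenerate_knee=knee.degenerate,
    )


@dataclass
class ContaminationReport:
    passed: bool
    n_genuine: int
    expected_n: int
    fractions: Dict[str, float] = field(default_factory=dict)


def cross_contamination_report(result: CallResult, expected_n: int) -> ContaminationReport:
    """Flag wells whose genuine-barcode count exceeds the expected clone number.

    Fractions are each genuine barcode's share of the total clustered reads,
    so a 1:100 contaminant shows up with fraction ~0.01.
    """
    if expected_n < 1:
        raise ValueError("expected_n must be >= 1")
    total = result.clustered_counts.total
    fractions = {
        s: result.clustered_counts.counts[s] / total for s in sorted(result.genuine)
    }
    return ContaminationReport(
        passed=len(result.genuine) <= expected_n,
        n_genuine=len(result.genuine),
        expected_n=expected_n,
        fractions=fractions,
    )
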