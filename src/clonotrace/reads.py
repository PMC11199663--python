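"""Amplicon read processing: adapter trim, pair merge, flank-anchored barcode extraction.

The amplicon places the 15-nt clone barcode between two known flanking
sequences.  Raw 2x150 paired-end reads are adapter-trimmed, merged by best
overlap with quality-weighted consensus, and the barcode is pulled out by
locating the left then the right flank (searching the reverse complement when
the forward orientation fails).  Inserts whose length differs from the
expected 15 are discarded, as are reads without recognizable flanks; every
rejection is categorized and counted.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field as dc_field
from typing import Dict, Iterable, Iterator, Optional, Tuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class FlankSpec:
    """Left/right flanking sequences delimiting the barcode insert."""

    left_flank: str
    right_flank: str
    expected_length: int = 15
    max_flank_mismatches: int = 0

    def __post_init__(self) -> None:
        if not self.left_flank or not self.right_flank:
            raise ValueError("flanks must be non-empty")
        if self.expected_length < 1:
            raise ValueError("expected_length must be >= 1")


#: Flank pairs of the three amplicon designs (one per expressed molecule).
FLANKS: Dict[str, FlankSpec] = {
    "M1": FlankSpec("GCTTAGCCGCTTAAT", "AACATCTAATGCGTA"),
    "M2": FlankSpec("CTTAGCCGCTTAAT", "AACTTAGCTCGCGTA"),
    "M3": FlankSpec("GCTTAGCCGCTTAAT", "AACCTCGCTTGCGTA"),
}


@dataclass
class ReadPair:
    id: str
    forward_seq: str
    forward_qual: str
    reverse_seq: str
    reverse_qual: str

    def __post_init__(self) -> None:
        if len(self.forward_seq) != len(self.forward_qual):
            raise ValueError(f"{self.id}: forward sequence/quality length mismatch")
        if len(self.reverse_seq) != len(self.reverse_qual):
            raise ValueError(f"{self.id}: reverse sequence/quality length mismatch")


@dataclass
class CountTable:
    """Per-sample barcode read counts — the central currency between stages."""

    counts: Dict[str, int] = dc_field(default_factory=dict)
    sample_id: str = ""
    total_reads_in: int = 0
    reads_extracted: int = 0

    def __post_init__(self) -> None:
        extracted = sum(self.counts.values())
        if self.reads_extracted == 0 and extracted:
            self.reads_extracted = extracted
        if self.total_reads_in == 0:
            self.total_reads_in = self.reads_extracted

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# adapter trimming


def _trim_one(seq: str, qual: str, adapter: str, min_overlap: int) -> Tuple[str, str]:
    # longest 3' suffix of the read that equals a prefix of the adapter
    max_len = min(len(seq), len(adapter))
    for length in range(max_len, min_overlap - 1, -1):
        if seq.endswith(adapter[:length]):
            return seq[: len(seq) - length], qual[: len(qual) - length]
    return seq, qual


def trim_adapters(pair: ReadPair, adapter: str, min_overlap: int = 3) -> ReadPair:
    """Remove a 3' adapter suffix (>= min_overlap bases) from each mate."""
    if not adapter:
        raise ValueError("adapter must be non-empty")
    fs, fq = _trim_one(pair.forward_seq, pair.forward_qual, adapter, min_overlap)
    rs, rq = _trim_one(pair.reverse_seq, pair.reverse_qual, adapter, min_overlap)
    return ReadPair(pair.id, fs, fq, rs, rq)


# ---------------------------------------------------------------------------
# pair merging


@dataclass
class MergedRead:
    seq: str
    qual: str


def merge_pair(
    pair: ReadPair, min_overlap: int = 10, max_mismatch_frac: float = 0.25
) -> Optional[MergedRead]:
    """Merge mates by their best 3' overlap; None when no acceptable overlap.

    The reverse mate is reverse-complemented, all overlap lengths from
    ``min_overlap`` upward are scored, and the overlap with the most matching
    bases (ties to the longer overlap) is taken provided its mismatch fraction
    stays within ``max_mismatch_frac``.  At mismatched positions the
    higher-quality base wins.
    """
    if not pair.forward_seq or not pair.reverse_seq:
        raise ValueError("both mates must be non-empty")
    f, fq = pair.forward_seq, pair.forward_qual
    r = reverse_complement(pair.reverse_seq)
    rq = pair.reverse_qual[::-1]

    best = None  # (matches, overlap_len, mismatches)
    upper = min(len(f), len(r))
    for L in range(min_overlap, upper + 1):
        a, b = f[-L:], r[:L]
        mism = sum(1 for x, y in zip(a, b) if x != y)
        if mism / L > max_mismatch_frac:
            continue
        matches = L - mism
        if best is None or (matches, L) > (best[0], best[1]):
            best = (matches, L, mism)
    if best is None:
        return None
    L = best[1]
    cons, consq = [], []
    for i in range(L):
        cf, cr = f[len(f) - L + i], r[i]
        qf, qr = fq[len(fq) - L + i], rq[i]
        if cf == cr or qf >= qr:
            cons.append(cf)
            consq.append(max(qf, qr) if cf == cr else qf)
        else:
            cons.append(cr)
            consq.append(qr)
    seq = f[:-L] + "".join(cons) + r[L:]
    qual = fq[:-L] + "".join(consq) + rq[L:]
    return MergedRead(seq, qual)


# ---------------------------------------------------------------------------
# barcode extraction

FLANK_NOT_FOUND = "flank_not_found"
WRONG_LENGTH = "wrong_length"
AMBIGUOUS = "ambiguous_multiple_hits"
UNMERGED = "unmerged"


def _find_all(haystack: str, needle: str, max_mismatches: int) -> list:
    if max_mismatches == 0:
        hits, start = [], 0
        while True:
            i = haystack.find(needle, start)
            if i < 0:
                return hits
            hits.append(i)
            start = i + 1
    hits = []
    n = len(needle)
    for i in range(len(haystack) - n + 1):
        mism = 0
        window = haystack[i : i + n]
        for x, y in zip(window, needle):
            if x != y:
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            hits.append(i)
    return hits


def _extract_oriented(seq: str, flanks: FlankSpec) -> Tuple[Optional[str], str]:
    mm = flanks.max_flank_mismatches
    left_hits = _find_all(seq, flanks.left_flank, mm)
    if not left_hits:
        return None, FLANK_NOT_FOUND
    if len(left_hits) > 1:
        return None, AMBIGUOUS
    start = left_hits[0] + len(flanks.left_flank)
    right_hits = _find_all(seq[start:], flanks.right_flank, mm)
    if not right_hits:
        return None, FLANK_NOT_FOUND
    insert = seq[start : start + right_hits[0]]
    if len(insert) != flanks.expected_length:
        return None, WRONG_LENGTH
    return insert, "ok"


def extract_barcode(seq: str, flanks: FlankSpec) -> Tuple[Optional[str], str]:
    """Extract the barcode between the flanks; returns (barcode, reason).

    The forward orientation is tried first; if its left flank is absent the
    reverse complement is searched.  ``reason`` is "ok" on success, otherwise
    one of flank_not_found / wrong_length / ambiguous_multiple_hits.
    """
    if not seq:
        raise ValueError("empty sequence")
    bc, reason = _extract_oriented(seq, flanks)
    if bc is not None or reason != FLANK_NOT_FOUND:
        return bc, reason
    return _extract_oriented(reverse_complement(seq), flanks)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RejectionReport:
    by_reason: Dict[str, int] = dc_field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.by_reason.values())


def count_merged(
    seq_counts: Iterable[Tuple[str, int]], flanks: FlankSpec, sample_id: str = ""
) -> Tuple[CountTable, RejectionReport]:
    """Count barcodes from (merged sequence, multiplicity) pairs."""
    counts: Counter = Counter()
    rej: Counter = Counter()
    n_in = 0
    for seq, mult in seq_counts:
        n_in += mult
        bc, reason = extract_barcode(seq, flanks)
        if bc is None:
            rej[reason] += mult
        else:
            counts[bc] += mult
    table = CountTable(
        counts=dict(counts),
        sample_id=sample_id,
        total_reads_in=n_in,
        reads_extracted=sum(counts.values()),
    )
    return table, RejectionReport(dict(rej))


def count_barcodes(
    pairs: Iterable[ReadPair],
    flanks: FlankSpec,
    adapter: Optional[str] = None,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
    sample_id: str = "",
) -> Tuple[CountTable, RejectionReport]:
    """Full pipeline: trim -> merge -> extract -> count.

    Unmerged pairs are dropped and counted under the "unmerged" reason;
    conservation total_reads_in = reads_extracted + sum(rejections) holds.
    """
    counts: Counter = Counter()
    rej: Counter = Counter()
    n_in = 0
    for pair in pairs:
        n_in += 1
        if adapter:
            pair = trim_adapters(pair, adapter)
        merged = merge_pair(pair, min_overlap, max_mismatch_frac)
        if merged is None:
            rej[UNMERGED] += 1
            continue
        bc, reason = extract_barcode(merged.seq, flanks)
        if bc is None:
            rej[reason] += 1
        else:
            counts[bc] += 1
    table = CountTable(
        counts=dict(counts),
        sample_id=sample_id,
        total_reads_in=n_in,
        reads_extracted=sum(counts.values()),
    )
    return table, RejectionReport(dict(rej))


# ---------------------------------------------------------------------------
# FASTQ IO (gzip transparent)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(r1_path, r2_path) -> Iterator[ReadPair]:
    """Stream read pairs from two (optionally gzipped) FASTQ files."""
    with _open_text(r1_path) as h1, _open_text(r2_path) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        for i, ((id1, s1, q1), (id2, s2, q2)) in enumerate(zip(it1, it2)):
            yield ReadPair(id1.split()[0], s1.upper(), q1, s2.upper(), q2)


def write_fastq_pairs(pairs: Iterable[ReadPair], r1_path, r2_path) -> None:
    op = gzip.open if str(r1_path).endswith(".gz") else open
    with op(r1_path, "wt") as h1, op(r2_path, "wt") as h2:
        for p in pairs:
            h1.write(f"@{p.id}/1\n{p.forward_seq}\n+\n{p.forward_qual}\n")
            h2.write(f"@{p.id}/2\n{p.reverse_seq}\n+\n{p.reverse_qual}\n")
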