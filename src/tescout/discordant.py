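"""Selection of discordant read pairs and anchor-read extraction.

A read pair predicts a TE insertion when it maps discordantly — not flagged as
a proper pair, and either on different chromosomes or at a mapping distance
greater than twice the mean fragment length — with one read (the anchor)
mapping uniquely and confidently to non-TE sequence and its mate hitting an
annotated TE at any of its placements. Each anchor predicts an insertion
within one fragment length (plus a jitter margin of s standard deviations)
downstream of itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterator, List, Optional, Tuple

import pysam

from .annotation import TEIndex
from .library import LibraryStats, RunParams
from .reads import ReadAlignment

log = logging.getLogger(__name__)

__all__ = [
    "AnchorRead",
    "is_repetitive",
    "is_valid_discordant",
    "classify_pair",
    "predicted_interval",
    "scan_bam",
]


@dataclass(frozen=True)
class AnchorRead:
    """A uniquely mapped anchor whose mate hits annotated TEs."""

    anchor: ReadAlignment
    te_hits: FrozenSet[str]
    interval: Tuple[str, int, int]  # predicted insertion interval, 0-based half-open

    def __post_init__(self) -> None:
        if not self.te_hits:
            raise ValueError("te_hits must be non-empty")
        _, lo, hi = self.interval
        if not lo < hi:
            raise ValueError(f"predicted interval empty: [{lo}, {hi})")


def is_repetitive(read: ReadAlignment) -> bool:
    """A read is repetitively mapped if mapq is 0 or it has alternative hits."""
    return read.mapq == 0 or bool(read.alt_hits)


def is_valid_discordant(r1: ReadAlignment, r2: ReadAlignment, stats: LibraryStats) -> bool:
    """True when the pair maps discordantly.

    Proper-pair-flagged pairs are never discordant; otherwise the reads must
    lie on different chromosomes or at a mapping distance (difference of
    leftmost coordinates) greater than 2 x mean fragment length.
    """
    if r1.proper_pair or r2.proper_pair:
        return False
    if r1.chrom != r2.chrom:
        return True
    return abs(r1.start - r2.start) > 2 * stats.fragment_mean


def predicted_interval(
    anchor: ReadAlignment, stats: LibraryStats, params: RunParams
) -> Optional[Tuple[str, int, int]]:
    """Predicted insertion interval downstream of the anchor (strandwise).

    Forward anchor: (anchor end, anchor start + fragment + s*sd]; reverse
    anchor: [anchor end - fragment - s*sd, anchor start). Returns None (with
    a warning) if the interval is empty under pathological statistics.
    """
    reach = int(round(stats.fragment_mean + params.s_factor * stats.fragment_sd))
    if anchor.is_forward:
        lo, hi = anchor.end, anchor.start + reach
    else:
        lo, hi = anchor.end - reach, anchor.start
    if lo >= hi:
        log.warning(
            "anchor %s at %s:%d-%d yields empty predicted interval [%d, %d); discarded",
            anchor.name, anchor.chrom, anchor.start, anchor.end, lo, hi,
        )
        return None
    return anchor.chrom, lo, hi


def _mate_te_hits(mate: ReadAlignment, te_index: TEIndex) -> FrozenSet[str]:
    """TE names overlapped by the mate at its primary or any alternative placement."""
    hits = {f.name for f in te_index.overlapping(mate.chrom, mate.start, mate.end)}
    for alt in mate.alt_hits:
        hits.update(f.name for f in te_index.overlapping(alt.chrom, alt.start, alt.end))
    return frozenset(hits)


def _try_anchor(
    anchor: ReadAlignment,
    mate: ReadAlignment,
    te_index: TEIndex,
    stats: LibraryStats,
    params: RunParams,
) -> Optional[AnchorRead]:
    if is_repetitive(anchor) or anchor.mapq < params.mapq_min:
        return None
    if te_index.overlaps(anchor.chrom, anchor.start, anchor.end):
        return None
    hits = _mate_te_hits(mate, te_index)
    if not hits:
        return None
    interval = predicted_interval(anchor, stats, params)
    if interval is None:
        return None
    return AnchorRead(anchor, hits, interval)


def classify_pair(
    r1: ReadAlignment,
    r2: ReadAlignment,
    te_index: TEIndex,
    stats: LibraryStats,
    params: RunParams,
) -> Optional[AnchorRead]:
    """Extract the anchor from a valid discordant pair, or None.

    The anchor must be non-repetitive, pass the mapping-quality threshold
    (which applies to the anchor only) and overlap no annotated TE; the mate
    must hit at least one TE at its primary or any alternative placement.
    """
    for anchor, mate in ((r1, r2), (r2, r1)):
        res = _try_anchor(anchor, mate, te_index, stats, params)
        if res is not None:
            return res
    return None


def _candidate(rec, two_frag: float) -> bool:
    """Cheap per-record test for potential membership in a valid discordant pair."""
    if rec.is_unmapped or rec.mate_is_unmapped or rec.is_secondary or rec.is_supplementary:
        return False
    if rec.is_proper_pair:
        return False
    if rec.reference_id != rec.next_reference_id:
        return True
    return abs(rec.reference_start - rec.next_reference_start) > two_frag


def scan_bam(
    bam: pysam.AlignmentFile,
    te_index: TEIndex,
    stats: LibraryStats,
    params: RunParams,
) -> Tuple[List[AnchorRead], float]:
    """Stream the BAM once, collecting anchor reads and the mean coverage.

    Discordant-candidate records are held by name until their mate is seen,
    then the pair is classified. Returns (anchors, fold-coverage over the
    reference sequences in the BAM header).
    """
    two_frag = 2 * stats.fragment_mean
    pending: Dict[str, ReadAlignment] = {}
    anchors: List[AnchorRead] = []
    total_bases = 0
    for rec in bam.fetch(until_eof=True):
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        total_bases += rec.query_alignment_length
        if not _candidate(rec, two_frag):
            continue
        read = ReadAlignment.from_pysam(rec)
        other = pending.pop(read.name, None)
        if other is None:
            pending[read.name] = read
            continue
        if not is_valid_discordant(read, other, stats):
            continue
        res = classify_pair(read, other, te_index, stats, params)
        if res is not None:
            anchors.append(res)
    total_ref = sum(bam.lengths)
    coverage = total_bases / total_ref if total_ref else 0.0
    return anchors, coverage
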