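"""Somatic vs germline classification of tumor-unique TEI calls.

Calls present in the filtered tumor (TD) set but absent from the unfiltered
normal (ND) set are putative somatic insertions; each is then checked against
the ND alignments in a window around the locus. Two percent or more
discordant reads there indicates a false negative in ND (the insertion is
germline); mean coverage below 8X indicates the ND sample cannot exclude the
insertion (indeterminate). Only clean, well-covered loci are called somatic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import pysam

from .calls import TEICall
from .library import LibraryStats

__all__ = [
    "SomaticVerdict",
    "td_unique_calls",
    "nd_window_stats",
    "classify_somatic",
    "run_somatic",
    "DISCORDANT_THRESHOLD",
    "MIN_ND_COVERAGE",
    "ND_WINDOW",
]

DISCORDANT_THRESHOLD = 0.02
MIN_ND_COVERAGE = 8.0
ND_WINDOW = 200
TD_UNIQUE_PAD = 200


@dataclass(frozen=True)
class SomaticVerdict:
    """Classification of one TD-unique call against the ND alignments."""

    call: TEICall
    nd_discordant_fraction: float
    nd_mean_coverage: float
    verdict: str  # somatic | germline_fn | low_coverage_fn

    def __post_init__(self) -> None:
        if not 0.0 <= self.nd_discordant_fraction <= 1.0:
            raise ValueError("nd_discordant_fraction out of [0, 1]")


def td_unique_calls(
    td_filtered: Iterable[TEICall],
    nd_raw: Iterable[TEICall],
    pad: int = TD_UNIQUE_PAD,
) -> List[TEICall]:
    """TD calls whose padded interval overlaps no raw ND call interval."""
    nd_by_chrom: dict = {}
    for c in nd_raw:
        nd_by_chrom.setdefault(c.chrom, []).append((c.lo, c.hi))
    out = []
    for c in td_filtered:
        lo, hi = c.lo - pad, c.hi + pad
        hits = nd_by_chrom.get(c.chrom, ())
        if not any(lo < nhi and nlo < hi for nlo, nhi in hits):
            out.append(c)
    return out


def nd_window_stats(
    nd_bam: pysam.AlignmentFile,
    chrom: str,
    locus: int,
    stats: LibraryStats,
    window: int = ND_WINDOW,
) -> Tuple[float, float]:
    """Discordant-read fraction and mean coverage in a window around a locus.

    The window is centred on the locus. A read is discordant when its pair is
    not proper-paired and maps to a different chromosome or at a distance
    greater than twice the mean fragment length. Returns (0, 0) for an empty
    window.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    lo = max(0, locus - window // 2)
    hi = lo + window
    two_frag = 2 * stats.fragment_mean
    n_reads = 0
    n_disc = 0
    bases = 0
    for rec in nd_bam.fetch(chrom, lo, hi):
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        n_reads += 1
        bases += min(rec.reference_end, hi) - max(rec.reference_start, lo)
        if rec.mate_is_unmapped or rec.is_proper_pair:
            continue
        if rec.reference_id != rec.next_reference_id:
            n_disc += 1
        elif abs(rec.reference_start - rec.next_reference_start) > two_frag:
            n_disc += 1
    if n_reads == 0:
        return 0.0, 0.0
    return n_disc / n_reads, bases / window


def classify_somatic(
    call: TEICall,
    nd_discordant_fraction: float,
    nd_mean_coverage: float,
    discordant_threshold: float = DISCORDANT_THRESHOLD,
    min_cov: float = MIN_ND_COVERAGE,
) -> SomaticVerdict:
    """Apply the discordant-fraction and coverage rules to a TD-unique call."""
    if nd_discordant_fraction >= discordant_threshold:
        verdict = "germline_fn"
    elif nd_mean_coverage < min_cov:
        verdict = "low_coverage_fn"
    else:
        verdict = "somatic"
    return SomaticVerdict(call, nd_discordant_fraction, nd_mean_coverage, verdict)


def run_somatic(
    td_filtered: Sequence[TEICall],
    nd_raw: Sequence[TEICall],
    nd_bam: pysam.AlignmentFile,
    stats: LibraryStats,
    window: int = ND_WINDOW,
    pad: int = TD_UNIQUE_PAD,
    discordant_threshold: float = DISCORDANT_THRESHOLD,
    min_cov: float = MIN_ND_COVERAGE,
) -> List[SomaticVerdict]:
    """Full TD/ND comparison: subtraction, window stats, classification."""
    verdicts = []
    for call in td_unique_calls(td_filtered, nd_raw, pad):
        frac, cov = nd_window_stats(nd_bam, call.chrom, call.locus, stats, window)
        verdicts.append(
            classify_somatic(call, frac, cov, discordant_threshold, min_cov)
        )
    return verdicts
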