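"""Breakpoint refinement from soft-clipped reads, core-read counting and zygosity.

Reads truncated (soft-clipped) at an insertion junction pinpoint the
breakpoint: clip boundary positions within the insertion interval are grouped
within +/-3 bp and the best-supported group's modal position is reported.
Properly-paired reads spanning the breakpoint by at least five bases on each
side ("core reads") evidence the reference allele; zygosity (variant allele
fraction) is clipped / (clipped + core).
"""

from __future__ import annotations

from collections import Counter
from typing import List, Optional, Tuple

import pysam

from .clustering import ClusterPair

__all__ = [
    "MIN_CLIP",
    "CLIP_GROUP_TOL",
    "CORE_MARGIN",
    "find_breakpoint",
    "count_core_reads",
    "zygosity",
    "annotate_te_identity",
]

# soft-clips shorter than this are adapter/quality noise, not junction evidence
MIN_CLIP = 5
# clip positions within this distance support the same breakpoint
CLIP_GROUP_TOL = 3
# a core read must cover the breakpoint by this many bases on each side
CORE_MARGIN = 5


def clip_positions(rec, min_clip: int = MIN_CLIP) -> List[int]:
    """Reference coordinates of soft-clip boundaries with clip length >= min_clip."""
    cig = rec.cigartuples
    if not cig:
        return []
    out = []
    if cig[0][0] == 4 and cig[0][1] >= min_clip:
        out.append(rec.reference_start)
    if cig[-1][0] == 4 and cig[-1][1] >= min_clip:
        out.append(rec.reference_end)
    return out


def _group_clips(positions: List[int], tol: int = CLIP_GROUP_TOL) -> List[Tuple[int, int]]:
    """Greedy left-to-right grouping of clip positions within +/-tol of the
    group's first member; returns (modal position, support) per group, modal
    ties broken to the leftmost position."""
    groups: List[List[int]] = []
    for pos in sorted(positions):
        if groups and pos - groups[-1][0] <= tol:
            groups[-1].append(pos)
        else:
            groups.append([pos])
    out = []
    for grp in groups:
        counts = Counter(grp)
        best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
        out.append((best[0], len(grp)))
    return out


def find_breakpoint(
    bam: pysam.AlignmentFile,
    chrom: str,
    lo: int,
    hi: int,
    min_clip: int = MIN_CLIP,
) -> Optional[Tuple[int, int]]:
    """Best-supported clip position within the insertion interval.

    Collects soft-clip boundary coordinates of reads overlapping [lo, hi),
    groups them within +/-3 bp and returns (breakpoint, support) for the
    group with the highest support, ties broken to the leftmost group.
    Returns None when no clipped read is found.
    """
    pad = CLIP_GROUP_TOL
    fetch_lo = max(0, lo - pad)
    fetch_hi = max(hi + pad, fetch_lo + 1)
    positions = []
    for rec in bam.fetch(chrom, fetch_lo, fetch_hi):
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        for pos in clip_positions(rec, min_clip):
            if lo - pad <= pos <= hi + pad:
                positions.append(pos)
    if not positions:
        return None
    groups = _group_clips(positions)
    best = max(groups, key=lambda g: (g[1], -g[0]))
    return best


def count_core_reads(
    bam: pysam.AlignmentFile,
    chrom: str,
    breakpoint: int,
    min_clip: int = MIN_CLIP,
    margin: int = CORE_MARGIN,
) -> int:
    """Count properly-paired reads spanning the breakpoint by >= margin bases.

    A read clipped at the breakpoint itself counts as clipped evidence, never
    as core, even if proper-paired (the two kinds of evidence are mutually
    exclusive).
    """
    n = 0
    lo, hi = breakpoint - margin, breakpoint + margin
    for rec in bam.fetch(chrom, max(0, lo), hi + 1):
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if not rec.is_proper_pair:
            continue
        if rec.reference_start > lo or rec.reference_end < hi:
            continue
        if any(
            abs(p - breakpoint) <= CLIP_GROUP_TOL for p in clip_positions(rec, min_clip)
        ):
            continue
        n += 1
    return n


def zygosity(clipped: int, core: int) -> Optional[float]:
    """Variant allele fraction clipped / (clipped + core); None when undefined."""
    if clipped < 0 or core < 0:
        raise ValueError("read counts must be >= 0")
    total = clipped + core
    if total == 0:
        return None
    return clipped / total


def annotate_te_identity(pair: ClusterPair) -> Tuple[str, str, bool]:
    """Predicted TE identity of a cluster pair.

    The predicted name is the most frequent TE name over both clusters'
    mate-hit multisets (ties to the lexicographically smallest name); the
    call is TE-consistent when the forward and reverse clusters share at
    least one hit name.
    """
    from .annotation import parse_family

    fwd_names = pair.fwd.te_names
    rev_names = pair.rev.te_names
    combined = fwd_names + rev_names
    name = min(combined.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    consistent = bool(set(fwd_names) & set(rev_names))
    return name, parse_family(name), consistent
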