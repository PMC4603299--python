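"""End-to-end single-sample TEI calling: BAM + TE annotation -> calls.

The scan collects anchor reads in one pass; anchors are then partitioned into
genomic bins (with an overlap margin wide enough that clustering, isolation
and pairing decisions are identical to a single-pass run — each bin owns the
calls whose insertion-site midpoint falls inside it), clustered per strand,
paired, and refined against the BAM for breakpoints, core reads and zygosity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pysam

from .annotation import TEIndex, load_te_annotation
from .breakpoints import annotate_te_identity, count_core_reads, find_breakpoint, zygosity
from .calls import TEICall
from .clustering import ClusterPair, cluster_anchors, insertion_interval, pair_clusters
from .discordant import AnchorRead, scan_bam
from .filtering import FilterConfig, apply_filter, default_cutoffs
from .library import LibraryStats, RunParams, estimate_library_stats

log = logging.getLogger(__name__)

__all__ = ["RunResult", "call_insertions", "cluster_and_pair", "run_sample"]


@dataclass
class RunResult:
    """Everything a single-sample run produces."""

    calls: List[TEICall]
    stats: LibraryStats
    coverage: float
    filter_config: Optional[FilterConfig] = None

    @property
    def passed_calls(self) -> List[TEICall]:
        return [c for c in self.calls if c.passed]


def _interval_margin(stats: LibraryStats, params: RunParams) -> int:
    # wide enough that every cluster/pairing decision near a bin edge sees
    # all anchors it could interact with
    return 4 * int(round(stats.fragment_mean + params.s_factor * stats.fragment_sd))


def cluster_and_pair(
    anchors: Sequence[AnchorRead],
    stats: LibraryStats,
    params: RunParams,
) -> List[ClusterPair]:
    """Cluster anchors per chromosome/strand within bins and pair the clusters.

    Bins are deterministic functions of (chromosome, bin_size); each bin is
    processed with an overlap margin and owns only the cluster pairs whose
    insertion-site midpoint lies inside it, so the result is independent of
    the binning (provided bins are not drastically smaller than the predicted
    interval width).
    """
    margin = _interval_margin(stats, params)
    by_chrom: Dict[str, List[AnchorRead]] = {}
    for a in anchors:
        by_chrom.setdefault(a.interval[0], []).append(a)

    pairs: List[ClusterPair] = []
    for chrom in sorted(by_chrom):
        chrom_anchors = by_chrom[chrom]
        mids = [(a.interval[1] + a.interval[2]) // 2 for a in chrom_anchors]
        bins = sorted({m // params.bin_size for m in mids})
        for b in bins:
            core_lo = b * params.bin_size
            core_hi = core_lo + params.bin_size
            sel = [
                a
                for a, m in zip(chrom_anchors, mids)
                if core_lo - margin <= m < core_hi + margin
            ]
            fwd = cluster_anchors(sel, "+")
            rev = cluster_anchors(sel, "-")
            for pair in pair_clusters(fwd, rev):
                _, lo, hi = insertion_interval(pair)
                if core_lo <= (lo + hi) // 2 < core_hi:
                    pairs.append(pair)
    pairs.sort(key=lambda p: (p.chrom, insertion_interval(p)[1], insertion_interval(p)[2]))
    return pairs


def call_insertions(
    bam: pysam.AlignmentFile,
    pairs: Sequence[ClusterPair],
) -> List[TEICall]:
    """Refine cluster pairs into TEI calls using the indexed BAM."""
    calls = []
    for pair in pairs:
        chrom, lo, hi = insertion_interval(pair)
        bp = find_breakpoint(bam, chrom, lo, hi)
        name, family, consistent = annotate_te_identity(pair)
        if bp is None:
            call = TEICall(
                chrom, lo, hi, pair.fwd, pair.rev,
                predicted_te_name=name,
                predicted_te_family=family,
                consistent_te=consistent,
            )
        else:
            breakpoint, support = bp
            core = count_core_reads(bam, chrom, breakpoint)
            call = TEICall(
                chrom, lo, hi, pair.fwd, pair.rev,
                breakpoint=breakpoint,
                clipped_support=support,
                core_reads=core,
                zygosity=zygosity(support, core),
                predicted_te_name=name,
                predicted_te_family=family,
                consistent_te=consistent,
            )
        calls.append(call)
    return calls


def run_sample(
    bam_path,
    te_gff=None,
    te_index: Optional[TEIndex] = None,
    params: Optional[RunParams] = None,
    stats: Optional[LibraryStats] = None,
    filter_calls: bool = True,
) -> RunResult:
    """Run the full single-sample pipeline on an indexed BAM.

    Library statistics are estimated from the BAM unless supplied; coverage is
    estimated during the scan unless overridden by ``params.coverage``
    (rounded to one decimal either way). With ``filter_calls`` the generated
    default cutoffs are applied; the raw calls are always retained with their
    filter status recorded.
    """
    if params is None:
        params = RunParams()
    if te_index is None:
        if te_gff is None:
            raise ValueError("either te_gff or te_index is required")
        te_index = load_te_annotation(te_gff)

    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        if stats is None:
            stats = estimate_library_stats(bam.fetch(until_eof=True))
            bam.reset()
        params.check_bin_size(stats)
        anchors, est_cov = scan_bam(bam, te_index, stats, params)
        coverage = round(params.coverage if params.coverage else est_cov, 1)
        log.info(
            "library: fragment %.1f +/- %.1f bp, read %.1f bp; coverage %.1fX; "
            "%d anchor reads",
            stats.fragment_mean, stats.fragment_sd, stats.read_len_mean,
            coverage, len(anchors),
        )
        pairs = cluster_and_pair(anchors, stats, params)
        calls = call_insertions(bam, pairs)

    fconf = None
    if filter_calls:
        fconf = default_cutoffs(stats, coverage)
        apply_filter(calls, fconf)
        log.info(
            "%d raw calls, %d pass generated filters",
            len(calls), sum(c.passed for c in calls),
        )
    else:
        log.info("%d raw calls (unfiltered)", len(calls))
    return RunResult(calls, stats, coverage, fconf)
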