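"""Clustering of anchor reads and pairing of forward/reverse clusters.

Anchors on a strand are clustered into maximal mutually-overlapping sets of
predicted insertion intervals (maximal cliques of the interval-overlap graph
— enumerable left-to-right because 1-D intervals have the Helly property:
pairwise overlap implies a common point). Clusters that overlap each other
are discarded to keep only isolated clusters; a forward and a reverse cluster
whose intervals overlap call one putative insertion.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .discordant import AnchorRead

log = logging.getLogger(__name__)

__all__ = [
    "Cluster",
    "ClusterPair",
    "cluster_anchors",
    "pair_clusters",
    "insertion_interval",
    "assign_bin",
]


@dataclass
class Cluster:
    """A maximal set of same-strand anchors with pairwise-overlapping intervals."""

    strand: str
    members: List[AnchorRead]
    interval: Tuple[str, int, int]  # intersection of member intervals

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def span(self) -> int:
        """Max distance between member anchor start positions; 0 = stacked reads."""
        starts = [m.anchor.start for m in self.members]
        return max(starts) - min(starts)

    @property
    def te_names(self) -> Counter:
        c: Counter = Counter()
        for m in self.members:
            c.update(m.te_hits)
        return c

    @property
    def read_names(self) -> List[str]:
        return [m.anchor.name for m in self.members]


@dataclass
class ClusterPair:
    """A forward and a reverse cluster with overlapping predicted intervals."""

    fwd: Cluster
    rev: Cluster

    @property
    def chrom(self) -> str:
        return self.fwd.interval[0]


def _maximal_cliques(anchors: Sequence[AnchorRead]) -> List[List[AnchorRead]]:
    """Maximal cliques of the interval-overlap graph by a left-to-right sweep.

    Intervals are half-open. The active set at any point is a clique; it is
    maximal exactly when the next event is a removal that follows at least one
    insertion since the last emission.
    """
    events = []  # (coord, kind, idx); removals sort before additions at equal coord
    for i, a in enumerate(anchors):
        _, lo, hi = a.interval
        events.append((lo, 1, i))
        events.append((hi, 0, i))
    events.sort(key=lambda e: (e[0], e[1]))
    active: Dict[int, AnchorRead] = {}
    cliques: List[List[AnchorRead]] = []
    grown = False
    for coord, kind, idx in events:
        if kind == 1:
            active[idx] = anchors[idx]
            grown = True
        else:
            if grown and active:
                cliques.append(list(active.values()))
                grown = False
            del active[idx]
    return cliques


def cluster_anchors(anchors: Iterable[AnchorRead], strand: str) -> List[Cluster]:
    """Cluster same-strand anchors; keep only isolated clusters.

    Two clusters are overlapping — and both discarded — when they share a
    member or their intersection intervals overlap. Every anchor therefore
    appears in at most one returned cluster.
    """
    anchors = sorted(
        (a for a in anchors if a.anchor.strand == strand),
        key=lambda a: (a.interval[1], a.interval[2], a.anchor.start, a.anchor.name),
    )
    if not anchors:
        return []
    chrom = anchors[0].interval[0]
    clusters = []
    for members in _maximal_cliques(anchors):
        lo = max(m.interval[1] for m in members)
        hi = min(m.interval[2] for m in members)
        members = sorted(members, key=lambda m: (m.anchor.start, m.anchor.name))
        clusters.append(Cluster(strand, members, (chrom, lo, hi)))

    # isolation: drop any pair of clusters that share a member or whose
    # intersection intervals overlap
    ids = [set(id(m) for m in c.members) for c in clusters]
    bad = set()
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            share = bool(ids[i] & ids[j])
            _, lo_i, hi_i = clusters[i].interval
            _, lo_j, hi_j = clusters[j].interval
            if share or (lo_i < hi_j and lo_j < hi_i):
                bad.add(i)
                bad.add(j)
    return [c for k, c in enumerate(clusters) if k not in bad]


def pair_clusters(fwd: Sequence[Cluster], rev: Sequence[Cluster]) -> List[ClusterPair]:
    """Pair forward with reverse clusters whose intervals overlap.

    A cluster participating in more than one overlap is ambiguous; all
    clusters it touches are dropped (specificity first).

    Overlap here is closed (touching intervals pair): a forward anchor ending
    exactly at the junction and a reverse anchor starting there produce
    abutting predicted intervals whose single shared coordinate IS the
    insertion point — with soft-clipped anchors this is the typical case.
    """
    links: List[Tuple[int, int]] = []
    for i, f in enumerate(fwd):
        _, flo, fhi = f.interval
        for j, r in enumerate(rev):
            _, rlo, rhi = r.interval
            if flo <= rhi and rlo <= fhi:
                links.append((i, j))
    fcount = Counter(i for i, _ in links)
    rcount = Counter(j for _, j in links)
    pairs = []
    for i, j in links:
        if fcount[i] == 1 and rcount[j] == 1:
            pairs.append(ClusterPair(fwd[i], rev[j]))
        else:
            log.warning(
                "ambiguous cluster pairing at %s:%d-%d dropped",
                fwd[i].interval[0], fwd[i].interval[1], fwd[i].interval[2],
            )
    return pairs


def insertion_interval(pair: ClusterPair) -> Tuple[str, int, int]:
    """Insertion-site interval of a cluster pair.

    Bounded by the greatest anchor start in the forward cluster and the
    smallest anchor end in the reverse cluster. When the innermost reads
    cross (lo >= hi, stacked reads), the interval collapses to the single
    midpoint with length 0.
    """
    chrom = pair.chrom
    lo = max(m.anchor.start for m in pair.fwd.members)
    hi = min(m.anchor.end for m in pair.rev.members)
    if lo >= hi:
        mid = (lo + hi) // 2
        return chrom, mid, mid
    return chrom, lo, hi


def assign_bin(anchor: AnchorRead, bin_size: int) -> int:
    """Bin index of an anchor: the bin containing its predicted-interval midpoint.

    Binning by interval midpoint guarantees a cluster is never split across
    work partitions (all members of a clique share a common point).
    """
    _, lo, hi = anchor.interval
    return ((lo + hi) // 2) // bin_size
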