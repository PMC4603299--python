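"""Clustering of anchor intervals: clique sweep vs brute force, isolation,
pairing and the insertion-site interval."""

import random

import networkx as nx
import pytest

from tescout import cluster_anchors, insertion_interval, pair_clusters
from tescout.clustering import Cluster, ClusterPair
from tescout.discordant import AnchorRead

from conftest import mk_read


def mk_anchor(lo, hi, strand="+", start=None, end=None, name=None, te="A_1"):
    start = lo - 100 if start is None else start
    end = start + 100 if end is None else end
    read = mk_read(
        name=name or f"a{lo}_{hi}_{random.random()}", start=start, end=end, strand=strand
    )
    return AnchorRead(read, frozenset({te}), ("chr1", lo, hi))


def brute_force_clusters(intervals):
    """Independent oracle: maximal cliques by exhaustive enumeration, then the
    isolation rule (discard pairs sharing a member or with overlapping
    intersection intervals)."""
    g = nx.Graph()
    g.add_nodes_from(range(len(intervals)))
    for i in range(len(intervals)):
        for j in range(i + 1, len(intervals)):
            (a1, b1), (a2, b2) = intervals[i], intervals[j]
            if a1 < b2 and a2 < b1:
                g.add_edge(i, j)
    cliques = [frozenset(c) for c in nx.find_cliques(g)]
    inter = {
        c: (max(intervals[i][0] for i in c), min(intervals[i][1] for i in c))
        for c in cliques
    }
    bad = set()
    for i, c1 in enumerate(cliques):
        for c2 in cliques[i + 1 :]:
            share = bool(c1 & c2)
            (l1, h1), (l2, h2) = inter[c1], inter[c2]
            if share or (l1 < h2 and l2 < h1):
                bad.add(c1)
                bad.add(c2)
    return {c for c in cliques if c not in bad}


class TestClusterAnchors:
    def test_all_overlapping_single_cluster(self):
        anchors = [mk_anchor(0, 10), mk_anchor(5, 15), mk_anchor(8, 20)]
        (cluster,) = cluster_anchors(anchors, "+")
        assert cluster.size == 3
        assert cluster.interval == ("chr1", 8, 10)

    def test_disjoint_intervals_isolated_singletons(self):
        anchors = [mk_anchor(0, 10), mk_anchor(100, 110)]
        clusters = cluster_anchors(anchors, "+")
        assert [c.size for c in clusters] == [1, 1]

    def test_chained_cliques_sharing_a_member_both_discarded(self):
        anchors = [mk_anchor(0, 10), mk_anchor(5, 15), mk_anchor(12, 25)]
        assert cluster_anchors(anchors, "+") == []

    def test_empty_input(self):
        assert cluster_anchors([], "+") == []

    def test_strand_filtering(self):
        anchors = [mk_anchor(0, 10, strand="+"), mk_anchor(0, 10, strand="-")]
        (c,) = cluster_anchors(anchors, "+")
        assert c.size == 1

    def test_order_invariance(self):
        rng = random.Random(5)
        intervals = [(lo, lo + rng.randint(5, 60)) for lo in rng.sample(range(0, 500), 20)]
        anchors = [mk_anchor(lo, hi, name=f"n{k}") for k, (lo, hi) in enumerate(intervals)]
        ref = {frozenset(c.read_names) for c in cluster_anchors(anchors, "+")}
        for _ in range(5):
            rng.shuffle(anchors)
            got = {frozenset(c.read_names) for c in cluster_anchors(anchors, "+")}
            assert got == ref

    def test_matches_brute_force_oracle_on_random_instances(self):
        """Sweep clustering equals exhaustive maximal-clique enumeration plus
        the isolation rule, over 1000 random instances of <= 12 intervals."""
        rng = random.Random(123)
        for trial in range(1000):
            n = rng.randint(1, 12)
            intervals = []
            for _ in range(n):
                lo = rng.randint(0, 80)
                intervals.append((lo, lo + rng.randint(1, 40)))
            anchors = [
                mk_anchor(lo, hi, name=f"t{trial}_{k}")
                for k, (lo, hi) in enumerate(intervals)
            ]
            got = {
                frozenset(m.anchor.name for m in c.members)
                for c in cluster_anchors(anchors, "+")
            }
            expected = {
                frozenset(anchors[i].anchor.name for i in c)
                for c in brute_force_clusters(intervals)
            }
            assert got == expected, f"trial {trial}: {intervals}"

    def test_span_definition(self):
        anchors = [
            mk_anchor(200, 600, start=100),
            mk_anchor(210, 610, start=110),
            mk_anchor(230, 630, start=130),
        ]
        (c,) = cluster_anchors(anchors, "+")
        assert c.span == 30

    def test_stacked_reads_span_zero(self):
        anchors = [mk_anchor(200, 600, start=100, name=f"s{i}") for i in range(4)]
        (c,) = cluster_anchors(anchors, "+")
        assert c.span == 0


def make_cluster(interval, strand="+", starts=(100,), ends=None, te="A_1"):
    ends = ends or [s + 100 for s in starts]
    members = [
        mk_anchor(interval[0], interval[1], strand=strand, start=s, end=e, name=f"m{s}_{e}_{i}", te=te)
        for i, (s, e) in enumerate(zip(starts, ends))
    ]
    return Cluster(strand, members, ("chr1", interval[0], interval[1]))


class TestPairClusters:
    def test_overlap_pairs(self):
        fwd = make_cluster((100, 300), "+")
        rev = make_cluster((250, 400), "-")
        assert len(pair_clusters([fwd], [rev])) == 1

    def test_disjoint_do_not_pair(self):
        fwd = make_cluster((100, 200), "+")
        rev = make_cluster((300, 400), "-")
        assert pair_clusters([fwd], [rev]) == []

    def test_touching_intervals_pair(self):
        # innermost anchors clipped exactly at the junction produce abutting intervals
        fwd = make_cluster((500, 700), "+")
        rev = make_cluster((300, 500), "-")
        assert len(pair_clusters([fwd], [rev])) == 1

    def test_ambiguous_multi_overlap_drops_all(self):
        f1 = make_cluster((100, 300), "+")
        r1 = make_cluster((250, 400), "-")
        r2 = make_cluster((280, 500), "-")
        assert pair_clusters([f1], [r1, r2]) == []


class TestInsertionInterval:
    def test_max_fwd_start_min_rev_end(self):
        fwd = make_cluster((300, 700), "+", starts=(100, 140, 180))
        rev = make_cluster((250, 650), "-", starts=(320, 360), ends=(420, 460))
        pair = ClusterPair(fwd, rev)
        assert insertion_interval(pair) == ("chr1", 180, 420)

    def test_singletons(self):
        fwd = make_cluster((300, 700), "+", starts=(100,))
        rev = make_cluster((250, 650), "-", starts=(300,), ends=(400,))
        assert insertion_interval(ClusterPair(fwd, rev)) == ("chr1", 100, 400)

    def test_crossing_stacks_collapse_to_midpoint(self):
        fwd = make_cluster((550, 900), "+", starts=(500,))
        rev = make_cluster((200, 560), "-", starts=(350,), ends=(450,))
        chrom, lo, hi = insertion_interval(ClusterPair(fwd, rev))
        assert (lo, hi) == (475, 475)
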