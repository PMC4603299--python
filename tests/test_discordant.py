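"""Discordant-pair selection, anchor classification and predicted intervals."""

import pytest

from tescout import (
    LibraryStats,
    RunParams,
    TEFeature,
    TEIndex,
    classify_pair,
    is_repetitive,
    is_valid_discordant,
    predicted_interval,
)
from tescout.reads import AltHit, cigar_reference_span, parse_xa

from conftest import STATS, mk_read

PARAMS = RunParams()

TE_INDEX = TEIndex(
    [
        TEFeature("chr1", 100_000, 103_000, "+", "ATCOPIA_1"),
        TEFeature("chr1", 200_000, 202_000, "-", "ATLINE_2"),
        TEFeature("chr1", 300_000, 302_000, "+", "ATLINE_7"),
        TEFeature("chr1", 50_000, 51_000, "+", "ATCOPIA_9"),
    ]
)


class TestIsValidDiscordant:
    def test_proper_pair_flag_rejects(self):
        r1 = mk_read(start=1000, end=1100, proper=True)
        r2 = mk_read(start=3000, end=3100, proper=True)
        assert not is_valid_discordant(r1, r2, STATS)

    def test_distance_beyond_twice_fragment_accepts(self):
        r1 = mk_read(start=1000, end=1100)
        r2 = mk_read(start=3000, end=3100)  # distance 2000 > 2 x 450
        assert is_valid_discordant(r1, r2, STATS)

    def test_different_chromosomes_accept(self):
        r1 = mk_read(chrom="chr1", start=1000, end=1100)
        r2 = mk_read(chrom="chr2", start=1000, end=1100)
        assert is_valid_discordant(r1, r2, STATS)

    def test_short_distance_rejects(self):
        r1 = mk_read(start=1000, end=1100)
        r2 = mk_read(start=1500, end=1600)  # distance 500 <= 900
        assert not is_valid_discordant(r1, r2, STATS)


class TestIsRepetitive:
    def test_mapq_zero(self):
        assert is_repetitive(mk_read(mapq=0))

    def test_alt_hits(self):
        assert is_repetitive(mk_read(mapq=37, alt_hits=[AltHit("chr1", 500, "+", 100)]))

    def test_unique(self):
        assert not is_repetitive(mk_read(mapq=37))


class TestPredictedInterval:
    def test_forward(self):
        # start 1000, end 1100, fragment 450 +/- 40, s=2 -> (1100, 1530]
        iv = predicted_interval(mk_read(start=1000, end=1100, strand="+"), STATS, PARAMS)
        assert iv == ("chr1", 1100, 1530)

    def test_reverse(self):
        iv = predicted_interval(mk_read(start=2000, end=2100, strand="-"), STATS, PARAMS)
        assert iv == ("chr1", 1570, 2000)

    def test_s_zero_collapses_sd_term(self):
        stats = LibraryStats(450, 40, 100, 0)
        params = RunParams(s_factor=0)
        iv = predicted_interval(mk_read(start=0, end=100, strand="+"), stats, params)
        assert iv == ("chr1", 100, 450)

    def test_pathological_stats_discarded(self, caplog):
        stats = LibraryStats(100, 0, 100, 0)
        # reverse anchor whose reach equals the read length: empty interval
        iv = predicted_interval(mk_read(start=1000, end=1100, strand="-"), stats, RunParams(s_factor=0))
        assert iv is None

    def test_strand_mirror(self):
        """Reverse-complementing the genome maps forward intervals to mirrored
        reverse intervals exactly."""
        L = 1_000_000
        fwd = mk_read(start=1000, end=1100, strand="+")
        mirrored = mk_read(start=L - 1100, end=L - 1000, strand="-")
        _, flo, fhi = predicted_interval(fwd, STATS, PARAMS)
        _, rlo, rhi = predicted_interval(mirrored, STATS, PARAMS)
        assert (rlo, rhi) == (L - fhi, L - flo)

    def test_constant_width(self):
        widths = set()
        for start in (0, 5_000, 90_000):
            _, lo, hi = predicted_interval(
                mk_read(start=start, end=start + 100, strand="+"), STATS, PARAMS
            )
            widths.add(hi - lo)
        assert len(widths) == 1
        assert widths.pop() == 450 + 2 * 40 - 100


class TestClassifyPair:
    def anchor(self, **kw):
        kw.setdefault("start", 1000)
        kw.setdefault("end", 1100)
        return mk_read(**kw)

    def test_primary_te_mate(self):
        mate = mk_read(start=100_500, end=100_600)  # inside ATCOPIA_1
        res = classify_pair(self.anchor(), mate, TE_INDEX, STATS, PARAMS)
        assert res is not None
        assert res.te_hits == {"ATCOPIA_1"}

    def test_low_mapq_anchor_rejected(self):
        mate = mk_read(start=100_500, end=100_600)
        assert classify_pair(self.anchor(mapq=10), mate, TE_INDEX, STATS, PARAMS) is None

    def test_alt_hit_te_mate_collects_all_names(self):
        mate = mk_read(
            start=10_000,
            end=10_100,
            mapq=0,
            alt_hits=[AltHit("chr1", 200_500, "+", 100), AltHit("chr1", 300_500, "+", 100)],
        )
        res = classify_pair(self.anchor(), mate, TE_INDEX, STATS, PARAMS)
        assert res is not None
        assert res.te_hits == {"ATLINE_2", "ATLINE_7"}

    def test_anchor_overlapping_te_rejected(self):
        anchor = self.anchor(start=50_500, end=50_600)  # inside ATCOPIA_9
        mate = mk_read(start=100_500, end=100_600)
        assert classify_pair(anchor, mate, TE_INDEX, STATS, PARAMS) is None

    def test_repetitive_anchor_rejected(self):
        anchor = self.anchor(alt_hits=[AltHit("chr1", 400_000, "+", 100)])
        mate = mk_read(start=100_500, end=100_600)
        assert classify_pair(anchor, mate, TE_INDEX, STATS, PARAMS) is None

    def test_non_te_mate_rejected(self):
        mate = mk_read(start=400_000, end=400_100)
        assert classify_pair(self.anchor(), mate, TE_INDEX, STATS, PARAMS) is None

    def test_symmetric_roles(self):
        anchor = self.anchor()
        mate = mk_read(start=100_500, end=100_600)
        assert classify_pair(mate, anchor, TE_INDEX, STATS, PARAMS).te_hits == {"ATCOPIA_1"}


class TestXaParsing:
    def test_parse(self):
        hits = parse_xa("chr1,+200501,100M,0;chr2,-1501,50M50S,2;")
        assert hits[0] == AltHit("chr1", 200_500, "+", 100)
        assert hits[1].chrom == "chr2"
        assert hits[1].start == 1500
        assert hits[1].ref_span == 50

    @pytest.mark.parametrize(
        "cigar,span", [("100M", 100), ("50M50S", 50), ("10M5D10M", 25), ("5S95M", 95)]
    )
    def test_cigar_reference_span(self, cigar, span):
        assert cigar_reference_span(cigar) == span


def test_simulated_anchors_satisfy_contract(small_sim, small_run):
    """Every anchor emitted on simulator output is valid, unique, confidently
    mapped and disjoint from the TE annotation."""
    import pysam

    from tescout.discordant import scan_bam
    from tescout.library import estimate_library_stats

    idx = small_sim.genome.index
    with pysam.AlignmentFile(str(small_sim.bam), "rb") as bam:
        stats = estimate_library_stats(bam.fetch(until_eof=True))
        bam.reset()
        anchors, cov = scan_bam(bam, idx, stats, RunParams())
    assert anchors
    assert cov == pytest.approx(40, rel=0.1)
    for a in anchors:
        r = a.anchor
        assert not r.proper_pair
        assert not is_repetitive(r)
        assert r.mapq >= 15
        assert not idx.overlaps(r.chrom, r.start, r.end)
        assert a.te_hits
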