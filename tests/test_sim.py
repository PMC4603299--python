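"""Simulator: genome construction, insertion planting, read emulation, scoring."""

import hashlib

import numpy as np
import pysam
import pytest

from tescout.sim import (
    SimReadConfig,
    make_sim_genome,
    plant_insertions,
    score_predictions,
    simulate_aligned_reads,
)
from tescout.sim.scoring import classify_af
from tescout.sim.insertions import TruthRecord


class TestMakeSimGenome:
    def test_construction_contract(self):
        g = make_sim_genome(
            genome_len=1_000_000, n_families=3, copies_per_family=10,
            te_len_range=(500, 3000), divergence=0.02, seed=7,
        )
        assert len(g.te_features) == 30
        assert all(f.length >= 500 for f in g.te_features)
        assert len(g.sequences["chr1"]) == 1_000_000
        fams = g.index.families()
        assert set(fams) == set(g.te_library)
        assert all(len(copies) == 10 for copies in fams.values())

    def test_determinism(self):
        a = make_sim_genome(genome_len=500_000, seed=7, te_len_range=(500, 1500))
        b = make_sim_genome(genome_len=500_000, seed=7, te_len_range=(500, 1500))
        assert a.sequences == b.sequences
        assert a.te_features == b.te_features

    def test_zero_divergence_copies_identical(self):
        g = make_sim_genome(
            genome_len=500_000, n_families=1, copies_per_family=5,
            te_len_range=(500, 800), divergence=0.0, seed=3,
        )
        seqs = {g.te_sequence(f) for f in g.te_features}
        assert len(seqs) == 1

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError):
            make_sim_genome(genome_len=10_000, te_len_range=(500, 3000))


@pytest.fixture(scope="module")
def genome():
    return make_sim_genome(
        genome_len=600_000, n_families=2, copies_per_family=5,
        te_len_range=(500, 1200), divergence=0.02, seed=5,
    )


class TestPlantInsertions:
    def test_nd_design_allele_fractions(self, genome):
        alleles, truth = plant_insertions(genome, 1, 1, 0, seed=1)
        assert sorted(t.true_af for t in truth) == [0.5, 1.0]
        assert [a.copies for a in alleles] == [1, 1]

    def test_td_design_lcf_records(self, genome):
        alleles, truth = plant_insertions(genome, 2, 2, 5, seed=1)
        assert sum(t.true_af == 0.25 for t in truth) == 5
        assert [a.copies for a in alleles] == [2, 1, 1]
        # LCF insertions live only on the third allele
        lcf = [t for t in truth if t.true_af == 0.25]
        assert all(t.allele_ids == frozenset({"A3"}) for t in lcf)

    def test_exclusion_zones_respected(self, genome):
        _, truth = plant_insertions(genome, 10, 10, 0, seed=2)
        for t in truth:
            for f in genome.te_features:
                if f.chrom == t.chrom:
                    assert not (f.start - 100 <= t.position < f.end + 100)

    def test_donors_are_annotated_copies(self, genome):
        _, truth = plant_insertions(genome, 5, 5, 0, seed=3)
        names = {f.name for f in genome.te_features}
        assert all(t.te_name in names for t in truth)


@pytest.fixture(scope="module")
def tiny(tmp_path_factory):
    g = make_sim_genome(
        genome_len=300_000, n_families=2, copies_per_family=4,
        te_len_range=(500, 1000), divergence=0.02, seed=11,
    )
    alleles, truth = plant_insertions(g, 1, 1, 0, seed=12)
    return g, alleles, truth, tmp_path_factory.mktemp("reads")


class TestSimulateAlignedReads:
    def test_zero_sd_fragments_give_exact_tlen(self, tiny):
        g, alleles, truth, d = tiny
        cfg = SimReadConfig(coverage=10, fragment_sd=0, substitution_rate=0, seed=1)
        simulate_aligned_reads(alleles, g, cfg, d / "sd0.bam")
        with pysam.AlignmentFile(str(d / "sd0.bam")) as bam:
            tlens = {
                abs(r.template_length)
                for r in bam.fetch(until_eof=True)
                if r.is_proper_pair
            }
        assert tlens == {450}

    def test_homozygous_locus_has_clips_and_no_core(self, tiny):
        g, alleles, truth, d = tiny
        cfg = SimReadConfig(coverage=40, substitution_rate=0, seed=2)
        simulate_aligned_reads(alleles, g, cfg, d / "hom.bam")
        hom = next(t for t in truth if t.true_af == 1.0)
        from tescout import count_core_reads, find_breakpoint

        with pysam.AlignmentFile(str(d / "hom.bam")) as bam:
            bp, support = find_breakpoint(bam, hom.chrom, hom.position - 50, hom.position + 50)
            assert bp == hom.position
            assert support >= 3
            assert count_core_reads(bam, hom.chrom, bp) == 0

    def test_heterozygous_locus_has_both_evidence_kinds(self, tiny):
        g, alleles, truth, d = tiny
        cfg = SimReadConfig(coverage=40, substitution_rate=0, seed=2)
        simulate_aligned_reads(alleles, g, cfg, d / "het.bam")
        het = next(t for t in truth if t.true_af == 0.5)
        from tescout import count_core_reads, find_breakpoint

        with pysam.AlignmentFile(str(d / "het.bam")) as bam:
            bp, support = find_breakpoint(bam, het.chrom, het.position - 50, het.position + 50)
            assert bp == het.position
            assert support > 0
            assert count_core_reads(bam, het.chrom, bp) > 0

    def test_byte_identical_for_same_seed(self, tiny):
        g, alleles, truth, d = tiny
        cfg = SimReadConfig(coverage=5, seed=42)
        simulate_aligned_reads(alleles, g, cfg, d / "det1.bam")
        simulate_aligned_reads(alleles, g, cfg, d / "det2.bam")
        h1 = hashlib.md5((d / "det1.bam").read_bytes()).hexdigest()
        h2 = hashlib.md5((d / "det2.bam").read_bytes()).hexdigest()
        assert h1 == h2

    def test_te_mate_placed_at_donor_with_alt_hits(self, tiny):
        g, alleles, truth, d = tiny
        cfg = SimReadConfig(coverage=30, substitution_rate=0, seed=3)
        simulate_aligned_reads(alleles, g, cfg, d / "mates.bam")
        idx = g.index
        hom = next(t for t in truth if t.true_af == 1.0)
        donor = idx.get(hom.te_name)
        with pysam.AlignmentFile(str(d / "mates.bam")) as bam:
            te_mates = [
                r for r in bam.fetch(donor.chrom, donor.start, donor.end)
                if not r.is_proper_pair
                and abs(r.next_reference_start - hom.position) < 600
            ]
        assert te_mates, "expected discordant mates at the donor copy"
        assert any(r.has_tag("XA") for r in te_mates)


class TestScoring:
    def mk_call(self, chrom="chr1", locus=1000, zyg=None):
        class C:
            pass

        c = C()
        c.chrom = chrom
        c.locus = locus
        c.zygosity = zyg
        return c

    def truth(self, pos, af=1.0):
        return TruthRecord("chr1", pos, "A_1", "A", af, frozenset({"A1"}))

    def test_counts_and_rates(self):
        truth = [self.truth(i * 1000) for i in range(10)]
        calls = [self.mk_call(locus=i * 1000 + 3, zyg=1.0) for i in range(9)]
        calls.append(self.mk_call(locus=500_000))  # FP
        rep = score_predictions(calls, truth, pad=20)
        assert (rep.tp, rep.fp, rep.fn) == (9, 1, 1)
        assert rep.ppv == pytest.approx(90.0)
        assert rep.sensitivity == pytest.approx(90.0)

    def test_padding_rule(self):
        rep = score_predictions(
            [self.mk_call(locus=1005, zyg=1.0)], [self.truth(1000)], pad=20
        )
        assert rep.tp == 1
        assert rep.breakpoint_errors() == [5]
        rep2 = score_predictions([self.mk_call(locus=1025)], [self.truth(1000)], pad=20)
        assert rep2.tp == 0

    def test_one_to_one_matching(self):
        truth = [self.truth(1000)]
        calls = [self.mk_call(locus=1002), self.mk_call(locus=1003)]
        rep = score_predictions(calls, truth, pad=20)
        assert (rep.tp, rep.fp) == (1, 1)

    def test_zygosity_classification(self):
        assert classify_af(0.97, [1.0, 0.5]) == 1.0
        assert classify_af(0.74, [1.0, 0.5]) == 0.5
        assert classify_af(0.75, [1.0, 0.5]) == 1.0
        assert classify_af(0.30, [1.0, 0.5, 0.25]) == 0.25
        assert classify_af(0.40, [1.0, 0.5, 0.25]) == 0.5
        # equidistant between 0.25 and 0.5: the larger fraction wins
        assert classify_af(0.375, [1.0, 0.5, 0.25]) == 0.5

    def test_zygosity_accuracy_and_detection(self):
        truth = [self.truth(1000, 1.0), self.truth(3000, 0.5), self.truth(5000, 0.25)]
        calls = [
            self.mk_call(locus=1000, zyg=0.97),
            self.mk_call(locus=3000, zyg=0.55),
            self.mk_call(locus=5000, zyg=0.70),  # misclassified as het
        ]
        rep = score_predictions(calls, truth, pad=20)
        assert rep.zygosity_accuracy() == pytest.approx(100 * 2 / 3)
        assert rep.detection_rate(0.25) == 100.0
        assert rep.mean_predicted_af(0.5) == pytest.approx(0.55)


def test_truth_gff_round_trip(tmp_path):
    from tescout.sim import read_truth_gff, write_truth_gff

    records = [
        TruthRecord("chr1", 999, "FAMA_3", "FAMA", 0.5, frozenset({"A2", "A3"})),
        TruthRecord("chr1", 5000, "FAMB_1", "FAMB", 0.25, frozenset({"A3"})),
    ]
    path = tmp_path / "truth.gff3"
    write_truth_gff(records, path)
    back = read_truth_gff(path)
    assert back == sorted(records, key=lambda t: t.position)
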