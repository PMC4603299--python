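"""Shared fixtures: programmatic BAM construction and small simulated samples."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pysam
import pytest

from tescout import LibraryStats, RunParams, load_te_annotation, run_sample
from tescout.reads import ReadAlignment
from tescout.sim import (
    SimReadConfig,
    make_sim_genome,
    plant_insertions,
    simulate_aligned_reads,
    write_te_gff,
)

REFS = {"chr1": 1_000_000, "chr2": 500_000}


def make_bam(path, records, refs=None):
    """Write a coordinate-sorted indexed BAM from record dicts.

    Each dict: chrom, pos, plus optional cigar (default 100M), flag fields,
    mapq, mate info, tags.
    """
    refs = refs or REFS
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": n, "LN": l} for n, l in refs.items()],
        }
    )
    tids = {n: i for i, n in enumerate(refs)}
    tmp = str(path) + ".unsorted"
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for i, rec in enumerate(records):
            a = pysam.AlignedSegment(header)
            a.query_name = rec.get("name", f"r{i:05d}")
            a.reference_id = tids[rec.get("chrom", "chr1")]
            a.reference_start = rec["pos"]
            a.cigarstring = rec.get("cigar", "100M")
            a.query_sequence = rec.get("seq", "A" * a.infer_query_length())
            a.mapping_quality = rec.get("mapq", 37)
            flag = 0x1
            if rec.get("reverse"):
                flag |= 0x10
            if rec.get("proper"):
                flag |= 0x2
            if rec.get("read2"):
                flag |= 0x80
            else:
                flag |= 0x40
            if rec.get("mate_reverse"):
                flag |= 0x20
            if rec.get("mate_unmapped"):
                flag |= 0x8
            a.flag = flag
            a.next_reference_id = tids[rec.get("mate_chrom", rec.get("chrom", "chr1"))]
            a.next_reference_start = rec.get("mate_pos", rec["pos"])
            a.template_length = rec.get("tlen", 0)
            if "xa" in rec:
                a.set_tag("XA", rec["xa"])
            out.write(a)
    pysam.sort("-o", str(path), tmp)
    Path(tmp).unlink()
    pysam.index(str(path))
    return path


def mk_read(
    name="r1",
    chrom="chr1",
    start=1000,
    end=1100,
    strand="+",
    mapq=37,
    proper=False,
    tlen=0,
    alt_hits=(),
    mate_chrom="chr1",
    mate_start=5000,
    left_clip=0,
    right_clip=0,
):
    return ReadAlignment(
        name=name,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        mapq=mapq,
        proper_pair=proper,
        template_length=tlen,
        left_clip=left_clip,
        right_clip=right_clip,
        alt_hits=list(alt_hits),
        mate_chrom=mate_chrom,
        mate_start=mate_start,
    )


STATS = LibraryStats(450.0, 40.0, 100.0, 0.0, 1000)


@pytest.fixture(scope="session")
def default_stats():
    return STATS


@dataclasses.dataclass
class SmallSim:
    genome: object
    alleles: list
    truth: list
    bam: Path
    te_gff: Path
    workdir: Path


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory) -> SmallSim:
    """A 400 kb genome, 5 hom + 5 het insertions, 40X aligned reads."""
    d = tmp_path_factory.mktemp("small_sim")
    genome = make_sim_genome(
        genome_len=400_000, n_families=2, copies_per_family=6,
        te_len_range=(500, 1500), divergence=0.02, seed=7,
    )
    alleles, truth = plant_insertions(genome, 5, 5, 0, seed=8)
    bam = d / "sample.bam"
    simulate_aligned_reads(alleles, genome, SimReadConfig(coverage=40, seed=9), bam)
    gff = d / "te.gff3"
    write_te_gff(genome, gff)
    return SmallSim(genome, alleles, truth, bam, gff, d)


@pytest.fixture(scope="session")
def small_run(small_sim):
    """The small simulated sample run through the full pipeline."""
    return run_sample(small_sim.bam, te_gff=small_sim.te_gff, params=RunParams(seed=1))
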