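"""Benchmark designs: the two-allele (normal) and four-allele-copy (tumor)
insertion simulations, run end-to-end through the caller and scored.

The normal (ND) design carries ~equal numbers of homozygous and heterozygous
insertions on two alleles; the tumor (TD) design adds a third allele with
low-cell-fraction insertions and reads the alleles 2:1:1 so those sit at 25 %
allele fraction. Reads use 100 bp pairs with 450 +/- 40 bp fragments. The
somatic comparison pairs the filtered TD calls with the raw ND calls and the
ND alignments.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pysam

from ..library import RunParams
from ..pipeline import RunResult, run_sample
from ..somatic import SomaticVerdict, run_somatic
from .genome import SimGenome, make_sim_genome, write_te_gff
from .insertions import Allele, TruthRecord, plant_insertions
from .reads import SimReadConfig, simulate_aligned_reads
from .scoring import DEFAULT_PAD, ScoreReport, score_predictions

__all__ = ["BenchmarkDesign", "BenchmarkRun", "run_benchmark", "label_somatic_verdicts"]


@dataclass
class BenchmarkDesign:
    """Study conditions for the simulation benchmark (desk scale)."""

    genome_len: int = 3_000_000
    n_families: int = 3
    copies_per_family: int = 10
    te_len_range: Tuple[int, int] = (500, 3000)
    divergence: float = 0.02
    n_hom: int = 75
    n_het: int = 75
    n_lcf: int = 73
    error_rate: float = 0.001
    pad: int = DEFAULT_PAD


@dataclass
class BenchmarkRun:
    """One simulated sample run through the caller and scored."""

    coverage: float
    result: RunResult
    report: ScoreReport  # passed calls vs the sample's truth
    bam_path: Path
    raw_report: ScoreReport


@dataclass
class BenchmarkOutput:
    genome: SimGenome
    truth: List[TruthRecord]  # full TD truth (hom + het + lcf)
    nd_truth: List[TruthRecord]
    nd: Dict[float, BenchmarkRun] = field(default_factory=dict)
    td: Dict[float, BenchmarkRun] = field(default_factory=dict)


def _simulate_and_call(
    alleles: Sequence[Allele],
    genome: SimGenome,
    te_gff: Path,
    truth: Sequence[TruthRecord],
    coverage: float,
    design: BenchmarkDesign,
    seed: int,
    bam_path: Path,
    pad: int,
) -> BenchmarkRun:
    cfg = SimReadConfig(
        coverage=coverage, substitution_rate=design.error_rate, seed=seed
    )
    simulate_aligned_reads(alleles, genome, cfg, bam_path)
    result = run_sample(bam_path, te_gff=te_gff, params=RunParams(seed=seed))
    report = score_predictions(result.passed_calls, truth, pad=pad)
    raw_report = score_predictions(result.calls, truth, pad=pad)
    return BenchmarkRun(coverage, result, report, bam_path, raw_report)


def run_benchmark(
    seed: int,
    nd_coverages: Sequence[float] = (10, 20, 40),
    td_coverages: Sequence[float] = (),
    design: Optional[BenchmarkDesign] = None,
    workdir=None,
) -> BenchmarkOutput:
    """Run the ND (and optionally TD) benchmark designs end to end.

    The TD sample shares the genome and the homozygous/heterozygous insertions
    with the ND sample, as a matched pair. All randomness derives from
    ``seed``. Intermediate BAMs live in ``workdir`` (a temporary directory by
    default).
    """
    design = design or BenchmarkDesign()
    if workdir is None:
        workdir = Path(tempfile.mkdtemp(prefix="tescout_bench_"))
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)

    genome = make_sim_genome(
        genome_len=design.genome_len,
        n_families=design.n_families,
        copies_per_family=design.copies_per_family,
        te_len_range=design.te_len_range,
        divergence=design.divergence,
        seed=seed,
    )
    te_gff = workdir / "te.gff3"
    write_te_gff(genome, te_gff)

    td_alleles, truth = plant_insertions(
        genome, design.n_hom, design.n_het, design.n_lcf, seed=seed + 1
    )
    # the matched normal: same hom/het insertions, two alleles, no LCF set
    nd_alleles = [
        Allele(genome, td_alleles[0].insertions, "A1", copies=1),
        Allele(genome, td_alleles[1].insertions, "A2", copies=1),
    ]
    nd_truth = [t for t in truth if t.true_af in (1.0, 0.5)]

    out = BenchmarkOutput(genome, truth, nd_truth)
    for i, cov in enumerate(nd_coverages):
        out.nd[cov] = _simulate_and_call(
            nd_alleles, genome, te_gff, nd_truth, cov, design,
            seed=seed + 100 + i, bam_path=workdir / f"nd_{cov:g}x.bam", pad=design.pad,
        )
    for i, cov in enumerate(td_coverages):
        out.td[cov] = _simulate_and_call(
            td_alleles, genome, te_gff, truth, cov, design,
            seed=seed + 200 + i, bam_path=workdir / f"td_{cov:g}x.bam", pad=design.pad,
        )
    return out


def label_somatic_verdicts(
    bench: BenchmarkOutput,
    coverage: float = 40,
    window: int = 200,
    discordant_threshold: float = 0.02,
    min_cov: float = 8.0,
) -> List[Tuple[SomaticVerdict, str]]:
    """Run the TD/ND somatic comparison at one coverage and label each verdict.

    Each TD-unique call is labelled ``somatic`` when it matches a
    low-cell-fraction truth record, ``germline`` when it matches a hom/het
    record, ``fp`` otherwise. Returns (verdict, truth label) pairs.
    """
    td_run = bench.td[coverage]
    nd_run = bench.nd[coverage]
    with pysam.AlignmentFile(str(nd_run.bam_path), "rb") as nd_bam:
        verdicts = run_somatic(
            td_run.result.passed_calls,
            nd_run.result.calls,
            nd_bam,
            td_run.result.stats,
            window=window,
            discordant_threshold=discordant_threshold,
            min_cov=min_cov,
        )
    pad = 20
    labelled = []
    for v in verdicts:
        label = "fp"
        best = None
        for t in bench.truth:
            if t.chrom != v.call.chrom:
                continue
            d = abs(v.call.locus - t.position)
            if d <= pad and (best is None or d < best[0]):
                best = (d, t)
        if best is not None:
            label = "somatic" if best[1].true_af == 0.25 else "germline"
        labelled.append((v, label))
    return labelled
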