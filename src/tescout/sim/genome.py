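"""Synthetic multi-copy-TE genome construction.

Builds a random background sequence with planted TE families: each family has
a consensus and several mutually similar copies (per-copy divergence from the
consensus), emulating the premise that a newly inserted TE resembles other
annotated copies of its family elsewhere in the reference. The annotation is
emitted in the same GFF3 dialect the caller consumes (unique Name=FAMILY_x
tags).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from ..annotation import TEFeature, TEIndex

__all__ = ["SimGenome", "make_sim_genome", "write_genome_fasta", "write_te_gff"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

MIN_TE_LEN = 200  # annotated fragments below this are never used as donors


@dataclass
class SimGenome:
    """A synthetic reference: sequences, TE annotation and family consensi."""

    sequences: Dict[str, str]
    te_features: List[TEFeature]
    te_library: Dict[str, str]  # family -> consensus
    divergence: float = 0.02  # per-base divergence of copies from their consensus

    def __post_init__(self) -> None:
        for f in self.te_features:
            if f.end > len(self.sequences[f.chrom]):
                raise ValueError(f"TE {f.name} extends past its sequence")

    @property
    def index(self) -> TEIndex:
        return TEIndex(self.te_features)

    def te_sequence(self, feat: TEFeature) -> str:
        return self.sequences[feat.chrom][feat.start : feat.end]

    def donors(self, min_len: int = MIN_TE_LEN) -> List[TEFeature]:
        """Annotated copies long enough to serve as insertion donors."""
        return [f for f in self.te_features if f.length >= min_len]


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return seq.copy()
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hits):
        # substitute with a uniformly chosen *different* base
        shift = rng.integers(1, 4, len(hits))
        idx = np.searchsorted(_BASES, out[hits])
        out[hits] = _BASES[(idx + shift) % 4]
    return out


def make_sim_genome(
    genome_len: int = 3_000_000,
    n_families: int = 3,
    copies_per_family: int = 10,
    te_len_range: Tuple[int, int] = (500, 3000),
    divergence: float = 0.02,
    seed: int = 0,
    chrom_name: str = "chr1",
) -> SimGenome:
    """Build a random genome with planted multi-copy TE families.

    Each family gets a random consensus with length drawn from
    ``te_len_range``; copies diverge from the consensus by the given per-base
    substitution rate and are placed without overlap, away from the sequence
    ends. Deterministic for a fixed seed.
    """
    lo_len, hi_len = te_len_range
    if lo_len < MIN_TE_LEN:
        raise ValueError(f"TE length range must start at >= {MIN_TE_LEN} bp")
    if genome_len < 10 * hi_len:
        raise ValueError("genome_len must be >= 10 x the longest TE")
    rng = np.random.default_rng(seed)
    background = _random_seq(rng, genome_len)

    consensi = {}
    for i in range(n_families):
        fam = f"FAM{chr(ord('A') + i)}"
        length = int(rng.integers(lo_len, hi_len + 1))
        consensi[fam] = _random_seq(rng, length)

    # place copies without overlap (margin keeps copies apart and off the ends)
    margin = 2000
    placements: List[Tuple[int, int, str]] = []  # (start, end, family)
    occupied: List[Tuple[int, int]] = []
    for fam, cons in consensi.items():
        L = len(cons)
        for _ in range(copies_per_family):
            for _attempt in range(10_000):
                start = int(rng.integers(margin, genome_len - L - margin))
                end = start + L
                if all(start - margin >= e or end + margin <= s for s, e in occupied):
                    occupied.append((start, end))
                    placements.append((start, end, fam))
                    break
            else:
                raise RuntimeError("could not place TE copies: genome too crowded")

    placements.sort()
    counters = {fam: 0 for fam in consensi}
    feats = []
    seq = background
    for start, end, fam in placements:
        counters[fam] += 1
        copy_seq = _mutate(rng, consensi[fam], divergence)
        seq[start:end] = copy_seq
        strand = "+" if rng.random() < 0.5 else "-"
        feats.append(TEFeature(chrom_name, start, end, strand, f"{fam}_{counters[fam]}"))

    return SimGenome(
        sequences={chrom_name: seq.tobytes().decode()},
        te_features=feats,
        te_library={fam: cons.tobytes().decode() for fam, cons in consensi.items()},
        divergence=divergence,
    )


def write_genome_fasta(genome: SimGenome, path, width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_te_gff(genome: SimGenome, path) -> None:
    """TE annotation GFF3 with unique Name=FAMILY_x tags."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(genome.te_features, key=lambda f: (f.chrom, f.start)):
            fh.write(
                "\t".join(
                    (
                        f.chrom,
                        "tescout_sim",
                        "transposable_element",
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.name};Name={f.name}",
                    )
                )
                + "\n"
            )
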