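"""Planting of TE insertions into alleles with exact liftover maps.

The two-allele (normal, ND) design carries homozygous insertions in both
alleles and heterozygous ones in a single allele; the four-allele-copy tumor
(TD) design adds a third distinct allele carrying additional low-cell-fraction
insertions, read in the proportion 2:1:1 so those insertions sit at 25 %
allele fraction while homozygous stay at 1.0 and heterozygous at 0.5.

Donor TEs are drawn uniformly from annotated copies of at least 200 bp and
pasted (copy-paste) at random positions at least 100 bp away from annotated
TEs; truth positions are recorded in reference coordinates.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..annotation import TEFeature
from .genome import MIN_TE_LEN, SimGenome

__all__ = ["TruthRecord", "Insertion", "Allele", "plant_insertions", "write_truth_gff", "read_truth_gff"]

TE_EXCLUSION = 100  # bp of clearance from annotated TEs (and N runs)
MIN_SEPARATION = 2000  # bp between planted insertion points


@dataclass(frozen=True)
class TruthRecord:
    """One simulated insertion: where, what, and at which allele fraction."""

    chrom: str
    position: int  # reference coordinate of the insertion point (0-based)
    te_name: str
    te_family: str
    true_af: float
    allele_ids: frozenset

    def __post_init__(self) -> None:
        if self.true_af not in (0.25, 0.5, 1.0):
            raise ValueError(f"true_af must be one of 0.25/0.5/1.0, got {self.true_af}")


@dataclass(frozen=True)
class Insertion:
    chrom: str
    position: int
    donor: TEFeature


class Allele:
    """One haplotype: the reference plus a set of insertions, with liftover.

    The allele sequence is never materialised as a whole; reads are rendered
    from per-chromosome segment maps (reference stretches interleaved with
    inserted TE copies), which makes allele->reference liftover exact.
    """

    def __init__(self, genome: SimGenome, insertions: Sequence[Insertion], allele_id: str, copies: int = 1):
        self.genome = genome
        self.allele_id = allele_id
        self.copies = copies
        self.insertions = sorted(insertions, key=lambda i: (i.chrom, i.position))
        # per chromosome: list of segments (allele_start, length, kind, payload)
        # kind "ref": payload = ref_start; kind "ins": payload = Insertion
        self._segments: Dict[str, List[Tuple[int, int, str, object]]] = {}
        self._starts: Dict[str, List[int]] = {}
        self.lengths: Dict[str, int] = {}
        for chrom, ref_seq in genome.sequences.items():
            segs = []
            pos = 0  # allele coordinate
            ref_pos = 0
            for ins in (i for i in self.insertions if i.chrom == chrom):
                if ins.position > ref_pos:
                    segs.append((pos, ins.position - ref_pos, "ref", ref_pos))
                    pos += ins.position - ref_pos
                    ref_pos = ins.position
                L = ins.donor.length
                segs.append((pos, L, "ins", ins))
                pos += L
            if len(ref_seq) > ref_pos:
                segs.append((pos, len(ref_seq) - ref_pos, "ref", ref_pos))
                pos += len(ref_seq) - ref_pos
            self._segments[chrom] = segs
            self._starts[chrom] = [s[0] for s in segs]
            self.lengths[chrom] = pos

    def segments_overlapping(self, chrom: str, start: int, end: int):
        """Segments (with intra-segment offsets) covering allele range [start, end)."""
        segs = self._segments[chrom]
        starts = self._starts[chrom]
        i = bisect.bisect_right(starts, start) - 1
        out = []
        while i < len(segs) and segs[i][0] < end:
            seg_start, seg_len, kind, payload = segs[i]
            s = max(start, seg_start)
            e = min(end, seg_start + seg_len)
            if s < e:
                out.append((s, e, kind, payload, s - seg_start))
            i += 1
        return out

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Allele sequence for [start, end)."""
        parts = []
        ref_seq = self.genome.sequences[chrom]
        for s, e, kind, payload, off in self.segments_overlapping(chrom, start, end):
            n = e - s
            if kind == "ref":
                rs = payload + off
                parts.append(ref_seq[rs : rs + n])
            else:
                donor = payload.donor
                donor_seq = self.genome.sequences[donor.chrom]
                ds = donor.start + off
                parts.append(donor_seq[ds : ds + n])
        return "".join(parts)


def plant_insertions(
    genome: SimGenome,
    n_hom: int,
    n_het: int,
    n_lcf: int = 0,
    seed: int = 0,
    te_exclusion: int = TE_EXCLUSION,
    min_separation: int = MIN_SEPARATION,
) -> Tuple[List[Allele], List[TruthRecord]]:
    """Plant insertions and build the allele set for the ND or TD design.

    With ``n_lcf == 0`` the result is the two-allele ND design (homozygous in
    both alleles, heterozygous in one); otherwise the four-allele-copy TD
    design (A1 x2, A2, A3) where the LCF insertions live only on A3. Donor
    copies are drawn uniformly among annotated TEs >= 200 bp; every insertion
    point keeps ``te_exclusion`` bp clear of annotated TEs and
    ``min_separation`` bp from other planted insertions.
    """
    rng = np.random.default_rng(seed)
    donors = genome.donors(MIN_TE_LEN)
    if not donors:
        raise ValueError("genome has no TE copies >= 200 bp to use as donors")

    # exclusion intervals around annotated TEs, per chromosome
    te_zones: Dict[str, List[Tuple[int, int]]] = {}
    for f in genome.te_features:
        te_zones.setdefault(f.chrom, []).append(
            (f.start - te_exclusion, f.end + te_exclusion)
        )

    chroms = sorted(genome.sequences)
    chrom_lens = np.array([len(genome.sequences[c]) for c in chroms], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()

    placed: Dict[str, List[int]] = {c: [] for c in chroms}
    edge = 1000  # keep insertions off the sequence ends

    def place_one() -> Tuple[str, int]:
        for _ in range(100_000):
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
            pos = int(rng.integers(edge, len(genome.sequences[chrom]) - edge))
            if any(lo <= pos < hi for lo, hi in te_zones.get(chrom, ())):
                continue
            if any(abs(pos - q) < min_separation for q in placed[chrom]):
                continue
            placed[chrom].append(pos)
            return chrom, pos
        raise RuntimeError("exhausted placement attempts; genome too crowded")

    def make_set(n: int, af: float, allele_ids: frozenset) -> Tuple[List[Insertion], List[TruthRecord]]:
        ins_list, records = [], []
        for _ in range(n):
            chrom, pos = place_one()
            donor = donors[int(rng.integers(len(donors)))]
            ins_list.append(Insertion(chrom, pos, donor))
            records.append(
                TruthRecord(chrom, pos, donor.name, donor.family, af, allele_ids)
            )
        return ins_list, records

    if n_lcf == 0:
        hom, hom_rec = make_set(n_hom, 1.0, frozenset({"A1", "A2"}))
        het, het_rec = make_set(n_het, 0.5, frozenset({"A2"}))
        alleles = [
            Allele(genome, hom, "A1", copies=1),
            Allele(genome, hom + het, "A2", copies=1),
        ]
        truth = hom_rec + het_rec
    else:
        hom, hom_rec = make_set(n_hom, 1.0, frozenset({"A1", "A2", "A3"}))
        het, het_rec = make_set(n_het, 0.5, frozenset({"A2", "A3"}))
        lcf, lcf_rec = make_set(n_lcf, 0.25, frozenset({"A3"}))
        alleles = [
            Allele(genome, hom, "A1", copies=2),
            Allele(genome, hom + het, "A2", copies=1),
            Allele(genome, hom + het + lcf, "A3", copies=1),
        ]
        truth = hom_rec + het_rec + lcf_rec
    truth.sort(key=lambda t: (t.chrom, t.position))
    return alleles, truth


def write_truth_gff(truth: Sequence[TruthRecord], path) -> None:
    """One GFF3 feature per simulated insertion, with a true_af attribute."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, t in enumerate(sorted(truth, key=lambda t: (t.chrom, t.position)), 1):
            fh.write(
                "\t".join(
                    (
                        t.chrom,
                        "tescout_sim",
                        "TE_insertion_site",
                        str(t.position + 1),
                        str(t.position + 1),
                        ".",
                        ".",
                        ".",
                        f"ID=truth_{i};Name={t.te_name};family={t.te_family};"
                        f"true_af={t.true_af};alleles={','.join(sorted(t.allele_ids))}",
                    )
                )
                + "\n"
            )


def read_truth_gff(path) -> List[TruthRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            attrs = dict(item.partition("=")[::2] for item in cols[8].split(";"))
            out.append(
                TruthRecord(
                    cols[0],
                    int(cols[3]) - 1,
                    attrs.get("Name", "."),
                    attrs.get("family", "."),
                    float(attrs.get("true_af", 1.0)),
                    frozenset(attrs.get("alleles", "").split(",")),
                )
            )
    return out
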