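"""Lightweight alignment-record abstraction used by the scan and clustering code.

Only the fields the caller needs are carried: coordinates, strand, mapping
quality, soft-clip lengths, the proper-pair flag, mate position and any
alternative placements recorded in an XA-style tag
``(chrom,±pos,CIGAR,NM;)*`` with 1-based signed positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

__all__ = ["AltHit", "ReadAlignment", "parse_xa", "cigar_reference_span"]

_CIG_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# CIGAR ops that consume the reference
_REF_OPS = set("MDN=X")


def cigar_reference_span(cigar: str) -> int:
    """Reference bases consumed by a CIGAR string."""
    return sum(int(n) for n, op in _CIG_RE.findall(cigar) if op in _REF_OPS)


@dataclass(frozen=True)
class AltHit:
    """One alternative placement from an XA-style tag (0-based start)."""

    chrom: str
    start: int
    strand: str
    ref_span: int

    @property
    def end(self) -> int:
        return self.start + self.ref_span


def parse_xa(tag: str) -> List[AltHit]:
    """Parse an XA tag value ``chrom,±pos,CIGAR,NM;...`` into alt hits."""
    hits = []
    for entry in tag.strip(";").split(";"):
        if not entry:
            continue
        parts = entry.split(",")
        if len(parts) < 3:
            continue
        chrom, spos, cigar = parts[0], parts[1], parts[2]
        strand = spos[0] if spos[0] in "+-" else "+"
        pos = int(spos.lstrip("+-")) - 1
        hits.append(AltHit(chrom, pos, strand, cigar_reference_span(cigar) or 1))
    return hits


@dataclass
class ReadAlignment:
    """A mapped primary alignment record."""

    name: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str  # '+' or '-'
    mapq: int
    proper_pair: bool
    template_length: int
    left_clip: int = 0
    right_clip: int = 0
    alt_hits: List[AltHit] = field(default_factory=list)
    mate_chrom: Optional[str] = None
    mate_start: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"read {self.name}: start {self.start} >= end {self.end}")
        if self.left_clip < 0 or self.right_clip < 0:
            raise ValueError("clip lengths must be >= 0")

    @property
    def is_forward(self) -> bool:
        return self.strand == "+"

    @classmethod
    def from_pysam(cls, rec) -> "ReadAlignment":
        """Build from a mapped primary pysam.AlignedSegment."""
        cig = rec.cigartuples or []
        left = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
        right = cig[-1][1] if cig and cig[-1][0] in (4, 5) else 0
        alt = []
        if rec.has_tag("XA"):
            alt = parse_xa(rec.get_tag("XA"))
        return cls(
            name=rec.query_name,
            chrom=rec.reference_name,
            start=rec.reference_start,
            end=rec.reference_end,
            strand="-" if rec.is_reverse else "+",
            mapq=rec.mapping_quality,
            proper_pair=rec.is_proper_pair,
            template_length=rec.template_length,
            left_clip=left,
            right_clip=right,
            alt_hits=alt,
            mate_chrom=rec.next_reference_name if not rec.mate_is_unmapped else None,
            mate_start=rec.next_reference_start if not rec.mate_is_unmapped else None,
        )
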