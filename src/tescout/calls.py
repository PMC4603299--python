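"""The TEI call record: one putative insertion with its evidence and metrics."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .clustering import Cluster, ClusterPair

__all__ = ["TEICall"]


@dataclass
class TEICall:
    """A putative TE insertion called from a forward/reverse cluster pair.

    Coordinates are 0-based half-open; ``zygosity`` is present exactly when a
    breakpoint could be refined from clipped reads.
    """

    chrom: str
    lo: int
    hi: int
    fwd: Cluster
    rev: Cluster
    breakpoint: Optional[int] = None
    clipped_support: int = 0
    core_reads: int = 0
    zygosity: Optional[float] = None
    predicted_te_name: str = "."
    predicted_te_family: str = "."
    consistent_te: bool = False
    filter_status: str = "raw"

    def __post_init__(self) -> None:
        if self.zygosity is not None and not 0.0 <= self.zygosity <= 1.0:
            raise ValueError(f"zygosity out of [0,1]: {self.zygosity}")
        if (self.zygosity is None) != (self.breakpoint is None):
            raise ValueError("zygosity must be present iff breakpoint is present")
        if self.clipped_support < 0:
            raise ValueError("clipped_support must be >= 0")

    # --- metrics -----------------------------------------------------------

    @property
    def interval_length(self) -> int:
        return self.hi - self.lo

    @property
    def fwd_size(self) -> int:
        return self.fwd.size

    @property
    def rev_size(self) -> int:
        return self.rev.size

    @property
    def fwd_span(self) -> int:
        return self.fwd.span

    @property
    def rev_span(self) -> int:
        return self.rev.span

    @property
    def locus(self) -> int:
        """Anchor point of the call: breakpoint if refined, else interval midpoint."""
        if self.breakpoint is not None:
            return self.breakpoint
        return (self.lo + self.hi) // 2

    @property
    def passed(self) -> bool:
        return self.filter_status == "pass"
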