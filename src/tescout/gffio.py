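"""Writers (and a reader) for call output: GFF3 and the per-call TSV table.

Internal coordinates are 0-based half-open; output follows the GFF3
convention (1-based inclusive). Missing values are rendered as ``.``.
"""

from __future__ import annotations

from typing import Iterable, List, Optional
from urllib.parse import quote

import pandas as pd

from .calls import TEICall

__all__ = ["write_calls_gff", "read_calls_gff", "write_call_table", "GffCall"]

_GFF_ESCAPE = ";=%&,\t\n"


def _esc(value: str) -> str:
    return quote(str(value), safe="".join(c for c in map(chr, range(33, 127)) if c not in _GFF_ESCAPE))


def _fmt_zyg(z: Optional[float]) -> str:
    return "." if z is None else f"{z:.3f}"


def write_calls_gff(calls: Iterable[TEICall], path) -> None:
    """Write calls as GFF3 ``TE_insertion`` features, ordered by (chrom, start).

    Score is the clipped support; attributes carry the zygosity, breakpoint,
    core reads, cluster metrics and filter status.
    """
    calls = sorted(calls, key=lambda c: (c.chrom, c.lo, c.hi))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(calls, 1):
            start = c.lo + 1  # 1-based inclusive
            end = max(c.hi, c.lo + 1)  # point intervals render as single-base
            attrs = [
                f"ID=tei_{i}",
                f"Name={_esc(c.predicted_te_name)}",
                f"family={_esc(c.predicted_te_family)}",
                f"zygosity={_fmt_zyg(c.zygosity)}",
                f"breakpoint={'.' if c.breakpoint is None else c.breakpoint + 1}",
                f"core_reads={c.core_reads}",
                f"fwd_cluster_size={c.fwd_size}",
                f"rev_cluster_size={c.rev_size}",
                f"fwd_span={c.fwd_span}",
                f"rev_span={c.rev_span}",
                f"interval_length={c.interval_length}",
                f"consistent_te={str(c.consistent_te).lower()}",
                f"filter_status={_esc(c.filter_status)}",
            ]
            fh.write(
                "\t".join(
                    (
                        c.chrom,
                        "tescout",
                        "TE_insertion",
                        str(start),
                        str(end),
                        str(c.clipped_support),
                        ".",
                        ".",
                        ";".join(attrs),
                    )
                )
                + "\n"
            )


class GffCall:
    """A call as read back from GFF output (coordinates restored to 0-based)."""

    def __init__(self, chrom, lo, hi, attrs, score):
        self.chrom = chrom
        self.lo = lo
        self.hi = hi
        self.clipped_support = score
        z = attrs.get("zygosity", ".")
        self.zygosity = None if z == "." else float(z)
        b = attrs.get("breakpoint", ".")
        self.breakpoint = None if b == "." else int(b) - 1
        self.core_reads = int(attrs.get("core_reads", 0))
        self.predicted_te_name = attrs.get("Name", ".")
        self.predicted_te_family = attrs.get("family", ".")
        self.consistent_te = attrs.get("consistent_te") == "true"
        self.filter_status = attrs.get("filter_status", "raw")
        self.fwd_size = int(attrs.get("fwd_cluster_size", 0))
        self.rev_size = int(attrs.get("rev_cluster_size", 0))
        self.fwd_span = int(attrs.get("fwd_span", 0))
        self.rev_span = int(attrs.get("rev_span", 0))
        self.interval_length_attr = int(attrs.get("interval_length", self.hi - self.lo))

    @property
    def interval_length(self):
        return self.interval_length_attr

    @property
    def locus(self) -> int:
        return self.breakpoint if self.breakpoint is not None else (self.lo + self.hi) // 2

    @property
    def passed(self) -> bool:
        return self.filter_status == "pass"


def read_calls_gff(path) -> List[GffCall]:
    """Read a call GFF back into lightweight call records."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF line: {line!r}")
            chrom, _, ftype, start, end, score, _, _, attr_col = cols
            if ftype != "TE_insertion":
                continue
            attrs = {}
            for item in attr_col.split(";"):
                if "=" in item:
                    k, _, v = item.partition("=")
                    attrs[k] = v
            lo = int(start) - 1
            hi = int(end)
            if attrs.get("interval_length") == "0":
                hi = lo  # collapsed point interval
            out.append(GffCall(chrom, lo, hi, attrs, int(score)))
    return out


_TABLE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "breakpoint",
    "fwd_cluster_size",
    "rev_cluster_size",
    "fwd_span",
    "rev_span",
    "interval_length",
    "clipped_support",
    "core_reads",
    "zygosity",
    "te_name",
    "te_family",
    "consistent_te",
    "fwd_reads",
    "rev_reads",
    "filter_status",
]


def write_call_table(calls: Iterable[TEICall], path) -> None:
    """Write the per-call TSV table (1-based inclusive coordinates).

    One row per call with cluster metrics and the semicolon-delimited names of
    the supporting reads per cluster, for downstream *NIX-tool workflows.
    """
    rows = []
    for c in sorted(calls, key=lambda c: (c.chrom, c.lo, c.hi)):
        rows.append(
            {
                "chrom": c.chrom,
                "start": c.lo + 1,
                "end": max(c.hi, c.lo + 1),
                "breakpoint": "." if c.breakpoint is None else c.breakpoint + 1,
                "fwd_cluster_size": c.fwd_size,
                "rev_cluster_size": c.rev_size,
                "fwd_span": c.fwd_span,
                "rev_span": c.rev_span,
                "interval_length": c.interval_length,
                "clipped_support": c.clipped_support,
                "core_reads": c.core_reads,
                "zygosity": _fmt_zyg(c.zygosity),
                "te_name": c.predicted_te_name,
                "te_family": c.predicted_te_family,
                "consistent_te": str(c.consistent_te).lower(),
                "fwd_reads": ";".join(c.fwd.read_names),
                "rev_reads": ";".join(c.rev.read_names),
                "filter_status": c.filter_status,
            }
        )
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
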