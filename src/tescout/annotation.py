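"""TE annotation loading and interval indexing.

The reference's transposable elements are supplied as GFF3 with unique
``Name=FAMILY_x`` tags; the family is the name with its trailing ``_digits``
stripped. Coordinates are converted to 0-based half-open at this boundary and
everywhere internally.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Set

import gffutils
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

__all__ = ["TEFeature", "TEIndex", "load_te_annotation", "parse_family"]

_FAMILY_RE = re.compile(r"_\d+$")


def parse_family(name: str) -> str:
    """Family of a TE copy: the unique name with its trailing ``_digits`` removed."""
    return _FAMILY_RE.sub("", name)


@dataclass(frozen=True)
class TEFeature:
    """One annotated TE copy, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"TE feature {self.name}: start {self.start} >= end {self.end}")

    @property
    def family(self) -> str:
        return parse_family(self.name)

    @property
    def length(self) -> int:
        return self.end - self.start


class TEIndex:
    """Per-chromosome interval index over TE features."""

    def __init__(self, features: Iterable[TEFeature]):
        self.features: List[TEFeature] = []
        self._by_name: Dict[str, TEFeature] = {}
        self._trees: Dict[str, IntervalTree] = {}
        seen: Set[str] = set()
        for feat in features:
            name = feat.name
            if name in seen:
                k = 2
                while f"{name}.{k}" in seen:
                    k += 1
                new = f"{name}.{k}"
                log.warning("duplicate TE name %r renamed to %r", name, new)
                feat = TEFeature(feat.chrom, feat.start, feat.end, feat.strand, new)
            seen.add(feat.name)
            self.features.append(feat)
            self._by_name[feat.name] = feat
            self._trees.setdefault(feat.chrom, IntervalTree()).addi(feat.start, feat.end, feat)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[TEFeature]:
        return iter(self.features)

    def get(self, name: str) -> Optional[TEFeature]:
        return self._by_name.get(name)

    def overlapping(self, chrom: str, start: int, end: int) -> List[TEFeature]:
        """TE features overlapping [start, end) by at least one base."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps(start, end))

    def families(self) -> Dict[str, List[TEFeature]]:
        fams: Dict[str, List[TEFeature]] = {}
        for feat in self.features:
            fams.setdefault(feat.family, []).append(feat)
        return fams


def load_te_annotation(gff_path) -> TEIndex:
    """Load a TE annotation GFF3 into an interval index.

    GFF3 1-based closed coordinates become 0-based half-open. Features lacking
    a ``Name`` attribute receive a synthesized unique name (with a warning).
    """
    try:
        db = gffutils.create_db(
            str(gff_path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError as exc:
        raise ValueError(f"no TE features found in {gff_path}") from exc
    feats: List[TEFeature] = []
    unnamed = 0
    for f in db.all_features():
        names = f.attributes.get("Name")
        if names:
            name = names[0]
        else:
            unnamed += 1
            name = f"UNNAMED_TE_{unnamed}"
            log.warning(
                "feature %s:%d-%d lacks a Name attribute; synthesized %r",
                f.seqid, f.start, f.end, name,
            )
        strand = f.strand if f.strand in ("+", "-") else "."
        feats.append(TEFeature(f.seqid, f.start - 1, f.end, strand, name))
    if not feats:
        raise ValueError(f"no TE features found in {gff_path}")
    return TEIndex(feats)
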