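"""Scoring of predicted insertions against a simulated truth set.

A call matches a truth record when its locus (refined breakpoint, else the
insertion-interval midpoint) padded by ``pad`` bp covers the true insertion
point; matching is one-to-one and greedy by distance. Zygosity is scored by
classifying the predicted allele fraction to the nearest truth class present
in the truth set, with the homozygous boundary at 0.75 (ties up).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .insertions import TruthRecord

__all__ = ["ScoreReport", "score_predictions", "classify_af", "DEFAULT_PAD"]

DEFAULT_PAD = 20
HOM_THRESHOLD = 0.75


def classify_af(z: float, classes: Sequence[float]) -> float:
    """Classify a predicted allele fraction to the nearest truth class.

    With 1.0 among the classes the homozygous boundary sits at 0.75
    (z >= 0.75 -> 1.0); below it (or without a homozygous class) the nearest
    class wins, ties going to the larger fraction.
    """
    classes = sorted(set(classes), reverse=True)
    if 1.0 in classes and z >= HOM_THRESHOLD:
        return 1.0
    sub = [c for c in classes if c != 1.0] or classes
    return min(sub, key=lambda c: (abs(z - c), -c))


@dataclass
class MatchedCall:
    call: object
    truth: TruthRecord
    breakpoint_error: int


@dataclass
class ScoreReport:
    """Evaluation of one call set against one truth set."""

    tp: int
    fp: int
    fn: int
    matches: List[MatchedCall] = field(repr=False, default_factory=list)
    unmatched_calls: List[object] = field(repr=False, default_factory=list)
    n_truth: int = 0
    _n_truth_af: Dict[float, int] = field(repr=False, default_factory=dict)

    @property
    def ppv(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def truth_classes(self) -> List[float]:
        return sorted({m.truth.true_af for m in self.matches})

    def zygosity_accuracy(self) -> Optional[float]:
        """Percent of TP calls with defined zygosity classified to the truth class."""
        scored = [m for m in self.matches if getattr(m.call, "zygosity", None) is not None]
        if not scored:
            return None
        classes = self.truth_classes
        good = sum(
            classify_af(m.call.zygosity, classes) == m.truth.true_af for m in scored
        )
        return 100.0 * good / len(scored)

    def breakpoint_errors(self) -> List[int]:
        return [m.breakpoint_error for m in self.matches]

    def detection_rate(self, true_af: float) -> Optional[float]:
        """Percent of truth records at a given allele fraction that were recalled."""
        total = self._n_truth_af.get(true_af, 0)
        if not total:
            return None
        hit = sum(m.truth.true_af == true_af for m in self.matches)
        return 100.0 * hit / total

    def mean_predicted_af(self, true_af: float) -> Optional[float]:
        vals = [
            m.call.zygosity
            for m in self.matches
            if m.truth.true_af == true_af and getattr(m.call, "zygosity", None) is not None
        ]
        return sum(vals) / len(vals) if vals else None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.matches:
            rows.append(
                {
                    "chrom": m.truth.chrom,
                    "truth_pos": m.truth.position,
                    "true_af": m.truth.true_af,
                    "call_locus": m.call.locus,
                    "breakpoint_error": m.breakpoint_error,
                    "zygosity": getattr(m.call, "zygosity", None),
                    "status": "TP",
                }
            )
        for c in self.unmatched_calls:
            rows.append(
                {
                    "chrom": c.chrom,
                    "truth_pos": None,
                    "true_af": None,
                    "call_locus": c.locus,
                    "breakpoint_error": None,
                    "zygosity": getattr(c, "zygosity", None),
                    "status": "FP",
                }
            )
        return pd.DataFrame(rows)


def score_predictions(
    calls: Sequence[object],
    truth: Sequence[TruthRecord],
    pad: int = DEFAULT_PAD,
) -> ScoreReport:
    """Score a call set against the truth, greedy one-to-one matching by distance."""
    candidates: List[Tuple[int, int, int]] = []  # (distance, call_idx, truth_idx)
    for ci, call in enumerate(calls):
        locus = call.locus
        for ti, t in enumerate(truth):
            if t.chrom != call.chrom:
                continue
            d = abs(locus - t.position)
            if d <= pad:
                candidates.append((d, ci, ti))
    candidates.sort()
    used_c: set = set()
    used_t: set = set()
    matches = []
    for d, ci, ti in candidates:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        matches.append(MatchedCall(calls[ci], truth[ti], d))
    tp = len(matches)
    fp = len(calls) - tp
    fn = len(truth) - tp
    report = ScoreReport(
        tp=tp,
        fp=fp,
        fn=fn,
        matches=matches,
        unmatched_calls=[c for i, c in enumerate(calls) if i not in used_c],
        n_truth=len(truth),
    )
    for t in truth:
        report._n_truth_af[t.true_af] = report._n_truth_af.get(t.true_af, 0) + 1
    return report
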