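"""Library-derived filter cutoffs and their application to raw calls.

Default cutoffs are generated from the library statistics and coverage:

    2 < cluster_size     < 5 * coverage        (each strand cluster)
    2 < span             < mean_fragment_length
    mean_read_length < interval_length
                     < 2 * (mean_fragment_length + 2*sd_fragment
                            - (mean_read_length - sd_read_length))
    2 < clipped_support  < 5 * coverage

All comparisons are strict. TE consistency is reported as a metric but not
enforced by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List

from .calls import TEICall
from .library import LibraryStats

__all__ = ["FilterConfig", "default_cutoffs", "apply_filter"]


@dataclass(frozen=True)
class FilterConfig:
    """Exclusive min/max bounds for the call metrics."""

    cluster_size_min: float
    cluster_size_max: float
    span_min: float
    span_max: float
    interval_len_min: float
    interval_len_max: float
    clipped_support_min: float
    clipped_support_max: float
    require_consistent_te: bool = False

    def __post_init__(self) -> None:
        for metric in ("cluster_size", "span", "interval_len", "clipped_support"):
            lo = getattr(self, f"{metric}_min")
            hi = getattr(self, f"{metric}_max")
            if not lo < hi:
                raise ValueError(f"{metric}: min {lo} must be < max {hi}")
            if not (lo > 0 and hi > 0):
                raise ValueError(f"{metric}: bounds must be > 0 (got {lo}, {hi})")


def default_cutoffs(stats: LibraryStats, coverage: float) -> FilterConfig:
    """Generate the default cutoffs from library statistics and fold-coverage."""
    if not coverage > 0:
        raise ValueError("coverage must be > 0")
    five_cov = 5 * coverage
    if five_cov <= 3:
        raise ValueError(
            f"coverage {coverage} too low for generated cutoffs (5*coverage = "
            f"{five_cov} <= 3); supply a manual filter config instead"
        )
    interval_max = 2 * (
        stats.fragment_mean
        + 2 * stats.fragment_sd
        - (stats.read_len_mean - stats.read_len_sd)
    )
    return FilterConfig(
        cluster_size_min=2,
        cluster_size_max=five_cov,
        span_min=2,
        span_max=stats.fragment_mean,
        interval_len_min=stats.read_len_mean,
        interval_len_max=interval_max,
        clipped_support_min=2,
        clipped_support_max=five_cov,
    )


def _first_violation(call: TEICall, cfg: FilterConfig) -> str:
    checks = (
        ("cluster_size", call.fwd_size),
        ("cluster_size", call.rev_size),
        ("span", call.fwd_span),
        ("span", call.rev_span),
        ("interval_len", call.interval_length),
        ("clipped_support", call.clipped_support),
    )
    for metric, value in checks:
        lo = getattr(cfg, f"{metric}_min")
        hi = getattr(cfg, f"{metric}_max")
        if not (lo < value < hi):
            return metric
    if cfg.require_consistent_te and not call.consistent_te:
        return "consistent_te"
    return ""


def apply_filter(calls: Iterable[TEICall], cfg: FilterConfig) -> List[TEICall]:
    """Set each call's filter status; returns the same call objects.

    A call passes when both cluster sizes, both spans, the interval length
    and the clipped support lie strictly inside their bounds (and, if
    required, the TE identity is consistent). Failing calls record the first
    violated criterion as ``fail:<criterion>``. Idempotent.
    """
    calls = list(calls)
    for call in calls:
        bad = _first_violation(call, cfg)
        call.filter_status = "pass" if not bad else f"fail:{bad}"
    return calls
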