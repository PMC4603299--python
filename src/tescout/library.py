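"""Sequencing-library statistics, run parameters and the key=value config format.

Every downstream quantity — predicted insertion intervals, the discordance
distance rule and the generated filter cutoffs — is a function of the fragment
(insert-size) and read-length distributions of the sequencing library, so these
are estimated once up front from properly-paired reads, or loaded from a config
file written by a previous run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import IO, Iterable, Mapping, Optional, Tuple

__all__ = [
    "LibraryStats",
    "RunParams",
    "LibraryError",
    "ConfigError",
    "estimate_library_stats",
    "estimate_coverage",
    "load_stats_config",
    "write_stats_config",
]


class LibraryError(ValueError):
    """Raised when a BAM cannot support library-statistics estimation."""


class ConfigError(ValueError):
    """Raised when a stats/filter config file is malformed."""


# minimum number of proper pairs below which the library is considered unusable
MIN_PROPER_PAIRS = 100


@dataclass(frozen=True)
class LibraryStats:
    """Fragment-size and read-length distribution of a paired-end library.

    All lengths are in base pairs. ``fragment_mean`` is the outer distance
    (aligner "insert size", |TLEN| of a proper pair); standard deviations are
    population standard deviations.
    """

    fragment_mean: float
    fragment_sd: float
    read_len_mean: float
    read_len_sd: float
    n_pairs_sampled: int = 0

    def __post_init__(self) -> None:
        if not self.fragment_mean > 0:
            raise ValueError(f"fragment_mean must be > 0, got {self.fragment_mean}")
        if self.fragment_sd < 0:
            raise ValueError(f"fragment_sd must be >= 0, got {self.fragment_sd}")
        if not self.read_len_mean > 0:
            raise ValueError(f"read_len_mean must be > 0, got {self.read_len_mean}")
        if self.read_len_sd < 0:
            raise ValueError(f"read_len_sd must be >= 0, got {self.read_len_sd}")
        if self.fragment_mean < self.read_len_mean:
            raise ValueError(
                "fragment_mean must be >= read_len_mean "
                f"({self.fragment_mean} < {self.read_len_mean})"
            )


@dataclass
class RunParams:
    """Global run parameters.

    ``s_factor`` multiplies the fragment-length standard deviation in the
    predicted-insertion-interval formula; ``mapq_min`` is the anchor-read
    mapping-quality threshold (poorly mapped reads, mapQ < 15, occur almost
    exclusively in false positives); ``coverage`` overrides the estimated
    fold-coverage used in generated filter cutoffs.
    """

    s_factor: float = 2.0
    mapq_min: int = 15
    bin_size: int = 50_000_000
    n_processes: int = 1
    coverage: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s_factor < 0:
            raise ValueError("s_factor must be >= 0")
        if self.mapq_min < 0:
            raise ValueError("mapq_min must be >= 0")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        if self.coverage is not None and not self.coverage > 0:
            raise ValueError("coverage must be > 0 when given")

    def check_bin_size(self, stats: LibraryStats) -> None:
        if self.bin_size <= 4 * stats.fragment_mean:
            raise ValueError(
                f"bin_size {self.bin_size} too small: must exceed "
                f"4 x fragment_mean ({4 * stats.fragment_mean:.0f})"
            )


def estimate_library_stats(alignment_stream: Iterable, max_pairs: int = 1_000_000) -> LibraryStats:
    """Estimate fragment and read-length statistics over proper pairs.

    Iterates the stream and uses the first ``max_pairs`` records flagged as
    properly paired with positive template length (one record per pair, the
    leftmost mate), taking |TLEN| as the fragment length. Population standard
    deviations are used.
    """
    if max_pairs < 1:
        raise ValueError("max_pairs must be >= 1")
    n = 0
    frag_sum = frag_sq = 0.0
    rl_sum = rl_sq = 0.0
    for rec in alignment_stream:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if not rec.is_proper_pair:
            continue
        tlen = rec.template_length
        if tlen <= 0:  # count each pair once via its leftmost mate
            continue
        rl = rec.infer_read_length() or rec.query_length or 0
        if rl <= 0:
            continue
        n += 1
        frag_sum += tlen
        frag_sq += tlen * tlen
        rl_sum += rl
        rl_sq += rl * rl
        if n >= max_pairs:
            break
    if n < MIN_PROPER_PAIRS:
        raise LibraryError(
            f"only {n} proper pairs found (need >= {MIN_PROPER_PAIRS}); "
            "library statistics cannot be estimated from this BAM"
        )
    fmean = frag_sum / n
    fvar = max(frag_sq / n - fmean * fmean, 0.0)
    rmean = rl_sum / n
    rvar = max(rl_sq / n - rmean * rmean, 0.0)
    return LibraryStats(fmean, math.sqrt(fvar), rmean, math.sqrt(rvar), n)


def estimate_coverage(alignment_stream: Iterable, reference_lengths: Mapping[str, int]) -> float:
    """Mean fold-coverage: total aligned read bases / total reference length."""
    total_ref = sum(reference_lengths.values())
    if total_ref <= 0:
        raise ValueError("total reference length is zero")
    total_bases = 0
    for rec in alignment_stream:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        total_bases += rec.query_alignment_length
    return total_bases / total_ref


_STATS_KEYS = ("fragment_mean", "fragment_sd", "read_len_mean", "read_len_sd")
_FILTER_KEYS = (
    "cluster_size_min",
    "cluster_size_max",
    "span_min",
    "span_max",
    "interval_len_min",
    "interval_len_max",
    "clipped_support_min",
    "clipped_support_max",
)


def _parse_kv(handle: IO[str]) -> dict:
    out = {}
    for lineno, raw in enumerate(handle, 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected key=value, got {raw.strip()!r}")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def load_stats_config(path) -> Tuple[LibraryStats, Optional["FilterConfig"]]:
    """Load library stats (and optionally filter cutoffs) from a config file.

    The format is plain ``key=value`` lines with ``#`` comments. Returns the
    filter config only when all eight bound keys are present.
    """
    from .filtering import FilterConfig  # local import avoids a cycle

    with open(path) as fh:
        kv = _parse_kv(fh)
    vals = {}
    for key in _STATS_KEYS:
        if key not in kv:
            raise ConfigError(f"missing mandatory key {key!r} in {path}")
        try:
            vals[key] = float(kv[key])
        except ValueError:
            raise ConfigError(f"non-numeric value for {key!r}: {kv[key]!r}") from None
    try:
        stats = LibraryStats(n_pairs_sampled=int(float(kv.get("n_pairs_sampled", 0))), **vals)
    except ValueError as exc:
        raise ConfigError(f"invalid library stats in {path}: {exc}") from None

    fconf = None
    present = [k for k in _FILTER_KEYS if k in kv]
    if present:
        if len(present) != len(_FILTER_KEYS):
            missing = sorted(set(_FILTER_KEYS) - set(present))
            raise ConfigError(f"incomplete filter section: missing {', '.join(missing)}")
        fvals = {}
        for key in _FILTER_KEYS:
            try:
                fvals[key] = float(kv[key])
            except ValueError:
                raise ConfigError(f"non-numeric value for {key!r}: {kv[key]!r}") from None
        req = kv.get("require_consistent_te", "false").lower() in ("1", "true", "yes")
        try:
            fconf = FilterConfig(require_consistent_te=req, **fvals)
        except ValueError as exc:
            raise ConfigError(f"invalid filter config in {path}: {exc}") from None
    return stats, fconf


def write_stats_config(path, stats: LibraryStats, filter_config: Optional["FilterConfig"] = None) -> None:
    """Write stats (and optional filter cutoffs) in the key=value format.

    Numeric values round-trip exactly through :func:`load_stats_config` (repr
    of floats is exact).
    """
    with open(path, "w") as fh:
        fh.write("# sequencing library statistics (bp)\n")
        for key in _STATS_KEYS:
            fh.write(f"{key}={getattr(stats, key)!r}\n")
        fh.write(f"n_pairs_sampled={stats.n_pairs_sampled}\n")
        if filter_config is not None:
            fh.write("# filter cutoffs (exclusive bounds)\n")
            for key in _FILTER_KEYS:
                fh.write(f"{key}={getattr(filter_config, key)!r}\n")
            fh.write(f"require_consistent_te={str(filter_config.require_consistent_te).lower()}\n")
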