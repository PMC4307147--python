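"""Per-read k-mer count profiles and discontinuity detection.

A read of length r yields r-k+1 counts, entry i being the table count of
the k-mer left-anchored at position i.  An error-free read drawn from a
randomly sampled genome has a profile that drifts smoothly with local
coverage; a sequencing error produces an abrupt step.  Adjacent entries
(c_d, c_{d+1}) are flagged as a discontinuity when their difference is both
greater than 3 and greater than 20% of the larger count — both inequalities
strict.  The fixed component governs low-coverage data, the relative
component high-coverage data; low counts alone are never treated as
erroneous.

The nucleotide implicated by a discontinuity with left index d is N = d for
a low-to-high step and N = d + k for a high-to-low step (clamped to the
final base when it would fall past the read end).  All coordinates are
0-based; intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .kmer_store import KmerTable, iter_codes

ABS_THRESHOLD = 3
REL_THRESHOLD = 0.2


class Direction(Enum):
    LOW_TO_HIGH = "low_to_high"
    HIGH_TO_LOW = "high_to_low"


@dataclass(frozen=True)
class Discontinuity:
    d: int  # left index of the offending adjacent pair
    direction: Direction
    counts: tuple[int, int]


@dataclass(frozen=True)
class ErrorSite:
    N: int  # 0-based nucleotide position implicated
    source: Discontinuity


def count_profile(sequence: str, table: KmerTable) -> list[int] | None:
    """Table counts of each left-anchored k-mer; ``None`` when r < k."""
    if len(sequence) < table.k:
        return None
    counts = table.counts
    return [counts.get(fwd, 1) for fwd, _ in iter_codes(sequence, table.k)]


def is_discontinuous(
    left: int,
    right: int,
    abs_threshold: float = ABS_THRESHOLD,
    rel_threshold: float = REL_THRESHOLD,
) -> bool:
    diff = abs(left - right)
    return diff > abs_threshold and diff > rel_threshold * max(left, right)


def find_discontinuities(
    profile: list[int],
    abs_threshold: float = ABS_THRESHOLD,
    rel_threshold: float = REL_THRESHOLD,
) -> list[Discontinuity]:
    """Flag adjacent count pairs exceeding both threshold components."""
    out = []
    for d in range(len(profile) - 1):
        left, right = profile[d], profile[d + 1]
        if is_discontinuous(left, right, abs_threshold, rel_threshold):
            direction = (
                Direction.LOW_TO_HIGH if right > left else Direction.HIGH_TO_LOW
            )
            out.append(Discontinuity(d, direction, (left, right)))
    return out


def locate_error(disc: Discontinuity, k: int, read_length: int) -> ErrorSite:
    """Map a discontinuity to the implicated nucleotide position.

    For deletions the low-to-high site is the base immediately before the
    missing base(s) and the high-to-low site the base immediately after.
    """
    if disc.direction is Direction.LOW_TO_HIGH:
        n = disc.d
    else:
        n = min(disc.d + k, read_length - 1)
    return ErrorSite(N=n, source=disc)


def trusted_regions(
    profile_length: int, discs: list[Discontinuity]
) -> list[tuple[int, int]]:
    """Maximal half-open index intervals containing no flagged pair."""
    if profile_length == 0:
        return []
    if discs and len(discs) >= profile_length - 1:
        return []  # every adjacent pair flagged: nothing to anchor on
    regions = []
    start = 0
    for disc in discs:
        regions.append((start, disc.d + 1))
        start = disc.d + 1
    regions.append((start, profile_length))
    return [(a, b) for a, b in regions if b > a]
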