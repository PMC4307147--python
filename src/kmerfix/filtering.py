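"""Post-correction low-information read flagging and the quality baseline.

After correction, a read whose k-mer count profile is more than 50% unique
k-mers (count 1) is considered to carry little usable information.  Such
reads are still corrected but written to a separate output rather than
discarded.  For paired-end data a pair is flagged only when BOTH mates
exceed the threshold, which rescues many otherwise-unusable reads.

A simple quality-score filter (drop reads with more than 10% of bases at
Q10 or below) is provided as the baseline this approach improves on; it is
not part of the main pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .kmer_store import KmerTable
from .profile import count_profile
from .read_io import ReadRecord


class FlagReason(Enum):
    NONE = "none"
    UNIQUE_KMERS = "unique_kmers"


@dataclass(frozen=True)
class FilterVerdict:
    unique_fraction: float
    flagged: bool
    reason: FlagReason


def unique_fraction(profile: list[int] | None) -> float:
    """Fraction of profile entries equal to 1.

    Reads too short to have a profile are treated as uninformative
    (fraction 1): they cannot be corrected or vouched for.
    """
    if profile is None or not profile:
        return 1.0
    return sum(1 for c in profile if c == 1) / len(profile)


def read_unique_fraction(read: ReadRecord, table: KmerTable) -> float:
    return unique_fraction(count_profile(read.sequence, table))


def flag_low_information(
    fraction: float, threshold: float = 0.5
) -> FilterVerdict:
    """Single-read rule: flagged iff strictly more than ``threshold`` unique."""
    flagged = fraction > threshold
    return FilterVerdict(
        fraction, flagged, FlagReason.UNIQUE_KMERS if flagged else FlagReason.NONE
    )


def flag_pair(
    fraction1: float, fraction2: float, threshold: float = 0.5
) -> tuple[FilterVerdict, FilterVerdict]:
    """Pair rule: both mates are flagged only when both exceed the threshold."""
    both = fraction1 > threshold and fraction2 > threshold
    reason = FlagReason.UNIQUE_KMERS if both else FlagReason.NONE
    return (
        FilterVerdict(fraction1, both, reason),
        FilterVerdict(fraction2, both, reason),
    )


def quality_filter(read: ReadRecord, q_cut: int = 10, frac_cut: float = 0.10) -> bool:
    """Baseline comparator: True iff more than ``frac_cut`` of bases are <= ``q_cut``."""
    if not read.qualities:
        return False
    low = sum(1 for q in read.qualities if q <= q_cut)
    return low / len(read.qualities) > frac_cut
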