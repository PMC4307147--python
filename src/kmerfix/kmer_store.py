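"""Two-bit k-mer encoding and global k-mer counting.

A k-mer over {A,C,G,T} is packed into an unsigned integer two bits per base
(A=00, C=01, G=10, T=11), 5' end in the most significant bits, so any odd
k <= 31 fits one 64-bit word.  Counting records every observed k-mer AND its
reverse complement as separate entries of a single table, which makes a
single lookup strand-symmetric by construction.

Two policies shape downstream behaviour:

* unique k-mers (count 1) are pruned from the table before correction;
* a lookup of an absent k-mer reports a count of 1, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE = "ACGT"
_SATURATE = 2**32 - 1

DEFAULT_K = 31


def validate_k(k: int) -> int:
    if not (1 < k <= 31) or k % 2 == 0:
        raise ValueError(f"k must be odd and in (1, 31], got {k}")
    return k


def encode_kmer(seq: str) -> int:
    """Pack a {A,C,G,T} string into its 2-bit integer code."""
    code = 0
    try:
        for base in seq:
            code = (code << 2) | _CODE[base]
    except KeyError as exc:
        raise ValueError(f"non-ACGT character {exc.args[0]!r} in k-mer") from None
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append(_BASE[(code >> shift) & 3])
    return "".join(out)


def reverse_complement(code: int, k: int) -> int:
    """Reverse-complement a 2-bit encoded k-mer in code space."""
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


def iter_codes(seq: str, k: int):
    """Yield (forward, reverse-complement) codes of every k-mer, rolling."""
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    fwd = 0
    rc = 0
    valid = 0
    for base in seq:
        b = _CODE[base]
        fwd = ((fwd << 2) | b) & mask
        rc = (rc >> 2) | ((3 - b) << shift)
        valid += 1
        if valid >= k:
            yield fwd, rc


@dataclass
class KmerTable:
    """Global map from 2-bit k-mer code to observed count."""

    k: int = DEFAULT_K
    counts: dict[int, int] = field(default_factory=dict)
    pruned: bool = False

    def add_read(self, sequence: str) -> None:
        if len(sequence) < self.k:
            return
        counts = self.counts
        for fwd, rc in iter_codes(sequence, self.k):
            counts[fwd] = min(counts.get(fwd, 0) + 1, _SATURATE)
            counts[rc] = min(counts.get(rc, 0) + 1, _SATURATE)

    def lookup(self, code: int) -> int:
        """Stored count, or 1 for any absent (possibly pruned) k-mer."""
        return self.counts.get(code, 1)

    def prune_unique(self) -> "KmerTable":
        """Drop all count-1 entries; absent k-mers still report count 1."""
        if not self.pruned:
            self.counts = {c: n for c, n in self.counts.items() if n > 1}
            self.pruned = True
        return self

    def __len__(self) -> int:
        return len(self.counts)


def build_table(reads: Iterable, k: int = DEFAULT_K) -> KmerTable:
    """Count every k-mer occurrence and its reverse complement over reads.

    ``reads`` may be :class:`~kmerfix.read_io.ReadRecord` objects or plain
    strings.  Reads shorter than k contribute nothing.
    """
    table = KmerTable(k=validate_k(k))
    for read in reads:
        table.add_read(read if isinstance(read, str) else read.sequence)
    return table
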