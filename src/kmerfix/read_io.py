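"""FASTQ reading/writing, N preprocessing, pairing and batch streaming.

Reads are handled in Sanger Phred+33 encoding by default; Phred+64 is
available behind a flag.  Preprocessing removes leading/trailing ``N`` runs
and replaces internal ``N`` bases deterministically so that the corrector
can operate in a pure {A,C,G,T} alphabet and treat former Ns as ordinary
substitution errors.
"""

from __future__ import annotations

import gzip
import hashlib
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator

BASES = "ACGT"
_MAX_PHRED = {33: 93, 64: 62}  # printable ASCII ceiling 126


@dataclass
class ReadRecord:
    """A single sequencing read: identifier, bases and per-base Phred scores."""

    read_id: str
    sequence: str
    qualities: list[int]
    mate_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )

    def copy(self) -> "ReadRecord":
        return replace(self, qualities=list(self.qualities))


@dataclass
class Batch:
    reads: list[ReadRecord] = field(default_factory=list)
    batch_size: int = 100_000


class FastqParseError(ValueError):
    """Malformed FASTQ input; the message names the offending line."""


def _open_text(path, mode: str = "rt") -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path, phred_offset: int = 33) -> Iterator[ReadRecord]:
    """Stream :class:`ReadRecord` objects from a 4-line FASTQ file.

    Parameters
    ----------
    path:
        FASTQ file, optionally gzip-compressed (detected by ``.gz`` suffix).
    phred_offset:
        33 (Sanger, default) or 64 (legacy Illumina).
    """
    if phred_offset not in (33, 64):
        raise ValueError(f"phred_offset must be 33 or 64, got {phred_offset}")
    with _open_text(path) as handle:
        lineno = 0
        while True:
            header = handle.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise FastqParseError(
                    f"{path}: line {lineno}: expected '@' header, got {header[:40]!r}"
                )
            seq = handle.readline()
            plus = handle.readline()
            qual = handle.readline()
            if not qual:
                raise FastqParseError(
                    f"{path}: truncated record starting at line {lineno}"
                )
            lineno += 3
            if not plus.startswith("+"):
                raise FastqParseError(
                    f"{path}: line {lineno - 1}: expected '+' separator, "
                    f"got {plus[:40]!r}"
                )
            seq = seq.strip().upper()
            qual = qual.rstrip("\n")
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"{path}: line {lineno}: quality length {len(qual)} does not "
                    f"match sequence length {len(seq)}"
                )
            yield ReadRecord(
                read_id=header[1:].strip(),
                sequence=seq,
                qualities=[ord(c) - phred_offset for c in qual],
            )


def format_fastq_record(read: ReadRecord, phred_offset: int = 33) -> str:
    """One 4-line FASTQ record as text; validates quality encodability."""
    max_q = _MAX_PHRED.get(phred_offset)
    if max_q is None:
        raise ValueError(f"phred_offset must be 33 or 64, got {phred_offset}")
    for q in read.qualities:
        if not 0 <= q <= max_q:
            raise ValueError(
                f"read {read.read_id!r}: quality {q} not encodable at "
                f"offset {phred_offset}"
            )
    return (
        f"@{read.read_id}\n{read.sequence}\n+\n"
        + "".join(chr(q + phred_offset) for q in read.qualities)
        + "\n"
    )


def write_fastq(reads: Iterable[ReadRecord], path, phred_offset: int = 33) -> None:
    """Write reads as 4-line FASTQ; inverse of :func:`read_fastq`."""
    with _open_text(path, "wt") as handle:
        for read in reads:
            handle.write(format_fastq_record(read, phred_offset))


def _replacement_base(read_id: str, position: int) -> str:
    """Deterministic, approximately uniform base for an internal N.

    Keyed on (read_id, post-trim position) through a stable hash so the
    outcome is identical across processes and independent of batching.
    """
    digest = hashlib.blake2b(
        f"{read_id}:{position}".encode(), digest_size=8
    ).digest()
    return BASES[int.from_bytes(digest, "little") % 4]


def preprocess_read(read: ReadRecord) -> ReadRecord:
    """Strip leading/trailing N runs and fill internal Ns deterministically.

    Internal Ns become substitution errors from the corrector's point of
    view.  An all-N read collapses to an empty read, which downstream stages
    pass through untouched.  Idempotent.
    """
    seq = read.sequence
    if "N" not in seq:
        return read
    start = 0
    end = len(seq)
    while start < end and seq[start] == "N":
        start += 1
    while end > start and seq[end - 1] == "N":
        end -= 1
    trimmed = seq[start:end]
    quals = read.qualities[start:end]
    if "N" in trimmed:
        chars = list(trimmed)
        for i, base in enumerate(chars):
            if base == "N":
                chars[i] = _replacement_base(read.read_id, i)
        trimmed = "".join(chars)
    return ReadRecord(read.read_id, trimmed, quals, read.mate_id)


def batched(reads: Iterable[ReadRecord], batch_size: int = 100_000) -> Iterator[Batch]:
    """Group a read stream into batches; content and order are preserved."""
    if batch_size < 1:
        raise ValueError("batch_size must be positive")
    batch = Batch(batch_size=batch_size)
    for read in reads:
        batch.reads.append(read)
        if len(batch.reads) == batch_size:
            yield batch
            batch = Batch(batch_size=batch_size)
    if batch.reads:
        yield batch


def read_pairs(
    path1, path2=None, interleaved: bool = False, phred_offset: int = 33
) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    """Stream mate pairs from two parallel files or one interleaved file.

    Mates are matched by record order, never by identifier munging.
    """
    if interleaved:
        stream = read_fastq(path1, phred_offset)
        while True:
            first = next(stream, None)
            if first is None:
                return
            second = next(stream, None)
            if second is None:
                raise FastqParseError(
                    f"{path1}: odd number of records in interleaved input"
                )
            yield _link(first, second)
    else:
        if path2 is None:
            raise ValueError("read_pairs needs a second file unless interleaved")
        s1, s2 = read_fastq(path1, phred_offset), read_fastq(path2, phred_offset)
        for first in s1:
            second = next(s2, None)
            if second is None:
                raise FastqParseError(f"{path2}: fewer records than {path1}")
            yield _link(first, second)
        if next(s2, None) is not None:
            raise FastqParseError(f"{path1}: fewer records than {path2}")


def _link(a: ReadRecord, b: ReadRecord) -> tuple[ReadRecord, ReadRecord]:
    a.mate_id = b.read_id
    b.mate_id = a.read_id
    return a, b
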