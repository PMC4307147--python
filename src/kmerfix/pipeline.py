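"""Two-pass correction pipeline: count and prune, then correct each read.

Pass 1 builds the global k-mer table over every input read (after N
preprocessing) and prunes unique k-mers.  Pass 2 corrects each read
independently, applies homopolymer corrections when enabled, computes the
post-correction unique-k-mer fraction and routes each read (or pair) to
the high-information or low-information output.  Because the table is
never updated by corrections, output is independent of read order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .corrector import CorrectionConfig, CorrectionResult, correct_read
from .filtering import flag_low_information, flag_pair, read_unique_fraction
from .kmer_store import build_table
from .read_io import ReadRecord, preprocess_read, read_fastq, read_pairs

logger = logging.getLogger("kmerfix")


@dataclass
class CorrectionSummary:
    """Attempted corrections by type, mirroring the corrector's own report."""

    reads: int = 0
    bases: int = 0
    mismatches: int = 0
    insertions: int = 0  # insertion errors fixed (base deletions)
    deletions: int = 0  # deletion errors fixed (base insertions)
    homopolymers: int = 0
    reverted_reads: int = 0
    flagged_reads: int = 0
    table_size_before: int = 0
    table_size_after: int = 0

    def record_edits(self, result: CorrectionResult) -> None:
        from .corrector import EditType

        if result.reverted:
            self.reverted_reads += 1
            return
        for edit in result.edits:
            if edit.homopolymer:
                self.homopolymers += 1
            elif edit.edit_type is EditType.SUBSTITUTION:
                self.mismatches += 1
            elif edit.edit_type is EditType.DELETE_BASE:
                self.insertions += 1
            else:
                self.deletions += 1

    def format_text(self) -> str:
        return (
            f"reads\t{self.reads}\nbases\t{self.bases}\n"
            f"mismatches\t{self.mismatches}\ninsertions\t{self.insertions}\n"
            f"deletions\t{self.deletions}\nhomopolymers\t{self.homopolymers}\n"
            f"reverted_reads\t{self.reverted_reads}\n"
            f"low_information_reads\t{self.flagged_reads}\n"
        )


def correct_reads(
    reads: list[ReadRecord],
    config: CorrectionConfig | None = None,
    pairs: bool = False,
    apply_filter: bool = True,
) -> tuple[list[CorrectionResult], CorrectionSummary]:
    """Correct an in-memory read set (pairs must be interleaved mate order)."""
    config = config or CorrectionConfig()
    reads = [preprocess_read(r) for r in reads]
    table = build_table(reads, config.k)
    summary = CorrectionSummary(
        reads=len(reads),
        bases=sum(len(r.sequence) for r in reads),
        table_size_before=len(table),
    )
    table.prune_unique()
    summary.table_size_after = len(table)
    logger.info(
        "k-mer table: %d entries before pruning, %d after",
        summary.table_size_before,
        summary.table_size_after,
    )

    results = [correct_read(r, table, config) for r in reads]
    for res in results:
        summary.record_edits(res)

    if apply_filter:
        if pairs:
            for i in range(0, len(results) - 1, 2):
                a, b = results[i], results[i + 1]
                fa = read_unique_fraction(a.read, table)
                fb = read_unique_fraction(b.read, table)
                va, vb = flag_pair(fa, fb, config.filter_threshold)
                a.flagged_low_info = va.flagged
                b.flagged_low_info = vb.flagged
        else:
            for res in results:
                frac = read_unique_fraction(res.read, table)
                res.flagged_low_info = flag_low_information(
                    frac, config.filter_threshold
                ).flagged
        summary.flagged_reads = sum(r.flagged_low_info for r in results)
    return results, summary


def run_correct(
    input1,
    output_prefix: str,
    input2=None,
    interleaved: bool = False,
    config: CorrectionConfig | None = None,
    phred_offset: int = 33,
    apply_filter: bool = True,
    batch_size: int = 100_000,
) -> CorrectionSummary:
    """File-to-file correction; returns the run summary.

    Two streaming passes over the input: the first builds and prunes the
    k-mer table, the second corrects and writes.  ``batch_size`` bounds
    the output write buffer only — it can never change results.

    Single input -> ``<prefix>.corrected.fastq`` and
    ``<prefix>.low_info.fastq``.  Paired input (two files or interleaved)
    -> ``_1``/``_2`` suffixed outputs with mates kept in sync.
    """
    from .kmer_store import KmerTable, validate_k
    from .read_io import format_fastq_record

    config = config or CorrectionConfig()
    paired = input2 is not None or interleaved

    def stream():
        if paired:
            for a, b in read_pairs(input1, input2, interleaved, phred_offset):
                yield preprocess_read(a), preprocess_read(b)
        else:
            for read in read_fastq(input1, phred_offset):
                yield (preprocess_read(read),)

    summary = CorrectionSummary()
    table = KmerTable(k=validate_k(config.k))
    for group in stream():
        for read in group:
            table.add_read(read.sequence)
            summary.reads += 1
            summary.bases += len(read.sequence)
    summary.table_size_before = len(table)
    table.prune_unique()
    summary.table_size_after = len(table)
    logger.info(
        "k-mer table: %d entries before pruning, %d after",
        summary.table_size_before,
        summary.table_size_after,
    )

    suffixes = ["_1", "_2"] if paired else [""]
    handles = {
        (kind, s): open(f"{output_prefix}.{kind}{s}.fastq", "w")
        for kind in ("corrected", "low_info")
        for s in suffixes
    }
    buffers: dict[tuple[str, str], list[str]] = {key: [] for key in handles}

    def emit(kind: str, suffix: str, read: ReadRecord) -> None:
        buf = buffers[(kind, suffix)]
        buf.append(format_fastq_record(read, phred_offset))
        if len(buf) >= max(1, batch_size):
            handles[(kind, suffix)].write("".join(buf))
            buf.clear()

    try:
        for group in stream():
            results = [correct_read(r, table, config) for r in group]
            for res in results:
                summary.record_edits(res)
            if apply_filter:
                fracs = [read_unique_fraction(r.read, table) for r in results]
                if paired:
                    va, vb = flag_pair(fracs[0], fracs[1], config.filter_threshold)
                    flags = [va.flagged, vb.flagged]
                else:
                    flags = [
                        flag_low_information(fracs[0], config.filter_threshold).flagged
                    ]
                for res, flag in zip(results, flags):
                    res.flagged_low_info = flag
                summary.flagged_reads += sum(flags)
            kind = (
                "low_info"
                if results and all(r.flagged_low_info for r in results)
                and any(r.flagged_low_info for r in results)
                else "corrected"
            )
            for res, suffix in zip(results, suffixes):
                emit(kind, suffix, res.read)
        for key, buf in buffers.items():
            if buf:
                handles[key].write("".join(buf))
    finally:
        for handle in handles.values():
            handle.close()
    return summary
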