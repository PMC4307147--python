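"""Truth-based error accounting: corrected / uncorrected / introduced.

Each emitted read is compared with its error-free source sequence (known
exactly from the simulator truth) before and after correction.  Errors are
keyed by (type, source coordinate): an error present only in the
uncorrected read was *corrected*; present only in the corrected read it
was *introduced*; present in both it remains *uncorrected*.

Comparisons use a banded global alignment with unit costs and
deterministic tie-breaking (mismatch preferred over indel, then leftmost),
so results are reproducible and need no external mapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

ERROR_TYPES = ("mismatch", "insertion", "deletion")


@dataclass(frozen=True)
class Edit:
    position: int  # source (clean-sequence) coordinate
    edit_type: str  # mismatch | insertion | deletion
    bases: str


class BandExceeded(Exception):
    """Read and source diverge beyond the alignment band."""


def edit_script(read: str, source: str, band: int = 30) -> list[Edit]:
    """Minimum-unit-cost global alignment of ``read`` against ``source``.

    Returns one edit per differing position, in source coordinates:
    ``mismatch`` (read base differs), ``insertion`` (base present in the
    read only; positioned before the given source base) and ``deletion``
    (source base absent from the read).  Ties prefer mismatch over indel
    and are resolved leftmost.  Raises :class:`BandExceeded` when the two
    sequences differ in length by more than ``band``.
    """
    n, m = len(source), len(read)
    if abs(n - m) > band:
        raise BandExceeded(f"length difference {abs(n - m)} exceeds band {band}")
    if read == source:
        return []
    INF = n + m + 10
    # dp[i][j] = cost aligning source[:i] with read[:j], banded |i-j|<=band
    width = 2 * band + 1

    def col(i: int, j: int, row: list[int]) -> int:
        off = j - i + band
        if 0 <= off < width:
            return row[off]
        return INF

    prev = [INF] * width
    for j in range(max(0, 0 - 0), min(m, band) + 1):
        prev[j + band] = j  # i = 0: insert j read bases
    # choice matrix for traceback: 0=diag, 1=up (delete source), 2=left (insert)
    choices: list[list[int]] = []
    rows: list[list[int]] = [prev]
    for i in range(1, n + 1):
        cur = [INF] * width
        ch = [0] * width
        lo = max(0, i - band)
        hi = min(m, i + band)
        for j in range(lo, hi + 1):
            off = j - i + band
            best = INF
            choice = 0
            if j >= 1:
                d = col(i - 1, j - 1, rows[i - 1]) + (
                    0 if source[i - 1] == read[j - 1] else 1
                )
                if d < best:
                    best, choice = d, 0
            up = col(i - 1, j, rows[i - 1]) + 1
            if up < best:
                best, choice = up, 1
            left = col(i, j - 1, cur) + 1
            if left < best:
                best, choice = left, 2
            cur[off] = best
            ch[off] = choice
        rows.append(cur)
        choices.append(ch)
    if col(n, m, rows[n]) >= INF:
        raise BandExceeded("alignment fell outside the band")
    # traceback
    edits: list[Edit] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i == 0:
            edits.append(Edit(0, "insertion", read[j - 1]))
            j -= 1
            continue
        off = j - i + band
        if j == 0 or not (0 <= off < width):
            edits.append(Edit(i - 1, "deletion", source[i - 1]))
            i -= 1
            continue
        choice = choices[i - 1][off]
        if choice == 0:
            if source[i - 1] != read[j - 1]:
                edits.append(Edit(i - 1, "mismatch", read[j - 1]))
            i -= 1
            j -= 1
        elif choice == 1:
            edits.append(Edit(i - 1, "deletion", source[i - 1]))
            i -= 1
        else:
            edits.append(Edit(i, "insertion", read[j - 1]))
            j -= 1
    edits.reverse()
    return edits


def script_cost(edits: list[Edit]) -> int:
    return len(edits)


@dataclass
class Tally:
    corrected: dict[str, int] = field(
        default_factory=lambda: dict.fromkeys(ERROR_TYPES, 0)
    )
    uncorrected: dict[str, int] = field(
        default_factory=lambda: dict.fromkeys(ERROR_TYPES, 0)
    )
    introduced: dict[str, int] = field(
        default_factory=lambda: dict.fromkeys(ERROR_TYPES, 0)
    )
    incomparable: int = 0
    evaluated_bases: int = 0

    def add(self, other: "Tally") -> None:
        for d_self, d_other in (
            (self.corrected, other.corrected),
            (self.uncorrected, other.uncorrected),
            (self.introduced, other.introduced),
        ):
            for t in ERROR_TYPES:
                d_self[t] += d_other[t]
        self.incomparable += other.incomparable
        self.evaluated_bases += other.evaluated_bases


def classify(
    uncorrected: str, corrected: str, source: str, band: int = 30
) -> Tally:
    """Per-read corrected/uncorrected/introduced tallies against the source."""
    tally = Tally()
    try:
        before = {(e.edit_type, e.position) for e in edit_script(uncorrected, source, band)}
        after = {(e.edit_type, e.position) for e in edit_script(corrected, source, band)}
    except BandExceeded:
        tally.incomparable = 1
        return tally
    tally.evaluated_bases = len(source)
    for t, _pos in before - after:
        tally.corrected[t] += 1
    for t, _pos in before & after:
        tally.uncorrected[t] += 1
    for t, _pos in after - before:
        tally.introduced[t] += 1
    return tally


@dataclass
class EvaluationReport:
    tally: Tally

    def percent_corrected(self, error_type: str | None = None) -> float | None:
        """corrected / (corrected + uncorrected), or None when undefined."""
        types = [error_type] if error_type else list(ERROR_TYPES)
        c = sum(self.tally.corrected[t] for t in types)
        u = sum(self.tally.uncorrected[t] for t in types)
        return None if c + u == 0 else 100.0 * c / (c + u)

    def percent_introduced(self, error_type: str | None = None) -> float | None:
        """introduced relative to (corrected + uncorrected), as the tables report."""
        types = [error_type] if error_type else list(ERROR_TYPES)
        c = sum(self.tally.corrected[t] for t in types)
        u = sum(self.tally.uncorrected[t] for t in types)
        i = sum(self.tally.introduced[t] for t in types)
        return None if c + u == 0 else 100.0 * i / (c + u)

    def abundance_per_kb(self, counter: str, error_type: str) -> float | None:
        counts = getattr(self.tally, counter)[error_type]
        kb = self.tally.evaluated_bases / 1000.0
        return None if kb == 0 else counts / kb

    def to_rows(self) -> list[dict]:
        rows = []
        for t in ERROR_TYPES:
            rows.append(
                {
                    "error_type": t,
                    "corrected": self.tally.corrected[t],
                    "uncorrected": self.tally.uncorrected[t],
                    "introduced": self.tally.introduced[t],
                    "percent_corrected": self.percent_corrected(t),
                    "percent_introduced": self.percent_introduced(t),
                }
            )
        return rows

    def to_tsv(self) -> str:
        header = [
            "error_type", "corrected", "uncorrected", "introduced",
            "percent_corrected", "percent_introduced",
        ]
        lines = ["\t".join(header)]
        for row in self.to_rows():
            lines.append(
                "\t".join(
                    "n/a" if row[col] is None else str(row[col]) for col in header
                )
            )
        return "\n".join(lines) + "\n"

    def format_text(self) -> str:
        lines = [
            f"{'type':<12}{'corrected':>10}{'uncorrected':>12}{'introduced':>11}"
            f"{'% corrected':>13}{'% introduced':>14}"
        ]
        for row in self.to_rows():
            pc = "n/a" if row["percent_corrected"] is None else f"{row['percent_corrected']:.1f}"
            pi = "n/a" if row["percent_introduced"] is None else f"{row['percent_introduced']:.1f}"
            lines.append(
                f"{row['error_type']:<12}{row['corrected']:>10}"
                f"{row['uncorrected']:>12}{row['introduced']:>11}{pc:>13}{pi:>14}"
            )
        total = self.percent_corrected()
        lines.append(
            "total corrected: "
            + ("n/a" if total is None else f"{total:.1f}%")
            + f" ({self.tally.incomparable} incomparable reads)"
        )
        return "\n".join(lines)


def summarize(tallies: Iterable[Tally]) -> EvaluationReport:
    total = Tally()
    for t in tallies:
        total.add(t)
    return EvaluationReport(total)


def evaluate_readset(
    uncorrected: Sequence[str],
    corrected: Sequence[str],
    sources: Sequence[str],
    band: int = 30,
) -> EvaluationReport:
    """Classify every read triple and aggregate into a report."""
    if not (len(uncorrected) == len(corrected) == len(sources)):
        raise ValueError("read lists must have equal length")
    return summarize(
        classify(u, c, s, band) for u, c, s in zip(uncorrected, corrected, sources)
    )
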