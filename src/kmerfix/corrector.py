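"""Enumeration, evaluation and iterative application of read corrections.

The corrector works entirely from the global k-mer count table; it never
consults quality scores and never writes its corrections back into the
table, so reads are corrected independently and read order cannot change
any outcome.

At each detected error site it considers, simultaneously, all single-base
substitutions, deletions of the implicated base(s) (fixing insertion
errors) and insertions before/after the site (fixing deletion errors).  A
candidate is acceptable only if every k-mer in a small evaluation window —
anchored on the trusted region bordering the erroneous region and extending
through the k-mer containing the first base after the error — has a
strictly larger count on the edited read than on the original.  Requiring
the window to reach past the erroneous base prevents "fixing" a
substitution with an insertion, which would merely push the error down the
read.  Among acceptable candidates the winner improves the most consecutive
k-mers beyond the required window, then has the largest window count sum.

Correction repeats within a read until no correctable site remains.  If a
read accumulates more than ``max_corrections`` edits, all changes are
reverted and the original read is returned.  Adjacent (compound) errors
outside homopolymer runs are not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from itertools import product

from .kmer_store import KmerTable, encode_kmer
from .profile import (
    Direction,
    ErrorSite,
    count_profile,
    find_discontinuities,
    locate_error,
)
from .read_io import ReadRecord

_BASES = "ACGT"


class EditType(IntEnum):
    # enum order doubles as the deterministic tie-break order
    SUBSTITUTION = 0
    INSERT_BASE = 1  # fixes a deletion error
    DELETE_BASE = 2  # fixes an insertion error


@dataclass(frozen=True)
class CorrectionCandidate:
    edit_type: EditType
    position: int
    bases: str  # replacement or inserted bases; empty for deletions
    n: int = 1  # indel length (1 for substitutions)
    homopolymer: bool = False


@dataclass
class CorrectionConfig:
    k: int = 31
    abs_threshold: float = 3
    rel_threshold: float = 0.2
    max_corrections: int = 10
    max_indel: int = 3
    homopolymer: bool = True
    filter_threshold: float = 0.5
    # extension scoring is scanned at most this far beyond the window
    max_extension: int = 62


@dataclass
class CorrectionResult:
    read: ReadRecord
    edits: list[CorrectionCandidate] = field(default_factory=list)
    reverted: bool = False
    flagged_low_info: bool = False


def apply_edit(
    seq: str, quals: list[int], cand: CorrectionCandidate
) -> tuple[str, list[int]]:
    """Apply one edit and adjust qualities.

    A corrected (substituted or inserted) base takes the floor of the mean
    of the qualities of its immediate original neighbours; at a read end
    the single available neighbour is used.  Deleted bases drop their
    qualities.  All other qualities are preserved.
    """
    p = cand.position
    if cand.edit_type is EditType.SUBSTITUTION:
        neighbours = [quals[i] for i in (p - 1, p + 1) if 0 <= i < len(quals)]
        q = sum(neighbours) // len(neighbours) if neighbours else quals[p]
        return seq[:p] + cand.bases + seq[p + 1 :], quals[:p] + [q] + quals[p + 1 :]
    if cand.edit_type is EditType.INSERT_BASE:
        neighbours = [quals[i] for i in (p - 1, p) if 0 <= i < len(quals)]
        q = sum(neighbours) // len(neighbours) if neighbours else 0
        return (
            seq[:p] + cand.bases + seq[p:],
            quals[:p] + [q] * len(cand.bases) + quals[p:],
        )
    return seq[:p] + seq[p + cand.n :], quals[:p] + quals[p + cand.n :]


def enumerate_candidates(
    seq: str, site: ErrorSite, n: int, k: int
) -> list[CorrectionCandidate]:
    """All length-n candidates at a site (plus substitutions when n == 1).

    For a high-to-low discontinuity the implicated inserted bases start at
    N; for low-to-high they end at N, so deletions are enumerated on the
    matching side.  Insertions are tried both before and after N.
    """
    cands: list[CorrectionCandidate] = []
    N = site.N
    r = len(seq)
    if n == 1:
        cands.extend(
            CorrectionCandidate(EditType.SUBSTITUTION, N, b)
            for b in _BASES
            if b != seq[N]
        )
    # deletions: read must stay >= k long
    if r - n >= k:
        starts = {N} if n == 1 else (
            {N} if site.source.direction is Direction.HIGH_TO_LOW else {N - n + 1}
        )
        for s in starts:
            if 0 <= s and s + n <= r:
                cands.append(CorrectionCandidate(EditType.DELETE_BASE, s, "", n))
    # insertions before and after N
    for bases in ("".join(t) for t in product(_BASES, repeat=n)):
        for pos in (N, N + 1):
            if 0 <= pos <= r:
                cands.append(CorrectionCandidate(EditType.INSERT_BASE, pos, bases, n))
    return cands


def _count_at(seq: str, i: int, k: int, table: KmerTable) -> int:
    return table.lookup(encode_kmer(seq[i : i + k]))


def evaluate_candidate(
    seq: str,
    cand: CorrectionCandidate,
    site: ErrorSite,
    old_profile: list[int],
    table: KmerTable,
    config: CorrectionConfig,
) -> tuple[int, int] | None:
    """Score a candidate, or ``None`` if it is not acceptable.

    Only the window k-mers of the edited read are recomputed (equivalent to
    recomputing the full profile, which tests verify).  Returns
    ``(consecutive improvements beyond the window, window count sum)``.
    """
    k = config.k
    new_seq, _ = apply_edit(seq, [0] * len(seq), cand)
    if len(new_seq) < k:
        return None
    len_new = len(new_seq) - k + 1
    len_old = len(old_profile)
    shift = 0
    if cand.edit_type is EditType.INSERT_BASE:
        shift = cand.n
    elif cand.edit_type is EditType.DELETE_BASE:
        shift = -cand.n

    if site.source.direction is Direction.HIGH_TO_LOW:
        # trusted region on the left; window grows rightward from border d
        t = site.source.d
        required = [i for i in (t + 1, t + 2) if 0 <= i < len_new]
        old_of = lambda i: old_profile[min(i, len_old - 1)]
        step = 1
        start_ext = t + 3
    else:
        # trusted region on the right; window mirrored, indel-shifted
        t_new = site.source.d + 1 + shift
        required = [i for i in (t_new - 1, t_new - 2) if 0 <= i < len_new]
        old_of = lambda i: old_profile[min(max(i - shift, 0), len_old - 1)]
        step = -1
        start_ext = t_new - 3
    if not required:
        return None
    window_sum = 0
    for i in required:
        c = _count_at(new_seq, i, k, table)
        if c <= old_of(i):
            return None
        window_sum += c
    extension = 0
    i = start_ext
    while 0 <= i < len_new and extension < config.max_extension:
        if _count_at(new_seq, i, k, table) <= old_of(i):
            break
        extension += 1
        i += step
    return extension, window_sum


def _rank_key(score: tuple[int, int], cand: CorrectionCandidate):
    extension, window_sum = score
    return (-extension, -window_sum, int(cand.edit_type), cand.bases, cand.position)


def best_candidate(
    seq: str,
    site: ErrorSite,
    old_profile: list[int],
    table: KmerTable,
    config: CorrectionConfig,
) -> CorrectionCandidate | None:
    """Best acceptable candidate at a site, staged by indel length.

    Length-1 edits are tried first; longer indels are explored only when no
    shorter candidate is acceptable (a true n-base indel cannot satisfy the
    strict window under a shorter edit, so staging never changes outcomes).
    """
    for n in range(1, config.max_indel + 1):
        scored = []
        for cand in enumerate_candidates(seq, site, n, config.k):
            score = evaluate_candidate(seq, cand, site, old_profile, table, config)
            if score is not None:
                scored.append((score, cand))
        if scored:
            return min(scored, key=lambda sc: _rank_key(*sc))[1]
    return None


def correct_read(
    read: ReadRecord, table: KmerTable, config: CorrectionConfig | None = None
) -> CorrectionResult:
    """Iteratively correct one read against the global k-mer table.

    Homopolymer run-length corrections (when enabled) run only after the
    general loop has exhausted all other possibilities, since their
    forgiving acceptance rule could otherwise mistake noise for a slight
    improvement and mask the true correction.
    """
    config = config or CorrectionConfig()
    k = config.k
    if len(read.sequence) < k:
        return CorrectionResult(read=read.copy())
    seq, quals = read.sequence, list(read.qualities)
    edits: list[CorrectionCandidate] = []

    def budget_exceeded() -> bool:
        return len(edits) > config.max_corrections

    for _ in range(4 * config.max_corrections):
        prof = count_profile(seq, table)
        discs = find_discontinuities(prof, config.abs_threshold, config.rel_threshold)
        applied = False
        for disc in discs:
            site = locate_error(disc, k, len(seq))
            cand = best_candidate(seq, site, prof, table, config)
            if cand is None:
                continue
            seq, quals = apply_edit(seq, quals, cand)
            edits.append(cand)
            if budget_exceeded():
                return CorrectionResult(read=read.copy(), reverted=True)
            applied = True
            break
        if not applied:
            break

    if config.homopolymer:
        from .homopolymer import homopolymer_pass

        seq, quals, reverted = homopolymer_pass(seq, quals, table, config, edits)
        if reverted:
            return CorrectionResult(read=read.copy(), reverted=True)

    corrected = ReadRecord(read.read_id, seq, quals, read.mate_id)
    return CorrectionResult(read=corrected, edits=edits)
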