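"""Homopolymer run-length error detection and correction.

Pyrosequencing (454) and semiconductor (Ion Torrent) platforms miscall the
length of homopolymer runs.  Such errors frequently coincide across reads,
so the k-mer counts of an accurately-called run can themselves look
discontinuous and the strict window rule of the general corrector often
cannot fire.  This module therefore uses a forgiving rule: for a run of
observed length L implicated by a discontinuity it explores candidate
lengths from ceil(L/2) to 2L (a length-1 run additionally offers length 2,
since real runs of length 2 are sometimes reported as 1), rebuilds the
local sequence for each candidate and keeps the length whose evaluation
k-mers — the pairs bordering the run on either side plus every k-mer
spanning the whole run and the two bases following it — have the largest
summed count.  Ties prefer the smallest length change, then the shorter
run, so the observed length wins whenever the evidence is flat.

Homopolymer correction runs only after all other corrections have been
exhausted, and its accepted edits count against the same revert budget.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corrector import (
    CorrectionCandidate,
    CorrectionConfig,
    EditType,
    apply_edit,
)
from .kmer_store import KmerTable, encode_kmer
from .profile import Direction, ErrorSite, count_profile, find_discontinuities, locate_error


@dataclass(frozen=True)
class HomopolymerRun:
    anchor: int  # leftmost base of the run
    base: str
    length: int


def find_homopolymer_anchor(seq: str, site: ErrorSite) -> HomopolymerRun:
    """Locate the run implicated by a site.

    The scan starts at N+1 for a low-to-high discrepancy and N-1 for a
    high-to-low one (clamped to the read), walks left while bases repeat
    and returns the full run containing that start point.
    """
    start = site.N + 1 if site.source.direction is Direction.LOW_TO_HIGH else site.N - 1
    start = min(max(start, 0), len(seq) - 1)
    base = seq[start]
    anchor = start
    while anchor > 0 and seq[anchor - 1] == base:
        anchor -= 1
    end = start
    while end + 1 < len(seq) and seq[end + 1] == base:
        end += 1
    return HomopolymerRun(anchor=anchor, base=base, length=end - anchor + 1)


def candidate_lengths(L: int) -> set[int]:
    """Candidate run lengths from ceil(L/2) to 2L (L=1 -> {1, 2})."""
    if L < 1:
        raise ValueError("run length must be >= 1")
    return set(range((L + 1) // 2, 2 * L + 1))


def _subset_sum(seq: str, anchor: int, m: int, k: int, table: KmerTable) -> int:
    """Summed counts of the evaluation k-mers for a rebuilt run of length m."""
    n_kmers = len(seq) - k + 1
    if n_kmers <= 0:
        return 0
    idx: set[int] = set()
    for i in (anchor - k, anchor - k + 1, anchor + m - 1, anchor + m):
        if 0 <= i < n_kmers:
            idx.add(i)
    lo = max(0, anchor + m + 2 - k)
    hi = min(anchor, n_kmers - 1)
    idx.update(range(lo, hi + 1))
    if not idx:
        idx = {min(max(anchor, 0), n_kmers - 1)}
    return sum(table.lookup(encode_kmer(seq[i : i + k])) for i in sorted(idx))


def correct_homopolymer(
    seq: str, run: HomopolymerRun, table: KmerTable, k: int
) -> int:
    """Best run length under the forgiving subset rule (may equal ``run.length``)."""
    L = run.length
    best = (float("-inf"), 0, 0, L)
    for m in sorted(candidate_lengths(L)):
        new_seq = seq[: run.anchor] + run.base * m + seq[run.anchor + L :]
        if len(new_seq) < k:
            continue
        total = _subset_sum(new_seq, run.anchor, m, k, table)
        key = (total, -abs(m - L), -m, m)
        if key[:3] > best[:3]:
            best = key
    return best[3]


def homopolymer_pass(
    seq: str,
    quals: list[int],
    table: KmerTable,
    config: CorrectionConfig,
    edits: list[CorrectionCandidate],
) -> tuple[str, list[int], bool]:
    """Run-length correction sweep; returns (seq, quals, reverted).

    Each distinct run (identified by its base and left flank, which survive
    run-length edits) is adjusted at most once, so the sweep terminates.
    Accepted edits are appended to ``edits`` and count toward the shared
    ``max_corrections`` budget.
    """
    k = config.k
    tried: set[tuple[str, str]] = set()
    for _ in range(config.max_corrections + 1):
        prof = count_profile(seq, table)
        if prof is None:
            break
        discs = find_discontinuities(prof, config.abs_threshold, config.rel_threshold)
        applied = False
        for disc in discs:
            site = locate_error(disc, k, len(seq))
            run = find_homopolymer_anchor(seq, site)
            key = (run.base, seq[max(0, run.anchor - 12) : run.anchor])
            if key in tried:
                continue
            tried.add(key)
            m = correct_homopolymer(seq, run, table, k)
            if m == run.length:
                continue
            if m > run.length:
                cand = CorrectionCandidate(
                    EditType.INSERT_BASE,
                    run.anchor,
                    run.base * (m - run.length),
                    m - run.length,
                    homopolymer=True,
                )
            else:
                cand = CorrectionCandidate(
                    EditType.DELETE_BASE,
                    run.anchor,
                    "",
                    run.length - m,
                    homopolymer=True,
                )
            seq, quals = apply_edit(seq, quals, cand)
            edits.append(cand)
            if len(edits) > config.max_corrections:
                return seq, quals, True
            applied = True
            break
        if not applied:
            break
    return seq, quals, False
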