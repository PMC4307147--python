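"""Synthetic genomes, read sampling and platform-profiled error injection.

The simulator provides ground truth for exercising and evaluating the
corrector.  Error profiles emulate the platforms the corrector targets:

* ``miseq`` — substitution-dominated (0.1%/base substitutions, indels
  essentially absent);
* ``pgm``   — homopolymer-indel-dominated (1.5%/base indels);
* ``gs454`` — homopolymer-indel-dominated at a lower rate (0.38%/base).

Indel probability inside homopolymer runs of length >= 3 is multiplied by
a bias that grows with run length, and such indels are realised as +-1
run-length changes (occasionally +-2 for runs >= 8), matching the
observation that length-1 adjustments dominate real homopolymer errors.

Every source of randomness is seeded; error injection draws from a stream
keyed by (seed, read index) so per-read outcomes are stable under
batching.  Truth records are complete: applying them to a clean read
reproduces the observed read exactly, and inverting them recovers the
clean read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .read_io import ReadRecord

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

DEFAULT_QUALITY = 35
ERROR_QUALITY = 15


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base error rates of a sequencing platform."""

    name: str
    sub_rate: float
    indel_rate: float
    homopolymer_bias: float = 1.0

    def __post_init__(self):
        for rate in (self.sub_rate, self.indel_rate):
            if not 0 <= rate <= 0.5:
                raise ValueError("error rates must lie in [0, 0.5]")


PROFILES = {
    "miseq": ErrorProfile("miseq", sub_rate=0.001, indel_rate=0.00001),
    "pgm": ErrorProfile("pgm", sub_rate=0.002, indel_rate=0.015, homopolymer_bias=24.0),
    "gs454": ErrorProfile(
        "gs454", sub_rate=0.001, indel_rate=0.0038, homopolymer_bias=24.0
    ),
}


@dataclass(frozen=True)
class ErrorTruth:
    """One injected error, in coordinates of the error-free read."""

    read_id: str
    position: int
    error_type: str  # substitution | insertion | deletion
    original: str
    observed: str


def generate_genome(
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    repeat_length: int = 0,
    repeat_positions: tuple[int, int] | None = None,
) -> str:
    """Random genome with the requested GC fraction.

    ``repeat_length`` > 0 plants an exact two-copy repeat by copying the
    segment at ``repeat_positions[0]`` over ``repeat_positions[1]``
    (defaults: first quarter copied onto the third quarter).
    """
    if not 0 < gc < 1:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)
    genome = arr.tobytes().decode()
    if repeat_length:
        if repeat_positions is None:
            repeat_positions = (length // 4, 3 * length // 4)
        a, b = repeat_positions
        if b + repeat_length > length:
            raise ValueError("planted repeat exceeds genome")
        genome = genome[:b] + genome[a : a + repeat_length] + genome[b + repeat_length :]
    return genome


def _make_read(read_id: str, seq: str) -> ReadRecord:
    return ReadRecord(read_id, seq, [DEFAULT_QUALITY] * len(seq))


def sample_reads(
    genome: str,
    coverage: float,
    read_len: int = 150,
    seed: int = 0,
    paired: bool = False,
    insert: int = 400,
    high_copy: tuple[int, int, float] | None = None,
    id_prefix: str = "sim",
) -> list[ReadRecord]:
    """Sample error-free reads uniformly from both strands.

    ``high_copy=(start, end, extra_fold)`` layers extra coverage on one
    segment, emulating a high-copy plasmid in an otherwise uniform library.
    """
    rng = np.random.default_rng(seed)
    reads: list[ReadRecord] = []

    def _sample_region(offset: int, region: str, cov: float, tag: str) -> None:
        if len(region) < read_len:
            return
        span = len(region) - read_len + 1
        if paired and tag == "":
            n_pairs = round(cov * len(region) / (2 * read_len))
            frag_span = len(region) - insert + 1
            if frag_span < 1:
                raise ValueError("insert size exceeds region")
            starts = rng.integers(0, frag_span, size=n_pairs)
            flips = rng.random(n_pairs) < 0.5
            for i, (s, flip) in enumerate(zip(starts, flips)):
                frag = region[s : s + insert]
                r1, r2 = frag[:read_len], revcomp(frag[insert - read_len :])
                if flip:
                    r1, r2 = r2, r1
                a = _make_read(f"{id_prefix}_{i}/1", r1)
                b = _make_read(f"{id_prefix}_{i}/2", r2)
                a.mate_id, b.mate_id = b.read_id, a.read_id
                reads.extend((a, b))
        else:
            n_reads = round(cov * len(region) / read_len)
            starts = rng.integers(0, span, size=n_reads)
            flips = rng.random(n_reads) < 0.5
            for i, (s, flip) in enumerate(zip(starts, flips)):
                seq = region[s : s + read_len]
                if flip:
                    seq = revcomp(seq)
                reads.append(_make_read(f"{id_prefix}{tag}_{i}", seq))

    _sample_region(0, genome, coverage, "")
    if high_copy is not None:
        start, end, extra = high_copy
        _sample_region(start, genome[start:end], extra, "_hc")
    return reads


def _run_lengths(seq: str) -> list[int]:
    """Length of the maximal homopolymer run containing each position."""
    out = [0] * len(seq)
    i = 0
    while i < len(seq):
        j = i
        while j + 1 < len(seq) and seq[j + 1] == seq[i]:
            j += 1
        for p in range(i, j + 1):
            out[p] = j - i + 1
        i = j + 1
    return out


def inject_errors(
    reads: Sequence[ReadRecord],
    profile: ErrorProfile,
    seed: int = 0,
) -> tuple[list[ReadRecord], list[ErrorTruth]]:
    """Inject per-base substitution/indel errors; return reads plus truth."""
    out_reads: list[ReadRecord] = []
    truths: list[ErrorTruth] = []
    for index, read in enumerate(reads):
        rng = np.random.default_rng([seed, index])
        seq = read.sequence
        runs = _run_lengths(seq)
        # Bias weights concentrate indels inside homopolymer runs, growing
        # with run length, but are normalised per read so the overall indel
        # rate stays at profile.indel_rate.
        weights = [
            profile.homopolymer_bias * (1 + 0.2 * (rl - 3)) if rl >= 3 else 1.0
            for rl in runs
        ]
        norm = (sum(weights) / len(weights)) if weights else 1.0
        pieces: list[str] = []
        quals: list[int] = []
        p = 0
        while p < len(seq):
            base = seq[p]
            in_run = runs[p] >= 3
            indel_p = min(profile.indel_rate * weights[p] / norm, 0.5)
            if profile.indel_rate and rng.random() < indel_p:
                width = 1
                if in_run and runs[p] >= 8 and rng.random() < 0.2:
                    width = 2
                if rng.random() < 0.5:
                    # deletion of width bases (within the run when biased)
                    width = min(width, len(seq) - p)
                    if in_run:
                        width = min(width, runs[p] - 1) or 1
                    deleted = seq[p : p + width]
                    truths.append(
                        ErrorTruth(read.read_id, p, "deletion", deleted, "")
                    )
                    p += width
                    continue
                ins = base * width if in_run else "".join(
                    rng.choice(list(_BASES), size=width)
                )
                truths.append(ErrorTruth(read.read_id, p, "insertion", "", ins))
                pieces.append(ins)
                quals.extend([ERROR_QUALITY] * width)
                pieces.append(base)
                quals.append(read.qualities[p])
                p += 1
                continue
            if profile.sub_rate and rng.random() < profile.sub_rate:
                new = _BASES[(("ACGT".index(base)) + rng.integers(1, 4)) % 4]
                truths.append(ErrorTruth(read.read_id, p, "substitution", base, new))
                pieces.append(new)
                quals.append(ERROR_QUALITY)
                p += 1
                continue
            pieces.append(base)
            quals.append(read.qualities[p])
            p += 1
        out_reads.append(
            ReadRecord(read.read_id, "".join(pieces), quals, read.mate_id)
        )
    return out_reads, truths


def apply_truth(clean: str, truths: Iterable[ErrorTruth]) -> str:
    """Replay truth records onto a clean sequence -> observed sequence."""
    events = sorted(truths, key=lambda t: t.position)
    pieces: list[str] = []
    p = 0
    for t in events:
        pieces.append(clean[p : t.position])
        p = t.position
        if t.error_type == "substitution":
            pieces.append(t.observed)
            p += 1
        elif t.error_type == "insertion":
            pieces.append(t.observed)
        else:  # deletion
            p += len(t.original)
    pieces.append(clean[p:])
    return "".join(pieces)


def invert_truth(observed: str, truths: Iterable[ErrorTruth]) -> str:
    """Undo truth records on an observed sequence -> clean sequence."""
    events = sorted(truths, key=lambda t: t.position)
    pieces: list[str] = []
    p = 0  # position in observed
    clean_pos = 0
    for t in events:
        advance = t.position - clean_pos
        pieces.append(observed[p : p + advance])
        p += advance
        clean_pos = t.position
        if t.error_type == "substitution":
            pieces.append(t.original)
            p += 1
            clean_pos += 1
        elif t.error_type == "insertion":
            p += len(t.observed)
        else:  # deletion
            pieces.append(t.original)
            clean_pos += len(t.original)
    pieces.append(observed[p:])
    return "".join(pieces)
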