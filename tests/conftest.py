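"""Shared fixtures: seeded simulations reused across test modules.

The heavier study conditions (MiSeq-like 100 kb / 50x recovery run and the
PGM-like 30x homopolymer run) are built once per session.
"""

from __future__ import annotations

import pytest

from kmerfix import (
    CorrectionConfig,
    ErrorProfile,
    PROFILES,
    build_table,
    correct_read,
    evaluate_readset,
    generate_genome,
    inject_errors,
    sample_reads,
)


def run_pipeline(clean, observed, config):
    """Correct an observed read set in memory; returns results + table."""
    table = build_table(observed, config.k).prune_unique()
    results = [correct_read(r, table, config) for r in observed]
    return results, table


def simulate_and_correct(
    genome_len, coverage, profile, seed, config, read_len=150
):
    genome = generate_genome(genome_len, seed=seed)
    clean = sample_reads(genome, coverage, read_len, seed=seed + 1)
    observed, truths = inject_errors(clean, profile, seed=seed + 2)
    results, table = run_pipeline(clean, observed, config)
    report = evaluate_readset(
        [o.sequence for o in observed],
        [r.read.sequence for r in results],
        [c.sequence for c in clean],
    )
    return {
        "genome": genome,
        "clean": clean,
        "observed": observed,
        "truths": truths,
        "results": results,
        "table": table,
        "report": report,
    }


MISEQ_LIKE = ErrorProfile("miseq_like", sub_rate=0.003, indel_rate=0.0)


@pytest.fixture(scope="session")
def miseq_recovery():
    """100 kb genome, 50x, 150 bp reads, 0.3% substitutions, fixed seed."""
    config = CorrectionConfig(homopolymer=False)
    return simulate_and_correct(100_000, 50, MISEQ_LIKE, seed=11, config=config)


@pytest.fixture(scope="session")
def miseq_recovery_5x():
    """Same genome and error process at 5x coverage."""
    config = CorrectionConfig(homopolymer=False)
    return simulate_and_correct(100_000, 5, MISEQ_LIKE, seed=11, config=config)


@pytest.fixture(scope="session")
def pgm_recovery():
    """40 kb genome, 30x, PGM-like homopolymer-indel-dominated errors."""
    config = CorrectionConfig(homopolymer=True)
    return simulate_and_correct(40_000, 30, PROFILES["pgm"], seed=23, config=config)


@pytest.fixture(scope="session")
def small_clean_run():
    """20 kb genome, 30x error-free reads and their k-mer table (k=31)."""
    genome = generate_genome(20_000, seed=5)
    reads = sample_reads(genome, 30, 150, seed=6)
    table = build_table(reads, 31)
    return {"genome": genome, "reads": reads, "table": table}
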