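"""Candidate enumeration, window evaluation and the correction loop."""

import pytest

from kmerfix.corrector import (
    CorrectionCandidate,
    CorrectionConfig,
    EditType,
    apply_edit,
    best_candidate,
    correct_read,
    enumerate_candidates,
    evaluate_candidate,
)
from kmerfix.kmer_store import KmerTable, build_table
from kmerfix.profile import count_profile, find_discontinuities, locate_error
from kmerfix.read_io import ReadRecord
from kmerfix.simulator import generate_genome


def _flip(base):
    return "T" if base != "T" else "A"


@pytest.fixture(scope="module")
def clean_context():
    """Dense error-free tiling of a 2 kb genome: every genomic 31-mer is
    covered ~30x, so any unique error drops counts to exactly 1."""
    genome = generate_genome(2_000, seed=7)
    reads = [genome[i : i + 150] for i in range(0, 1850, 5)]
    table = build_table(reads, 31)
    return genome, table


def _mutate(read, pos, base=None):
    base = base or _flip(read[pos])
    return read[:pos] + base + read[pos + 1 :]


def _first_site(seq, table, cfg):
    prof = count_profile(seq, table)
    discs = find_discontinuities(prof, cfg.abs_threshold, cfg.rel_threshold)
    assert discs, "expected at least one discontinuity"
    return locate_error(discs[0], cfg.k, len(seq)), prof


class TestEnumerate:
    def test_substitutions_exclude_original_base(self, clean_context):
        genome, table = clean_context
        read = genome[100:250]
        site, _ = _first_site(_mutate(read, 75), table, CorrectionConfig())
        cands = enumerate_candidates(_mutate(read, 75), site, 1, 31)
        subs = [c for c in cands if c.edit_type is EditType.SUBSTITUTION]
        assert len(subs) == 3
        assert all(c.bases != _mutate(read, 75)[site.N] for c in subs)

    def test_minimum_candidate_set_size(self, clean_context):
        genome, table = clean_context
        read = _mutate(genome[100:250], 75)
        site, _ = _first_site(read, table, CorrectionConfig())
        cands = enumerate_candidates(read, site, 1, 31)
        # 3 substitutions + 1 deletion + 4 insert-before + 4 insert-after
        assert len(cands) >= 8

    def test_insertions_clipped_at_read_end(self):
        from kmerfix.profile import Direction, Discontinuity, ErrorSite

        seq = "ACGT" * 10
        site = ErrorSite(39, Discontinuity(8, Direction.HIGH_TO_LOW, (50, 1)))
        cands = enumerate_candidates(seq, site, 1, 31)
        assert all(c.position <= len(seq) for c in cands)


class TestEvaluate:
    def test_true_substitution_accepted_wrong_rejected(self, clean_context):
        genome, table = clean_context
        read = genome[400:550]
        bad = _mutate(read, 75)
        cfg = CorrectionConfig()
        site, prof = _first_site(bad, table, cfg)
        assert site.N == 75
        true_cand = CorrectionCandidate(EditType.SUBSTITUTION, 75, read[75])
        assert evaluate_candidate(bad, true_cand, site, prof, table, cfg) is not None
        for base in "ACGT":
            if base in (read[75], bad[75]):
                continue
            wrong = CorrectionCandidate(EditType.SUBSTITUTION, 75, base)
            assert evaluate_candidate(bad, wrong, site, prof, table, cfg) is None

    def test_insertion_fixing_substitution_rejected(self, clean_context):
        # an insertion would shift, not remove, the error: window k-mer
        # containing the base after N cannot improve
        genome, table = clean_context
        read = genome[400:550]
        bad = _mutate(read, 75)
        cfg = CorrectionConfig()
        site, prof = _first_site(bad, table, cfg)
        for base in "ACGT":
            for pos in (site.N, site.N + 1):
                cand = CorrectionCandidate(EditType.INSERT_BASE, pos, base)
                assert evaluate_candidate(bad, cand, site, prof, table, cfg) is None

    def test_best_candidate_is_true_base(self, clean_context):
        genome, table = clean_context
        read = genome[700:850]
        bad = _mutate(read, 60)
        cfg = CorrectionConfig()
        site, prof = _first_site(bad, table, cfg)
        cand = best_candidate(bad, site, prof, table, cfg)
        assert cand.edit_type is EditType.SUBSTITUTION
        assert cand.position == 60 and cand.bases == read[60]

    def test_window_scores_match_full_profile_recomputation(self, clean_context):
        genome, table = clean_context
        read = genome[700:850]
        bad = _mutate(read, 60)
        cfg = CorrectionConfig()
        site, prof = _first_site(bad, table, cfg)
        cand = CorrectionCandidate(EditType.SUBSTITUTION, 60, read[60])
        fixed_prof = count_profile(read, table)
        # every window index the evaluator requires must indeed improve in
        # the fully recomputed profile
        t = site.source.d
        for i in (t + 1, t + 2):
            assert fixed_prof[i] > prof[i]
        assert evaluate_candidate(bad, cand, site, prof, table, cfg) is not None


class TestCorrectRead:
    def test_single_substitution_restored(self, clean_context):
        genome, table = clean_context
        read = genome[300:450]
        rec = ReadRecord("r", _mutate(read, 80), [35] * 150)
        res = correct_read(rec, table, CorrectionConfig(homopolymer=False))
        assert res.read.sequence == read
        assert len(res.edits) == 1 and not res.reverted

    @pytest.mark.parametrize("pos", [0, 3, 74, 146, 149])
    def test_substitution_anywhere_restored(self, clean_context, pos):
        genome, table = clean_context
        read = genome[600:750]
        rec = ReadRecord("r", _mutate(read, pos), [35] * 150)
        res = correct_read(rec, table, CorrectionConfig(homopolymer=False))
        assert res.read.sequence == read

    def test_two_distant_substitutions_both_corrected(self, clean_context):
        genome, table = clean_context
        read = genome[300:450]
        bad = _mutate(_mutate(read, 30), 110)
        res = correct_read(
            ReadRecord("r", bad, [35] * 150), table, CorrectionConfig(homopolymer=False)
        )
        assert res.read.sequence == read
        assert len(res.edits) == 2

    def test_insertion_error_removed(self, clean_context):
        genome, table = clean_context
        read = genome[300:450]
        bad = read[:70] + "T" + read[70:]
        res = correct_read(
            ReadRecord("r", bad, [35] * 151), table, CorrectionConfig(homopolymer=False)
        )
        assert res.read.sequence == read[:150]

    def test_deletion_error_restored(self, clean_context):
        genome, table = clean_context
        read = genome[300:450]
        bad = read[:70] + read[71:]
        res = correct_read(
            ReadRecord("r", bad, [35] * 149), table, CorrectionConfig(homopolymer=False)
        )
        assert res.read.sequence == read  # missing base restored

    def test_flat_low_coverage_profile_unchanged(self):
        # all counts 1: low counts alone are not erroneous
        table = KmerTable(k=31)
        seq = generate_genome(150, seed=9)
        res = correct_read(ReadRecord("r", seq, [35] * 150), table)
        assert res.read.sequence == seq and res.edits == []

    def test_read_shorter_than_k_passthrough(self, clean_context):
        _, table = clean_context
        rec = ReadRecord("r", "ACGTACGT", [35] * 8)
        res = correct_read(rec, table)
        assert res.read.sequence == rec.sequence and res.edits == []

    def test_revert_when_budget_exceeded(self, clean_context):
        genome, table = clean_context
        read = genome[300:450]
        bad = read
        for p in (10, 75, 140):  # >= 2k apart: each independently correctable
            bad = _mutate(bad, p)
        cfg = CorrectionConfig(homopolymer=False, max_corrections=2)
        res = correct_read(ReadRecord("r", bad, [35] * 150), table, cfg)
        assert res.reverted
        assert res.read.sequence == bad and res.edits == []

    def test_order_independence(self, clean_context):
        genome, table = clean_context
        reads = [
            ReadRecord(f"r{i}", _mutate(genome[s : s + 150], 40 + i), [35] * 150)
            for i, s in enumerate(range(200, 1000, 100))
        ]
        cfg = CorrectionConfig(homopolymer=False)
        fwd = [correct_read(r, table, cfg).read.sequence for r in reads]
        rev = [correct_read(r, table, cfg).read.sequence for r in reversed(reads)]
        assert fwd == rev[::-1]


class TestQualityUpdate:
    def test_substitution_takes_floor_of_neighbour_mean(self):
        cand = CorrectionCandidate(EditType.SUBSTITUTION, 1, "G")
        seq, quals = apply_edit("ACA", [30, 10, 30], cand)
        assert seq == "AGA" and quals == [30, 30, 30]

    def test_floor_of_non_integer_mean(self):
        cand = CorrectionCandidate(EditType.SUBSTITUTION, 1, "G")
        _, quals = apply_edit("ACA", [20, 10, 25], cand)
        assert quals[1] == 22  # floor(22.5)

    def test_edit_at_read_start_uses_sole_right_neighbour(self):
        cand = CorrectionCandidate(EditType.SUBSTITUTION, 0, "G")
        _, quals = apply_edit("CA", [10, 33], cand)
        assert quals == [33, 33]

    def test_insert_and_delete_preserve_length_invariant(self):
        ins = CorrectionCandidate(EditType.INSERT_BASE, 2, "GT", 2)
        seq, quals = apply_edit("AACC", [10, 20, 30, 40], ins)
        assert len(seq) == len(quals) == 6
        assert quals[2:4] == [25, 25]  # mean of flanking 20 and 30
        dele = CorrectionCandidate(EditType.DELETE_BASE, 1, "", 2)
        seq, quals = apply_edit("AACC", [10, 20, 30, 40], dele)
        assert seq == "AC" and quals == [10, 40]
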