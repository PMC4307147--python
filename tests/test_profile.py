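"""Count profiles, discontinuity thresholds and error localization."""

import pytest

from kmerfix.kmer_store import KmerTable, build_table, encode_kmer
from kmerfix.profile import (
    Direction,
    Discontinuity,
    count_profile,
    find_discontinuities,
    locate_error,
    trusted_regions,
)
from kmerfix.simulator import generate_genome, revcomp


class TestCountProfile:
    def test_length_is_r_minus_k_plus_1(self, small_clean_run):
        table = small_clean_run["table"]
        read = small_clean_run["reads"][0]
        prof = count_profile(read.sequence, table)
        assert len(prof) == len(read.sequence) - 31 + 1 == 120

    def test_short_read_has_no_profile(self):
        assert count_profile("ACGT", KmerTable(k=31)) is None

    def test_absent_kmers_give_all_ones(self):
        prof = count_profile("A" * 40, KmerTable(k=31))
        assert prof == [1] * 10

    def test_covered_read_floor(self, small_clean_run):
        # error-free reads drawn at 30x should have decently covered k-mers
        table = small_clean_run["table"]
        prof = count_profile(small_clean_run["genome"][500:650], table)
        assert min(prof) >= 5

    def test_entries_match_single_lookups(self, small_clean_run):
        table = small_clean_run["table"]
        seq = small_clean_run["reads"][3].sequence
        prof = count_profile(seq, table)
        for i in (0, 17, 119):
            assert prof[i] == table.lookup(encode_kmer(seq[i : i + 31]))


class TestDiscontinuities:
    @pytest.mark.parametrize(
        "pair,flagged",
        [
            ((10, 10), False),
            ((100, 80), False),  # 20 = 20% of 100: not strictly greater
            ((100, 79), True),
            ((79, 100), True),
            ((5, 1), True),  # fixed component governs at low coverage
            ((4, 1), False),  # difference 3 not > 3
            ((1000, 900), False),  # 100 > 3 but only 10% of the larger
        ],
    )
    def test_both_threshold_components_strict(self, pair, flagged):
        discs = find_discontinuities(list(pair))
        assert bool(discs) == flagged

    def test_direction_and_counts_recorded(self):
        (disc,) = find_discontinuities([100, 79])
        assert disc.direction is Direction.HIGH_TO_LOW
        assert disc.counts == (100, 79) and disc.d == 0
        (disc,) = find_discontinuities([1, 50])
        assert disc.direction is Direction.LOW_TO_HIGH

    def test_flat_and_smooth_profiles_unflagged(self):
        assert find_discontinuities([7] * 50) == []
        smooth = [100 + i for i in range(50)]  # +1 steps: never > 3
        assert find_discontinuities(smooth) == []

    def test_percentage_component_scale_invariant(self):
        base = [100, 79]
        scaled = [1000, 790]
        assert len(find_discontinuities(base)) == len(find_discontinuities(scaled)) == 1


class TestLocateError:
    def test_high_to_low_site_is_d_plus_k(self):
        disc = Discontinuity(10, Direction.HIGH_TO_LOW, (50, 1))
        assert locate_error(disc, k=31, read_length=150).N == 41

    def test_low_to_high_site_is_d(self):
        disc = Discontinuity(10, Direction.LOW_TO_HIGH, (1, 50))
        assert locate_error(disc, k=31, read_length=150).N == 10

    def test_high_to_low_clamped_to_read_end(self):
        disc = Discontinuity(118, Direction.HIGH_TO_LOW, (50, 1))
        assert locate_error(disc, k=31, read_length=150).N == 149


@pytest.fixture(scope="module")
def setting():
    genome = generate_genome(2_000, seed=42)
    reads = [genome[i : i + 150] for i in range(0, 1850, 10)]
    table = build_table(reads, 31)
    held_out = genome[900:1050]
    return table, held_out


class TestPerturbationIdentities:
    """A unique error in otherwise-unique context perturbs a known number
    of profile entries: k for a substitution, k+n-1 for an insertion, k-n
    for a deletion, and only p entries when p < k bases from the 3' end."""

    @staticmethod
    def _perturbed(table, clean, mutated):
        a = count_profile(clean, table)
        b = count_profile(mutated, table)
        assert len(a) == len(b)
        return sum(x != y for x, y in zip(a, b))

    @staticmethod
    def _flip(base):
        return "T" if base != "T" else "A"

    def test_midread_substitution_perturbs_k_entries(self, setting):
        table, read = setting
        mutated = read[:75] + self._flip(read[75]) + read[76:]
        assert self._perturbed(table, read, mutated) == 31

    def test_substitution_4_from_3prime_end_perturbs_4(self, setting):
        table, read = setting
        p = len(read) - 4
        mutated = read[:p] + self._flip(read[p]) + read[p + 1 :]
        assert self._perturbed(table, read, mutated) == 4

    @staticmethod
    def _novel(table, seq):
        """Entries whose k-mer is unsupported by the read set (count 1)."""
        return sum(c == 1 for c in count_profile(seq, table))

    def test_clean_read_has_no_novel_kmers(self, setting):
        table, read = setting
        assert self._novel(table, read) == 0

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_insertion_perturbs_k_plus_n_minus_1(self, setting, n):
        # exactly the k+n-1 k-mers containing an inserted base are corrupted
        table, read = setting
        mutated = read[:75] + "T" * n + read[75:]
        assert self._novel(table, mutated) == 31 + n - 1

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_deletion_perturbs_k_minus_n(self, setting, n):
        table, read = setting
        mutated = read[:75] + read[75 + n :]
        assert self._novel(table, mutated) == 31 - n

    def test_error_free_sampled_read_is_smooth(self, setting):
        table, read = setting
        assert find_discontinuities(count_profile(read, table)) == []


class TestTrustedRegions:
    def test_no_discontinuities_single_interval(self):
        assert trusted_regions(120, []) == [(0, 120)]

    def test_single_discontinuity_splits_at_d(self):
        disc = Discontinuity(40, Direction.HIGH_TO_LOW, (50, 1))
        assert trusted_regions(120, [disc]) == [(0, 41), (41, 120)]

    def test_every_pair_flagged_yields_empty(self):
        discs = [
            Discontinuity(d, Direction.HIGH_TO_LOW, (50, 1)) for d in range(4)
        ]
        assert trusted_regions(5, discs) == []

    def test_all_unique_read_is_one_flat_region(self):
        prof = [1] * 90
        assert trusted_regions(90, find_discontinuities(prof)) == [(0, 90)]
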