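"""Correct a single substitution error in one read, step by step.

Builds a small read set over a random genome, plants one substitution in
a held-out read and walks through the stages the corrector uses: count
profile, discontinuity detection, site localization and candidate
evaluation.
"""

from kmerfix import build_table, correct_read, count_profile, find_discontinuities
from kmerfix.read_io import ReadRecord
from kmerfix.simulator import generate_genome, sample_reads

genome = generate_genome(10_000, seed=1)
reads = sample_reads(genome, 30, 150, seed=2)
table = build_table(reads, 31)
table.prune_unique()

read = genome[4_000:4_150]
bad = read[:75] + ("A" if read[75] != "A" else "G") + read[76:]

profile = count_profile(bad, table)
discs = find_discontinuities(profile)
print(f"profile has {len(profile)} entries; counts around the error:")
print("  ", profile[40:50], "...", profile[73:78], "...", profile[100:105])
print(f"discontinuities at pair indices: {[d.d for d in discs]} "
      f"({[d.direction.value for d in discs]})")
# The high-to-low step at d implicates base N = d + k; the low count region
# spans exactly the k-mers containing the wrong base.

result = correct_read(ReadRecord("demo", bad, [35] * 150), table)
print(f"applied edits: {[(e.edit_type.name, e.position, e.bases) for e in result.edits]}")
print(f"restored the true sequence: {result.read.sequence == read}")
# Expected: one SUBSTITUTION edit at position 75 restoring the planted base.
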