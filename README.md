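# kmerfix

Platform-independent error correction for second-generation sequencing
reads, with a seeded read simulator and a truth-based evaluation harness.

Illumina instruments mostly miscall single bases (substitutions); Ion
Torrent and Roche 454 instruments mostly miscall the lengths of
homopolymer runs (insertions/deletions of the repeated base). `kmerfix`
corrects substitution, insertion, deletion and homopolymer errors in any
of these read types without using quality scores or a reference genome,
and remains conservative in low-coverage and mixed-coverage data. It is
aimed at people preparing reads for de novo assembly or reference-free
analyses such as metagenomics.

## Method

Every k-mer (default k = 31, the longest odd k that fits a 64-bit word
at two bits per base) observed in the read set — and its reverse
complement, as a separate entry — is counted in a single hash table.
Unique k-mers are then pruned, and any absent k-mer is reported with
count 1.

A read of length *r* yields a count profile of *r* − *k* + 1 entries,
entry *i* being the count of the k-mer left-anchored at position *i*.
An error-free read has a profile that drifts smoothly with local
coverage; a sequencing error unique in the read set drops a block of
entries to 1. Low counts alone are never treated as errors — only
*discontinuities*: adjacent entries (c_d, c_{d+1}) whose difference is
both **greater than 3** and **greater than 20% of the larger count**.
The implicated base is *N* = *d* for a low-to-high step and
*N* = *d* + *k* for a high-to-low step.

At each site all single-base substitutions, deletions and insertions
(and short multi-base indels) are considered. A candidate is accepted
only if every k-mer in an evaluation window — anchored on the trusted
(discontinuity-free) region bordering the error and extending through
the k-mer containing the base after *N* — strictly improves, which
prevents "fixing" a substitution with an insertion and pushing the error
down the read. Correction repeats until nothing correctable remains;
reads needing too many edits are reverted. Homopolymer run lengths are
corrected last by a more forgiving rule that picks the candidate length
(from half to double the observed length) maximizing the counts of the
k-mers around and across the run. After correction, reads whose profile
is more than 50% unique k-mers are routed to a separate low-information
output (for pairs, only when both mates qualify).

## Worked example

```sh
kmerfix simulate --length 15000 --coverage 25 --profile miseq --seed 3 -o run
kmerfix correct -i run.fastq -o out --no-homopolymer
kmerfix evaluate -u run.fastq -c out.corrected.fastq -c out.low_info.fastq \
    --truth run.truth.tsv
```

which prints:

```
simulated 2500 reads (miseq), 351 injected errors -> run.*
...
type         corrected uncorrected introduced  % corrected  % introduced
mismatch           346           0          0        100.0           0.0
insertion            2           0          0        100.0           0.0
deletion             3           0          0        100.0           0.0
total corrected: 100.0% (0 incomparable reads)
```

`% corrected` is the share of injected errors of each type no longer
present after correction; `% introduced` counts new errors relative to
the same denominator. The same loop is available from Python — see
`examples/simulate_correct_evaluate.py`, which runs the PGM-like
homopolymer-dominated profile and prints, for 4,000 reads carrying
10,260 injected errors (1.71%/base), a total of 94.8% corrected with
~2% introduced.

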