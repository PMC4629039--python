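# Methods

## Scoring model

Local alignment scores are computed with the affine-gap Gotoh
recurrence: `H(i,j) = max(H(i-1,j-1) + S_ij, E(i,j), F(i,j), 0)`, where
`E`/`F` track gaps in the subject/query respectively,
`E(i,j) = max(E(i,j-1) - Ge, H(i,j-1) - Gs - Ge)` and symmetrically for
`F`. Boundary conditions are `H(i,0) = H(0,j) = 0` with `E`, `F` at
effective negative infinity; the reported score is the maximum `H` over
the whole matrix, floored at 0. A gap of length `k` costs `Gs + k*Ge`,
so the first gap column already pays `Gs + Ge`. A simpler recurrence
that drops the `-Ge` term from the gap-continuation branch is sometimes
seen in print; it would make gap length free after opening and
contradicts the `Gs + k*Ge` cost model, so the standard Gotoh form is
used. All arithmetic is integer; there is no floating point in the DP
and no traceback — the contract is score-only.

Defaults are BLOSUM62 with `Gs = 10`, `Ge = 2` (conventional
SSEARCH-style settings); matrix and penalties are fully configurable.
Substitution matrices are read from the NCBI flat format (`#` comments,
residue header row, labeled integer rows); parsing validates symmetry
and rectangular shape and reports the offending line. Scores are also
exposed as a dense 128x128 table indexed by character codes so the
inner loop does no hashing.

### Row-staged variant

`sw_score_row_staged` computes each row in two passes: pass one takes
the diagonal term, the vertical-gap state `F` and the 0 floor — all
functions of the previous row, hence vectorizable with no intra-row
dependence — and pass two sweeps left-to-right folding in the
horizontal-gap state `E`. The split is exact, not approximate: `E` only
depends on finalized cells to its left and can only raise `H`, so the
variant returns bit-identical scores to the reference DP (property-
tested on random pairs up to length 200). This mirrors how
row-synchronous parallel implementations organize the work; here it is
also simply the faster CPU route, and `batch_scores` uses it.

### Enumeration oracle

`sw_score_bruteforce` maximizes over all monotone sets of aligned
residue pairs; unaligned residues between consecutive pairs form gap
runs costing `Gs + len*Ge` each (two runs when both sequences
contribute). Because gap penalties are non-negative, optimal local
alignments start and end on aligned pairs, so this enumeration covers
all substring pairs and all gapped alignments between them. It is
exponential and refuses inputs longer than 10 residues; it exists as an
independent test oracle, never as a production path. A second
independent check in the test suite compares against Biopython's
`PairwiseAligner` on longer random pairs.

## Filtration model

A sequence's frequency vector counts each alphabet residue. The default
frequency distance is the max-of-signed-sums form
`FD = max(sum_r (fu-fv)^+, sum_r (fv-fu)^+)`. Each single edit
(substitution, insertion or deletion) changes either signed sum by at
most 1, giving the lower bound `FD <= ED` that makes filtering lossless.
The plain L1 form (`sum_r |fu-fv|`) is retained behind
`fd_definition="l1"` for comparison but is *not* a valid bound — one
substitution yields L1 = 2 against ED = 1 — and can reject true
positives at tight thresholds; this is demonstrated in the tests.

The user threshold is a sequence identity `theta in [0,1]`. For a
length-`L` query it converts to an edit budget
`ed_bound = floor((1-theta)*L)` (a sequence at identity >= theta
differs in at most that many positions). A small epsilon guards the
floor against binary-float artifacts (`(1-0.9)*1030` evaluates to
`102.999...`). Database sequences with `FD <= ed_bound` are selected;
ties at the bound pass. Sequences strictly longer than the query are
always selected (`length_exempt`) with no FD computed: their
composition difference reflects length, yet they may contain a
high-identity local match, so filtering them would risk false
negatives. Equal-length sequences are filtered normally. The filter is
vectorized over the precomputed count matrix of the whole database; at
n = 10,000 it runs in milliseconds.

## Database index

`build_index` sorts sequences by length ascending (ties by id, making
the build a pure function of the input multiset) and precomputes the
count matrix. The sidecar format is a single plain-text file: header
lines carrying format version, alphabet, entry count and a SHA-256
checksum of the body, then one tab-separated row per entry
(`id, length, counts..., sequence`). Keeping the residues in the same
file (rather than a FASTA alongside) makes the index self-contained:
one artifact to checksum, copy and diff. Load verifies version, count
and checksum and fails loudly on any mismatch.

The default residue alphabet for databases and filtration is the 20
standard amino acids plus the B/X/Z ambiguity codes (23 letters, all
scored by BLOSUM62). Internally positions are 0-based; residue
positions in error messages are 1-based, per bioinformatics convention.

## Synthetic benchmark

The generator emulates a controlled mutation study: one query (by
default a uniform random protein over the 20 standard residues; the
acceptance run uses length 1028) and `n` equal-length mutants stratified
into ten mutation deciles with exactly `n/10` sequences each. A
decile-`d` mutant draws `t` uniformly from the inclusive integer
interval `[floor(L*d/10), floor(L*(d+1)/10)]` (adjacent deciles share a
boundary value) and substitutes `t` distinct uniformly-chosen positions.

Mutated positions are rewritten to a uniformly chosen B/X/Z ambiguity
residue — i.e. to a residue from *outside* the standard alphabet —
rather than to another standard residue. This is deliberate and is what
makes the benchmark measure the threshold arithmetic: substitutions
within a 20-letter alphabet largely cancel in composition (an A→C here
offsets a C→A there), so FD concentrates near `sqrt(t)` rather than `t`
and the filter would admit ~99% of sequences even at threshold 0.90,
telling you nothing about the threshold. Out-of-alphabet targets never
cancel, so FD equals the Hamming distance `t` exactly, and the selected
ratio at threshold `theta` becomes `100 * P(t <= floor((1-theta)L))` —
approximately `100(1-theta)%`, slightly above it because the
decile-`d+1` draws that land exactly on the budget also pass. B/X/Z are
chosen because they are real IUPAC codes with BLOSUM62 scores, so the
mutants stay alignable end to end. With three target symbols and a
standard-residue query the FD = t identity is exact (verified in the
tests).

What the generator does **not** emulate: indels (mutants are
substitution-only and length-preserving), realistic residue composition
(queries are uniform i.i.d.), length variation within the database
(lengths are equal by design so the length exemption stays out of the
measurement), and homologous-family structure. Passing the benchmark
therefore demonstrates the filter's threshold-to-budget arithmetic and
losslessness guarantees, not its selectivity on real proteomes — on
real data, where substitutions do cancel in composition, the filter is
conservative: it never loses a true positive (the FD <= ED bound holds
regardless), but it rejects fewer sequences than the benchmark's 90%.

## Pipeline

`run_search` filters first, then dispatches the selected sequences for
alignment in batches (`batch_size`, default 1000) across `workers`
threads. Batching and worker count are throughput knobs with a hard
correctness contract — output is byte-identical to the sequential run —
enforced by tests. Output rows are sorted by score descending, ties by
database id; filtered-out sequences appear (score `NA`) only with
`emit_filtered`. The CLI (`fdsw index/search/simulate/bench`) is a thin
wrapper; a plain `key=value` config file can hold defaults, with flags
winning.

Invalid residues are a hard error naming the sequence and 1-based
position; `batch_scores(..., on_invalid="skip")` downgrades to a
per-sequence skip with a logged warning.

## Problem sizes and determinism

The shipped acceptance run uses the study-scale configuration: query
length 1028, 10,000 database sequences (1,000 per decile), threshold
0.90 — about 6 s end to end. The test suite exercises the same
machinery at a mix of scales (up to n = 40,000 for the occupancy check
and lengths up to 200 for alignment equivalences). All randomness flows
through a single seeded `numpy` generator per run; identical seeds give
identical databases, reports and JSON output.

## Known limitations

- The filter's usefulness degrades when the query is short relative to
  the database (most sequences become length-exempt) or the threshold
  is loose — both regimes select nearly everything, by design.
- Composition filtering cannot be applied to database sequences longer
  than the query without risking false negatives; no windowed variant
  is attempted.
- Absolute SW scores depend on the matrix and gap penalties; the
  benchmark's filtration ratios do not, but no published score values
  exist to compare against.
- The alignment kernels are pure Python/numpy and are meant for
  correctness and desk-scale studies, not GCUPS-class throughput.
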