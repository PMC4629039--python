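# fdsw — filtered Smith-Waterman protein database search

`fdsw` searches a protein database with the Smith-Waterman local
alignment algorithm (affine gaps, score only) and uses a
**frequency-distance filtration** step to discard, before any alignment
is computed, database sequences that provably cannot reach a user-chosen
sequence identity to the query. It is aimed at people running exhaustive
similarity searches against large single-organism or synthetic protein
collections who want exact SW scores but not the cost of aligning
everything.

## The method

**Alignment.** For sequences $S_1, S_2$ the local similarity score is the
maximum over all cells of the Gotoh dynamic program

$$
\begin{aligned}
E(i,j) &= \max\bigl(E(i,j-1) - G_e,\; H(i,j-1) - G_s - G_e\bigr)\\
F(i,j) &= \max\bigl(F(i-1,j) - G_e,\; H(i-1,j) - G_s - G_e\bigr)\\
H(i,j) &= \max\bigl(H(i-1,j-1) + S_{ij},\; E(i,j),\; F(i,j),\; 0\bigr)
\end{aligned}
$$

with substitution scores $S_{ij}$ (BLOSUM62 by default) and a gap of
length $k$ costing $G_s + kG_e$. Three equivalent implementations are
provided: a reference cell-by-cell DP, a row-staged two-pass variant in
which each row is first computed from the previous row only (vectorized)
and then corrected left-to-right for the horizontal gap state, and a
brute-force enumeration oracle for tiny inputs used in testing.

**Filtration.** Each sequence $s$ is summarized by its frequency vector
$f_s = (\alpha_1, \dots, \alpha_n)$ of per-residue counts. The frequency
distance

$$
\mathrm{FD}(f_u, f_v) = \max\Bigl(\sum_r (f_u[r]-f_v[r])^+,\;
\sum_r (f_v[r]-f_u[r])^+\Bigr)
$$

changes by at most 1 per edit, so $\mathrm{FD} \le \mathrm{ED}(u,v)$.
An identity threshold $\theta$ on a length-$L$ query therefore implies
an edit budget $\lfloor (1-\theta) L \rfloor$: any database sequence
whose FD to the query exceeds it is rejected without alignment, with
zero false negatives. Sequences **longer** than the query are exempt
(they may contain a high-identity local match despite a divergent
overall composition) and always proceed to alignment.

**Benchmark generator.** A built-in simulator produces the calibration
database: equal-length mutants of a query, stratified into ten mutation
deciles (a decile-$d$ mutant carries $t$ substitutions, $t$ uniform in
$[\lfloor Ld/10\rfloor, \lfloor L(d{+}1)/10\rfloor]$), with mutated
positions rewritten to B/X/Z ambiguity residues so that FD equals the
mutation count exactly. On this database the selected ratio at threshold
$\theta$ tracks $100(1-\theta)\%$.

## Worked example

```sh
fdsw simulate --length 1028 --n 10000 --seed 1 --out db.fa --query-out query.fa
fdsw index --fasta db.fa --out db.idx
fdsw bench --db db.idx --query query.fa --thresholds 0.5,0.6,0.7,0.8,0.9
```

prints

```
threshold	ratio_percent
0.5	50.0700
0.6	40.0800
0.7	30.1600
0.8	20.1600
0.9	10.0900
```

i.e. at identity 0.90 only 10.09% of the 10,000 database sequences pass
the filter — the 0–10% mutation decile plus the handful of next-decile
draws that land exactly on the 102-edit budget — so roughly 90% of the
SW alignments are skipped with no loss. A subsequent
`fdsw search --query query.fa --db db.idx --identity 0.9 --output hits.tsv`
aligns only the selected sequences and writes them ranked by SW score.

The same flows are available as library calls; see `examples/` for
short narrative scripts (single-pair scoring, database filtration, the
threshold sweep, and the end-to-end search).

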