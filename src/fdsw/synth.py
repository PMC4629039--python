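"""Synthetic mutated-database generation and the filtration-ratio sweep.

Real protein databases mix lengths, which entangles the filter's
selectivity with the length exemption. The benchmark here isolates the
composition filter: a single query of length L and a database of
equal-length sequences derived from it by a controlled number of point
substitutions. Mutation loads are stratified into ten deciles of the
query length — a sequence in decile d carries t substitutions with t
drawn uniformly from [floor(L*d/10), floor(L*(d+1)/10)] — with equal
occupancy per decile. At identity threshold theta only sequences whose
edit distance can be at most floor((1-theta)*L) should survive, so the
expected selected ratio tracks 100*(1-theta)% on such a database.

Mutated positions are rewritten to residues from outside the query's
standard 20-letter alphabet: each substitution puts a uniformly chosen
IUPAC ambiguity code (B, X or Z) at the position. Substitutions into
the standard alphabet would partially cancel in composition (an A->C
here offsets a C->A there), collapsing the frequency distance to far
below the Hamming distance and defeating the calibration; out-of-
alphabet targets make the frequency distance equal the drawn mutation
count t exactly, so the selected ratio measures the threshold-to-bound
arithmetic and nothing else. B/X/Z carry BLOSUM62 scores, so the
mutants remain alignable end to end.
"""

from __future__ import annotations

import numpy as np

from dataclasses import dataclass

from .errors import ValidationError
from .filtration import FiltrationConfig, apply_fdfs, frequency_vector
from .seqdb import (
    AMBIGUITY_RESIDUES,
    PROTEIN_ALPHABET,
    PreprocessedDatabase,
    ProteinSequence,
)


def random_protein(length: int, rng: np.random.Generator,
                   seq_id: str = "query",
                   alphabet: str = PROTEIN_ALPHABET) -> ProteinSequence:
    """Uniform i.i.d. random protein of the given length."""
    if length < 1:
        raise ValidationError(f"length must be >= 1, got {length}")
    letters = np.frombuffer(alphabet.encode(), dtype=np.uint8)
    residues = rng.choice(letters, size=length).tobytes().decode()
    return ProteinSequence(seq_id, residues)


def extract_subsequence(seq: ProteinSequence, length: int,
                        rng: np.random.Generator) -> ProteinSequence:
    """Contiguous subsequence of the given length at a uniform start."""
    if length < 1 or length > len(seq):
        raise ValidationError(
            f"subsequence length must be in [1, {len(seq)}], got {length}"
        )
    start = int(rng.integers(0, len(seq) - length + 1))
    return ProteinSequence(
        f"{seq.id}_sub{length}", seq.residues[start : start + length]
    )


def decile_bounds(query_length: int, decile: int) -> tuple[int, int]:
    """Inclusive mutation-count interval for a decile of the query length."""
    if not 0 <= decile <= 9:
        raise ValidationError(f"decile must be in 0..9, got {decile}")
    lo = query_length * decile // 10
    hi = query_length * (decile + 1) // 10
    return lo, hi


def mutate_sequence(query: ProteinSequence, decile: int,
                    rng: np.random.Generator,
                    seq_id: str | None = None,
                    targets: str = AMBIGUITY_RESIDUES) -> ProteinSequence:
    """Apply a decile-drawn number of point substitutions to the query.

    t is uniform over the decile's inclusive bounds; t distinct positions
    are chosen uniformly and each residue there is replaced by a
    uniformly chosen *different* residue from ``targets`` (default: the
    B/X/Z ambiguity codes, outside the standard alphabet so the
    substitutions never cancel in composition). The result has Hamming
    distance exactly t to the query and the same length.
    """
    if len(query) < 10:
        raise ValidationError("query must have length >= 10")
    lo, hi = decile_bounds(len(query), decile)
    t = int(rng.integers(lo, hi + 1))
    positions = rng.choice(len(query), size=t, replace=False)
    residues = list(query.residues)
    for pos in positions:
        pool = targets.replace(residues[pos], "")
        if not pool:
            raise ValidationError(
                f"no substitution target differs from {residues[pos]!r}"
            )
        residues[pos] = pool[int(rng.integers(0, len(pool)))]
    return ProteinSequence(seq_id or f"d{decile}_mut", "".join(residues))


def generate_database(query: ProteinSequence, n_sequences: int,
                      rng: np.random.Generator,
                      targets: str = AMBIGUITY_RESIDUES) -> list[ProteinSequence]:
    """Equal-occupancy decile-mutation database of ``n_sequences``.

    n_sequences must be divisible by 10; n/10 sequences are generated
    per decile, in decile order, with ids ``d{decile}_{index}``.
    """
    if n_sequences < 10 or n_sequences % 10:
        raise ValidationError(
            f"n_sequences must be a positive multiple of 10, got {n_sequences}"
        )
    per = n_sequences // 10
    out: list[ProteinSequence] = []
    for decile in range(10):
        for i in range(per):
            out.append(
                mutate_sequence(query, decile, rng,
                                seq_id=f"d{decile}_{i}", targets=targets)
            )
    return out


@dataclass(frozen=True)
class RatioCurve:
    """Selected-ratio (%) as a function of the identity threshold."""

    thresholds: tuple[float, ...]
    ratios: tuple[float, ...]


def filtration_ratio_curve(db_index: PreprocessedDatabase,
                           query: ProteinSequence,
                           thresholds,
                           fd_definition: str = "max_signed_sums") -> RatioCurve:
    """Sweep identity thresholds and record the selected ratio at each.

    Thresholds must be sorted ascending; the resulting ratios are
    checked to be non-increasing (they must be, since raising the
    threshold only shrinks the edit-distance budget).
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValidationError("thresholds must be sorted ascending")
    qfv = frequency_vector(query, db_index.alphabet)
    ratios = []
    for theta in thresholds:
        cfg = FiltrationConfig(identity_threshold=theta,
                               fd_definition=fd_definition)
        result = apply_fdfs(qfv, len(query), db_index, cfg)
        ratios.append(result.ratio)
    for lo, hi in zip(ratios[1:], ratios[:-1]):
        if lo > hi + 1e-12:
            raise RuntimeError(
                "ratio curve is not non-increasing; filtration invariant broken"
            )
    return RatioCurve(tuple(thresholds), tuple(ratios))
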