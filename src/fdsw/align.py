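"""Score-only Smith-Waterman local alignment with affine gaps.

Three routes to the same number:

* :func:`sw_score` — the reference cell-by-cell Gotoh recurrence. A gap
  of length k costs ``gap_open + k * gap_extend``; the local-alignment
  floor clamps every H cell at 0 and the reported score is the maximum
  H over the whole matrix. No traceback is kept.
* :func:`sw_score_row_staged` — a row-staged variant that computes each
  row in two passes: a vectorizable pass using only the previous row
  (diagonal term, vertical-gap state, 0), then a left-to-right sweep
  folding in the horizontal-gap state. This mirrors how row-synchronous
  parallel implementations split the work, and returns bit-identical
  scores.
* :func:`sw_score_bruteforce` — an enumeration oracle for tiny inputs.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import AlphabetError, OracleSizeError, ValidationError
from .matrices import INVALID_SCORE, SubstitutionMatrix
from .seqdb import ProteinSequence

log = logging.getLogger(__name__)

_NEG = -(10**9)  # effective -infinity for the E/F gap states


@dataclass(frozen=True)
class AlignmentParams:
    """Affine gap penalties: a length-k gap costs gap_open + k*gap_extend."""

    gap_open: int = 10
    gap_extend: int = 2

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValidationError(
                f"gap penalties must be non-negative, got "
                f"gap_open={self.gap_open}, gap_extend={self.gap_extend}"
            )


def _residues(seq) -> tuple[str, str]:
    if isinstance(seq, ProteinSequence):
        return seq.id, seq.residues
    return "<anonymous>", str(seq).upper()


def _check_alphabet(seq_id: str, residues: str, matrix: SubstitutionMatrix) -> None:
    for pos, ch in enumerate(residues, start=1):
        if not matrix.is_valid_residue(ch):
            raise AlphabetError(
                f"sequence {seq_id!r}: residue {ch!r} at position {pos} "
                f"is not in the matrix alphabet"
            )


def sw_score(seq1, seq2, matrix: SubstitutionMatrix,
             params: AlignmentParams = AlignmentParams()) -> int:
    """Reference affine-gap local alignment score (Gotoh recurrence).

    H(i,j) = max(H(i-1,j-1) + S_ij, E(i,j), F(i,j), 0) with
    E(i,j) = max(E(i,j-1) - Ge, H(i,j-1) - Gs - Ge) and the symmetric F;
    boundaries H(i,0) = H(0,j) = 0 and E, F at -infinity. Integer
    arithmetic throughout.
    """
    id1, s1 = _residues(seq1)
    id2, s2 = _residues(seq2)
    _check_alphabet(id1, s1, matrix)
    _check_alphabet(id2, s2, matrix)
    n2 = len(s2)
    if not s1 or not s2:
        return 0
    gs, ge = params.gap_open, params.gap_extend
    open_cost = gs + ge
    score = matrix.scores
    prev_h = [0] * (n2 + 1)
    prev_f = [_NEG] * (n2 + 1)
    best = 0
    for a in s1:
        h = [0] * (n2 + 1)
        f = [_NEG] * (n2 + 1)
        e = _NEG
        for j in range(1, n2 + 1):
            e = max(e - ge, h[j - 1] - open_cost)
            fij = max(prev_f[j] - ge, prev_h[j] - open_cost)
            hij = prev_h[j - 1] + score[(a, s2[j - 1])]
            if e > hij:
                hij = e
            if fij > hij:
                hij = fij
            if hij < 0:
                hij = 0
            h[j] = hij
            f[j] = fij
            if hij > best:
                best = hij
        prev_h, prev_f = h, f
    return best


def sw_score_row_staged(seq1, seq2, matrix: SubstitutionMatrix,
                        params: AlignmentParams = AlignmentParams()) -> int:
    """Row-staged Smith-Waterman: identical score to :func:`sw_score`.

    Stage 1 computes every cell of a row from the previous row only
    (diagonal term, F state, 0) with no intra-row dependence, so it
    vectorizes across the row. Stage 2 sweeps left-to-right once to fold
    in the E (horizontal gap) state. Equivalence with the single-pass
    recurrence holds because E only ever raises H and depends on cells
    to the left that stage 2 has already finalized.
    """
    id1, s1 = _residues(seq1)
    id2, s2 = _residues(seq2)
    _check_alphabet(id1, s1, matrix)
    _check_alphabet(id2, s2, matrix)
    if not s1 or not s2:
        return 0
    gs, ge = params.gap_open, params.gap_extend
    open_cost = gs + ge
    n2 = len(s2)
    codes2 = matrix.encode(s2).astype(np.intp)
    lookup = matrix.ascii_lookup.astype(np.int64)
    prev_h = np.zeros(n2 + 1, dtype=np.int64)
    prev_f = np.full(n2 + 1, _NEG, dtype=np.int64)
    best = 0
    for a in s1:
        srow = lookup[ord(a), codes2]  # S_ij across the row
        # stage 1: diagonal + F + 0, vectorized (previous row only)
        f = np.maximum(prev_f[1:] - ge, prev_h[1:] - open_cost)
        h_mid = np.maximum(np.maximum(prev_h[:-1] + srow, f), 0)
        # stage 2: left-to-right correction with the E state
        h = np.zeros(n2 + 1, dtype=np.int64)
        hm = h_mid.tolist()
        out = h[1:]
        e = _NEG
        left = 0
        for j, mid in enumerate(hm):
            e = max(e - ge, left - open_cost)
            left = mid if mid >= e else e
            out[j] = left
        row_best = int(out.max(initial=0))
        if row_best > best:
            best = row_best
        prev_h = h
        prev_f = np.concatenate(([np.int64(_NEG)], f))
    return int(best)


def sw_score_bruteforce(seq1, seq2, matrix: SubstitutionMatrix,
                        params: AlignmentParams = AlignmentParams(),
                        max_len: int = 10) -> int:
    """Enumeration oracle: best local alignment score by exhausting all
    monotone residue-pair matchings.

    Any local alignment is determined by the ordered set of aligned
    residue pairs; unaligned residues between consecutive pairs form
    gap runs costing gap_open + len*gap_extend each (two runs when both
    sequences contribute residues). Leading/trailing gaps never help, so
    maximizing over matchings equals maximizing over all substring pairs
    and all gapped alignments between them. Exponential: inputs are
    capped at ``max_len``.
    """
    id1, s1 = _residues(seq1)
    id2, s2 = _residues(seq2)
    if len(s1) > max_len or len(s2) > max_len:
        raise OracleSizeError(
            f"brute-force oracle limited to length {max_len}, "
            f"got {len(s1)} and {len(s2)}"
        )
    _check_alphabet(id1, s1, matrix)
    _check_alphabet(id2, s2, matrix)
    gs, ge = params.gap_open, params.gap_extend
    score = matrix.scores
    n1, n2 = len(s1), len(s2)
    best = 0
    for m in range(1, min(n1, n2) + 1):
        for ii in combinations(range(n1), m):
            for jj in combinations(range(n2), m):
                total = 0
                for k in range(m):
                    total += score[(s1[ii[k]], s2[jj[k]])]
                    if k:
                        di = ii[k] - ii[k - 1] - 1
                        dj = jj[k] - jj[k - 1] - 1
                        if di:
                            total -= gs + di * ge
                        if dj:
                            total -= gs + dj * ge
                if total > best:
                    best = total
    return best


def batch_scores(query, subjects, matrix: SubstitutionMatrix,
                 params: AlignmentParams = AlignmentParams(),
                 workers: int = 1, on_invalid: str = "raise"):
    """Align ``query`` against every subject; order follows the input.

    ``workers`` only affects throughput, never values. ``on_invalid``
    is ``"raise"`` (default) or ``"skip"``: skipped subjects yield
    ``None`` and a logged warning, others are unaffected.
    """
    if workers < 1:
        raise ValidationError(f"workers must be >= 1, got {workers}")
    if on_invalid not in ("raise", "skip"):
        raise ValidationError(f"unknown on_invalid policy {on_invalid!r}")
    subjects = list(subjects)

    def one(subject):
        try:
            return sw_score_row_staged(query, subject, matrix, params)
        except AlphabetError:
            if on_invalid == "skip":
                sid, _ = _residues(subject)
                log.warning("skipping subject %r: invalid residue", sid)
                return None
            raise

    if workers == 1 or len(subjects) <= 1:
        return [one(s) for s in subjects]
    with ThreadPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(one, subjects))
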