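"""Frequency-distance filtration (FDFS) of a protein database.

The prefilter compares residue compositions, not residues. Each sequence
is summarized by its frequency vector (per-residue counts); a frequency
distance between two vectors lower-bounds their edit distance, so any
database sequence whose frequency distance to the query exceeds the edit
distance allowed by the user's identity threshold cannot reach that
identity and is rejected before any alignment is run.

Two frequency-distance definitions are provided:

* ``max_signed_sums`` (default): max of the summed positive and summed
  negative count differences. One substitution moves each signed sum by
  at most 1, so FD <= edit distance — the bound the filter relies on.
* ``l1``: the plain sum of absolute count differences. One substitution
  changes it by 2, so it does NOT lower-bound edit distance and can
  reject true positives at tight thresholds; retained for comparison.

Sequences longer than the query are exempt from filtering: a longer
sequence can contain a high-identity local match to the query while its
overall composition differs arbitrarily, so rejecting on composition
would risk false negatives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import AlphabetError, ValidationError
from .seqdb import DEFAULT_ALPHABET, PreprocessedDatabase, sequence_counts

log = logging.getLogger(__name__)

FD_DEFINITIONS = ("max_signed_sums", "l1")


@dataclass(frozen=True)
class FrequencyVector:
    """Per-residue occurrence counts of a sequence over a fixed alphabet."""

    counts: np.ndarray
    alphabet: str = DEFAULT_ALPHABET

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (len(self.alphabet),):
            raise ValidationError(
                f"counts must have one entry per alphabet residue "
                f"({len(self.alphabet)}), got shape {counts.shape}"
            )
        if (counts < 0).any():
            raise ValidationError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return int(self.counts.sum())

    def __getitem__(self, residue: str) -> int:
        return int(self.counts[self.alphabet.index(residue)])

    def __eq__(self, other) -> bool:
        if not isinstance(other, FrequencyVector):
            return NotImplemented
        return self.alphabet == other.alphabet and np.array_equal(
            self.counts, other.counts
        )


def frequency_vector(seq, alphabet: str = DEFAULT_ALPHABET) -> FrequencyVector:
    """Count each alphabet residue in ``seq`` (order-insensitive summary)."""
    residues = seq.residues if hasattr(seq, "residues") else str(seq).upper()
    return FrequencyVector(sequence_counts(residues, alphabet), alphabet)


def frequency_distance(fu: FrequencyVector, fv: FrequencyVector,
                       definition: str = "max_signed_sums") -> int:
    """Distance between two frequency vectors.

    ``max_signed_sums``: max(sum of positive differences, sum of
    negative differences) — a lower bound on edit distance.
    ``l1``: sum of absolute differences.
    """
    if fu.alphabet != fv.alphabet:
        raise AlphabetError(
            f"frequency vectors use different alphabets: "
            f"{fu.alphabet!r} vs {fv.alphabet!r}"
        )
    diff = fu.counts - fv.counts
    if definition == "max_signed_sums":
        return int(max(diff[diff > 0].sum(), -diff[diff < 0].sum(), 0))
    if definition == "l1":
        return int(np.abs(diff).sum())
    raise ValidationError(f"unknown fd definition {definition!r}")


def ed_bound(query_length: int, identity_threshold: float) -> int:
    """Edit-distance budget implied by an identity threshold.

    A database sequence with identity >= threshold to a length-L query
    differs in at most floor((1 - threshold) * L) positions, so that is
    the largest edit distance the filter may admit.
    """
    if not 0.0 <= identity_threshold <= 1.0:
        raise ValidationError(
            f"identity threshold must be in [0, 1], got {identity_threshold}"
        )
    if query_length < 1:
        raise ValidationError(f"query length must be positive, got {query_length}")
    # epsilon guards binary-float artifacts like (1-0.9)*1030 = 102.999...
    return int(math.floor((1.0 - identity_threshold) * query_length + 1e-9))


@dataclass(frozen=True)
class FiltrationConfig:
    identity_threshold: float
    fd_definition: str = "max_signed_sums"

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_threshold <= 1.0:
            raise ValidationError(
                f"identity threshold must be in [0, 1], "
                f"got {self.identity_threshold}"
            )
        if self.fd_definition not in FD_DEFINITIONS:
            raise ValidationError(
                f"fd_definition must be one of {FD_DEFINITIONS}, "
                f"got {self.fd_definition!r}"
            )


@dataclass(frozen=True)
class FiltrationRecord:
    id: str
    length: int
    fd: int | None  # undefined for length-exempt sequences
    selected: bool
    reason: str  # fd_pass | fd_reject | length_exempt


@dataclass
class FiltrationResult:
    records: list[FiltrationRecord]
    ed_bound: int
    ratio: float = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.records)
        self.ratio = 100.0 * self.n_selected / n if n else 0.0

    @property
    def n_selected(self) -> int:
        return sum(r.selected for r in self.records)

    def selected_ids(self) -> list[str]:
        return [r.id for r in self.records if r.selected]

    def to_tsv(self, path) -> None:
        """Write the per-sequence report: id, length, fd, selected, reason."""
        with open(path, "w") as fh:
            fh.write("seq_id\tlength\tfd\tselected\treason\n")
            for r in self.records:
                fd = "NA" if r.fd is None else str(r.fd)
                fh.write(
                    f"{r.id}\t{r.length}\t{fd}\t"
                    f"{'true' if r.selected else 'false'}\t{r.reason}\n"
                )


def apply_fdfs(query_fv: FrequencyVector, query_length: int,
               db: PreprocessedDatabase,
               config: FiltrationConfig) -> FiltrationResult:
    """Run the filtration over a preprocessed database.

    Sequences strictly longer than the query are selected with reason
    ``length_exempt`` and no FD is computed. Every other sequence gets an
    FD against the query vector and is selected iff FD <= the edit
    bound (ties at the bound pass: only strictly larger FDs are
    rejected). Database order is preserved.
    """
    if query_fv.alphabet != db.alphabet:
        raise AlphabetError(
            f"query alphabet {query_fv.alphabet!r} does not match "
            f"database alphabet {db.alphabet!r}"
        )
    bound = ed_bound(query_length, config.identity_threshold)
    records: list[FiltrationRecord] = []
    if len(db) == 0:
        log.warning("apply_fdfs: empty database, ratio defined as 0")
        return FiltrationResult(records=[], ed_bound=bound)
    lengths = db.lengths
    diff = db.counts - query_fv.counts[np.newaxis, :]
    if config.fd_definition == "max_signed_sums":
        pos = np.where(diff > 0, diff, 0).sum(axis=1)
        neg = np.where(diff < 0, -diff, 0).sum(axis=1)
        fds = np.maximum(pos, neg)
    else:
        fds = np.abs(diff).sum(axis=1)
    exempt = lengths > query_length
    for i, seq in enumerate(db.entries):
        if exempt[i]:
            records.append(
                FiltrationRecord(seq.id, int(lengths[i]), None, True,
                                 "length_exempt")
            )
        else:
            fd = int(fds[i])
            ok = fd <= bound
            records.append(
                FiltrationRecord(seq.id, int(lengths[i]), fd, ok,
                                 "fd_pass" if ok else "fd_reject")
            )
    return FiltrationResult(records=records, ed_bound=bound)
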