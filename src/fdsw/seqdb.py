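"""Protein sequences, FASTA I/O and the preprocessed database index.

A database search against a large protein collection benefits from a
one-off preprocessing pass: sequences are length-sorted and their
per-residue composition (frequency vector) is precomputed and stored in a
plain-text sidecar, so the composition prefilter never has to touch the
raw residues at query time.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .errors import AlphabetError, FastaFormatError, IndexCorruptionError

#: The 20 standard amino acids, alphabetically by one-letter code.
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: IUPAC ambiguity residues with BLOSUM62 scores: Asx, any, Glx.
AMBIGUITY_RESIDUES = "BXZ"

#: Default residue alphabet for databases and filtration: the 20
#: standard amino acids plus the B/X/Z ambiguity codes, sorted.
DEFAULT_ALPHABET = "".join(sorted(PROTEIN_ALPHABET + AMBIGUITY_RESIDUES))

_INDEX_MAGIC = "#fdsw-index"
_INDEX_VERSION = "v1"


@dataclass(frozen=True)
class ProteinSequence:
    """An identified protein sequence.

    ``id`` is the first whitespace-delimited token of a FASTA header and
    must be non-empty; ``residues`` is stored uppercased.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FastaFormatError(f"invalid sequence id {self.id!r}")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


def validate_residues(seq: ProteinSequence, alphabet: str) -> None:
    """Raise :class:`AlphabetError` naming the first offending residue.

    Positions in the message are 1-based.
    """
    allowed = set(alphabet)
    for pos, res in enumerate(seq.residues, start=1):
        if res not in allowed:
            raise AlphabetError(
                f"sequence {seq.id!r}: residue {res!r} at position {pos} "
                f"is not in the alphabet {alphabet!r}"
            )


def read_fasta(path) -> list[ProteinSequence]:
    """Read a FASTA file into a list of :class:`ProteinSequence`.

    Ids are the first whitespace-delimited header token; sequence lines
    are concatenated and uppercased; file order is preserved. Empty
    files, empty records and duplicate ids are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    seqs: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in records:
        if len(rec.seq) == 0:
            raise FastaFormatError(f"record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise FastaFormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seqs.append(ProteinSequence(rec.id, str(rec.seq)))
    return seqs


def write_fasta(seqs, path, wrap: int = 60) -> None:
    """Write sequences as FASTA with lines wrapped at ``wrap`` residues."""
    if wrap < 1:
        raise ValueError("wrap must be a positive integer")
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for start in range(0, len(seq.residues), wrap):
                fh.write(seq.residues[start : start + wrap] + "\n")


def sequence_counts(residues: str, alphabet: str = DEFAULT_ALPHABET) -> np.ndarray:
    """Residue counts of ``residues`` over ``alphabet``, as an int64 array."""
    # np.bincount over mapped codes; -1 marks out-of-alphabet residues
    codes = np.frombuffer(residues.encode("ascii", "replace"), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for i, ch in enumerate(alphabet):
        lut[ord(ch)] = i
    mapped = lut[codes]
    if (mapped < 0).any():
        bad = int(np.argmax(mapped < 0))
        raise AlphabetError(
            f"residue {residues[bad]!r} at position {bad + 1} "
            f"is not in the alphabet {alphabet!r}"
        )
    return np.bincount(mapped, minlength=len(alphabet)).astype(np.int64)


@dataclass
class PreprocessedDatabase:
    """Length-sorted sequences with precomputed frequency-vector counts.

    ``entries`` are sorted by length ascending, ties broken by id;
    ``counts`` is an ``(n, |alphabet|)`` int64 matrix whose row ``i`` is
    the residue composition of ``entries[i]``.
    """

    entries: list[ProteinSequence]
    counts: np.ndarray
    alphabet: str = DEFAULT_ALPHABET
    checksum: str = field(default="")

    def __post_init__(self) -> None:
        if not self.checksum:
            self.checksum = _body_checksum(self._body_lines())

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(s) for s in self.entries], dtype=np.int64)

    def _body_lines(self) -> list[str]:
        lines = []
        for seq, row in zip(self.entries, self.counts):
            counts = "\t".join(str(int(c)) for c in row)
            lines.append(f"{seq.id}\t{len(seq)}\t{counts}\t{seq.residues}")
        return lines

    def __eq__(self, other) -> bool:
        if not isinstance(other, PreprocessedDatabase):
            return NotImplemented
        return (
            self.alphabet == other.alphabet
            and self.entries == other.entries
            and np.array_equal(self.counts, other.counts)
            and self.checksum == other.checksum
        )


def _body_checksum(lines: list[str]) -> str:
    h = hashlib.sha256()
    for line in lines:
        h.update(line.encode())
        h.update(b"\n")
    return h.hexdigest()


def build_index(seqs, alphabet: str = DEFAULT_ALPHABET) -> PreprocessedDatabase:
    """Build the preprocessed index: length-ascending sort, id tiebreak,
    precomputed composition counts.

    The build is a pure function of the input multiset of sequences.
    """
    ordered = sorted(seqs, key=lambda s: (len(s), s.id))
    for seq in ordered:
        validate_residues(seq, alphabet)
    if ordered:
        counts = np.stack([sequence_counts(s.residues, alphabet) for s in ordered])
    else:
        counts = np.zeros((0, len(alphabet)), dtype=np.int64)
    return PreprocessedDatabase(entries=ordered, counts=counts, alphabet=alphabet)


def save_index(db: PreprocessedDatabase, path) -> None:
    """Write the index as a human-diffable text sidecar.

    Header lines carry format version, alphabet, entry count and a
    SHA-256 checksum of the body; each body row is
    ``id  length  <counts...>  sequence`` (tab-separated).
    """
    body = db._body_lines()
    with open(path, "w") as fh:
        fh.write(f"{_INDEX_MAGIC}\t{_INDEX_VERSION}\n")
        fh.write(f"#alphabet\t{db.alphabet}\n")
        fh.write(f"#count\t{len(db.entries)}\n")
        fh.write(f"#checksum\t{_body_checksum(body)}\n")
        for line in body:
            fh.write(line + "\n")


def load_index(path) -> PreprocessedDatabase:
    """Load an index sidecar, verifying version, count and checksum."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith(_INDEX_MAGIC):
        raise IndexCorruptionError(f"{path}: not an fdsw index file")
    magic = lines[0].split("\t")
    if len(magic) != 2 or magic[1] != _INDEX_VERSION:
        raise IndexCorruptionError(
            f"{path}: unsupported index version {lines[0]!r}"
        )
    header: dict[str, str] = {}
    body_start = 1
    for line in lines[1:]:
        if not line.startswith("#"):
            break
        key, _, value = line[1:].partition("\t")
        header[key] = value
        body_start += 1
    try:
        alphabet = header["alphabet"]
        count = int(header["count"])
        checksum = header["checksum"]
    except (KeyError, ValueError) as exc:
        raise IndexCorruptionError(f"{path}: malformed header ({exc})") from exc
    body = lines[body_start:]
    if len(body) != count:
        raise IndexCorruptionError(
            f"{path}: expected {count} entries, found {len(body)} (truncated?)"
        )
    if _body_checksum(body) != checksum:
        raise IndexCorruptionError(f"{path}: checksum mismatch")
    entries: list[ProteinSequence] = []
    rows = []
    width = len(alphabet)
    for lineno, line in enumerate(body, start=body_start + 1):
        fields = line.split("\t")
        if len(fields) != width + 3:
            raise IndexCorruptionError(f"{path}: malformed entry at line {lineno}")
        seq = ProteinSequence(fields[0], fields[-1])
        if int(fields[1]) != len(seq):
            raise IndexCorruptionError(
                f"{path}: length mismatch for {seq.id!r} at line {lineno}"
            )
        entries.append(seq)
        rows.append([int(c) for c in fields[2:-1]])
    counts = (
        np.array(rows, dtype=np.int64)
        if rows
        else np.zeros((0, width), dtype=np.int64)
    )
    return PreprocessedDatabase(
        entries=entries, counts=counts, alphabet=alphabet, checksum=checksum
    )
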