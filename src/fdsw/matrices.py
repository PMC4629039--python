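"""Substitution matrices in NCBI flat format, with an ASCII-indexed lookup.

The scoring table is exposed two ways: a residue-pair mapping for
readable access, and a dense 128x128 table indexed directly by character
codes so the alignment inner loop can fetch S_ij without any hashing —
the classic constant-memory lookup trick from GPU Smith-Waterman
implementations, which is just as convenient on a CPU.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import MatrixFormatError, MatrixValidationError

#: Sentinel marking character-code pairs outside the matrix alphabet.
INVALID_SCORE = np.iinfo(np.int32).min

_BUILTINS = {"BLOSUM62": "BLOSUM62"}


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric residue-pair score table.

    ``alphabet`` preserves the column order of the source file;
    ``ascii_lookup[ord(a), ord(b)]`` equals ``score(a, b)`` for alphabet
    pairs and :data:`INVALID_SCORE` otherwise.
    """

    alphabet: str
    scores: dict[tuple[str, str], int]
    ascii_lookup: np.ndarray

    def score(self, a: str, b: str) -> int:
        return self.scores[(a, b)]

    def encode(self, residues: str) -> np.ndarray:
        """Character codes of ``residues`` as a uint8 array (no validation)."""
        return np.frombuffer(residues.encode("ascii"), dtype=np.uint8)

    def is_valid_residue(self, ch: str) -> bool:
        return ch in self.alphabet


def _build_lookup(alphabet: str, scores: dict[tuple[str, str], int]) -> np.ndarray:
    table = np.full((128, 128), INVALID_SCORE, dtype=np.int32)
    for (a, b), s in scores.items():
        table[ord(a), ord(b)] = s
    return table


def load_substitution_matrix(source) -> SubstitutionMatrix:
    """Load a substitution matrix from an NCBI flat file or builtin name.

    The format is: optional ``#`` comment lines, a header row of residue
    characters, then one labeled integer row per residue. ``"BLOSUM62"``
    resolves to the bundled copy of the standard matrix.

    Raises
    ------
    MatrixFormatError
        On structural problems, naming the offending line number.
    MatrixValidationError
        If the parsed matrix is asymmetric.
    """
    name = str(source)
    if name in _BUILTINS:
        text = (
            resources.files("fdsw.data").joinpath(_BUILTINS[name]).read_text()
        )
    else:
        with open(source) as fh:
            text = fh.read()
    return _parse_matrix(text, origin=name)


def _parse_matrix(text: str, origin: str = "<matrix>") -> SubstitutionMatrix:
    header: list[str] | None = None
    rows: dict[str, list[int]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if header is None:
            if not all(len(f) == 1 for f in fields):
                raise MatrixFormatError(
                    f"{origin}: line {lineno}: header must be single residue "
                    f"characters, got {fields!r}"
                )
            if len(set(fields)) != len(fields):
                raise MatrixFormatError(
                    f"{origin}: line {lineno}: duplicate residue in header"
                )
            header = fields
            continue
        label, *cells = fields
        if len(label) != 1 or label not in header:
            raise MatrixFormatError(
                f"{origin}: line {lineno}: row label {label!r} not in header"
            )
        if len(cells) != len(header):
            raise MatrixFormatError(
                f"{origin}: line {lineno}: expected {len(header)} scores, "
                f"got {len(cells)}"
            )
        try:
            rows[label] = [int(c) for c in cells]
        except ValueError as exc:
            raise MatrixFormatError(
                f"{origin}: line {lineno}: non-integer score ({exc})"
            ) from exc
    if header is None:
        raise MatrixFormatError(f"{origin}: missing header row")
    missing = [r for r in header if r not in rows]
    if missing:
        raise MatrixFormatError(f"{origin}: missing rows for {missing!r}")
    for ch in header:
        if not (ch == "*" or (ch.isalpha() and ch.isupper())):
            raise MatrixFormatError(
                f"{origin}: residue {ch!r} is not an uppercase letter or '*'"
            )
    scores = {
        (a, b): rows[a][j] for a in header for j, b in enumerate(header)
    }
    for a in header:
        for b in header:
            if scores[(a, b)] != scores[(b, a)]:
                raise MatrixValidationError(
                    f"{origin}: asymmetric matrix: "
                    f"score({a},{b})={scores[(a, b)]} != "
                    f"score({b},{a})={scores[(b, a)]}"
                )
    alphabet = "".join(header)
    return SubstitutionMatrix(
        alphabet=alphabet,
        scores=scores,
        ascii_lookup=_build_lookup(alphabet, scores),
    )
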