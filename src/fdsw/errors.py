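"""Exception hierarchy for fdsw."""


class FdswError(Exception):
    """Base class for all fdsw errors."""


class MatrixFormatError(FdswError):
    """A substitution-matrix file could not be parsed."""


class MatrixValidationError(FdswError):
    """A parsed substitution matrix violates an invariant (e.g. asymmetry)."""


class AlphabetError(FdswError):
    """A sequence contains a residue outside the configured alphabet."""


class FastaFormatError(FdswError):
    """A FASTA file violates the expected structure."""


class IndexCorruptionError(FdswError):
    """A database index sidecar failed its integrity checks."""


class OracleSizeError(FdswError):
    """The brute-force oracle was asked for inputs beyond its length cap."""


class ValidationError(FdswError):
    """A parameter is outside its documented range."""
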