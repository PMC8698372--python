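"""Exception hierarchy.

All package errors derive from :class:`SdpscanError` so callers (and the
CLI) can catch one type; each also subclasses :class:`ValueError` since
every failure mode here is an invalid input or corrupt data table.
"""


class SdpscanError(ValueError):
    """Base class for all sdpscan errors."""


class ScaleError(SdpscanError):
    """Invalid or corrupt property-scale / substitution-matrix data."""


class AlignmentError(SdpscanError):
    """Malformed or unusable multiple sequence alignment."""


class ScoringError(SdpscanError):
    """Invalid scoring request (label mismatch, nothing to score, ...)."""


class FunctionalMatrixError(SdpscanError):
    """Invalid external functional-similarity matrix."""


class SyntheticError(SdpscanError):
    """Invalid synthetic-alignment specification."""
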