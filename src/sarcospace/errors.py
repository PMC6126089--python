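"""Exception hierarchy.

``InvalidInputError`` maps to CLI exit code 2, ``AnalysisError`` to exit
code 3; everything raised by the library derives from ``SarcospaceError``.
"""


class SarcospaceError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SarcospaceError):
    """Malformed or out-of-contract input (bad ROI, wrong image type...)."""


class AnalysisError(SarcospaceError):
    """A well-formed input on which the analysis cannot proceed."""


class InsufficientStriationsError(AnalysisError):
    """Fewer than two usable striation peaks before or after filtering."""
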