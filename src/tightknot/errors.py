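"""Exception hierarchy shared across the toolkit."""


class TightknotError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TightknotError, ValueError):
    """An input object violates a documented precondition or invariant."""


class FitError(TightknotError, RuntimeError):
    """A model fit failed to converge or is degenerate; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateTitrationError(TightknotError, ValueError):
    """Titration data do not bracket an interpretable equivalence point."""


class EnvelopeError(TightknotError, ValueError):
    """No internally consistent charge assignment exists for a peak list."""


class ParseError(TightknotError, ValueError):
    """A structure or table file could not be parsed."""


class GenerationError(TightknotError, ValueError):
    """Synthetic-data constraints are mutually inconsistent."""
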