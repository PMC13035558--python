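"""Exception types shared across the pipeline."""


class EndoviewError(Exception):
    """Base class for all package errors."""


class InvalidInputError(EndoviewError, ValueError):
    """An argument violates a precondition or invariant."""


class FormatError(EndoviewError, ValueError):
    """A file on disk is corrupted or internally inconsistent."""


class ValidationError(EndoviewError, ValueError):
    """A label map or hierarchy fails validation; message lists offenders."""


class GenerationError(EndoviewError, RuntimeError):
    """The synthetic generator could not satisfy its constraints."""
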