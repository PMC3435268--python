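"""Exception hierarchy shared across the pipeline."""


class PacpipeError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(PacpipeError):
    """A domain object violates one of its invariants."""


class FormatError(PacpipeError):
    """A file could not be parsed in the declared format."""


class ParameterError(PacpipeError):
    """An operation was called with out-of-domain parameters."""
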