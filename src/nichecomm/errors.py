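"""Exception hierarchy shared across the package."""


class NichecommError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NichecommError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(NichecommError):
    """An in-memory object violates a container invariant."""


class ParameterError(NichecommError):
    """A caller-supplied parameter is out of its admissible range."""


class EmptyAfterQCError(NichecommError):
    """Quality control removed every cell; downstream stages need at least one."""


class PipelineError(NichecommError):
    """A pipeline stage failed; the message names the stage."""
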