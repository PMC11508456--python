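"""Exception hierarchy shared across the pipeline stages."""


class ProteomarkError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ProteomarkError, ValueError):
    """A configuration or function parameter is outside its documented range."""


class InputError(ProteomarkError, ValueError):
    """Input data violates a precondition (empty universe, malformed ID, ...)."""


class FormatError(ProteomarkError, ValueError):
    """A file does not conform to its declared format (wrong column count, ...)."""


class AnnotationError(ProteomarkError, KeyError):
    """A network node has no matching entry in the statistics table."""


class DegenerateFitError(ProteomarkError, ValueError):
    """The model cannot be fitted (e.g. constant matrix with no variance)."""
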