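"""Exception hierarchy shared across the package."""


class PathminerError(Exception):
    """Base class for all package-specific errors."""


class EdgeListParseError(PathminerError):
    """An edge-list file could not be parsed; the message names the offending line."""


class ClassConflictError(PathminerError):
    """The same node id was declared with two different node classes."""


class AnnotationMissingError(PathminerError):
    """A path node has no annotation record."""


class GenerationError(PathminerError):
    """The synthetic-data generator could not satisfy its constraints."""


class PipelineError(PathminerError):
    """A pipeline stage failed; the message names the stage."""
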