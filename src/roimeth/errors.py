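"""Exception hierarchy.

Validation-type errors (bad configuration, malformed input files, inconsistent
tables) derive from :class:`ValidationError` and map to CLI exit code 2;
anything else raised at run time maps to exit code 1.
"""


class RoimethError(Exception):
    """Base class for all package errors."""


class ValidationError(RoimethError):
    """Invalid configuration or input data detected before/while loading."""


class ConfigurationError(ValidationError):
    """A simulation or pipeline configuration value is out of range/missing."""


class FormatError(ValidationError):
    """A file does not conform to its declared format.

    Carries optional ``path`` and ``line`` for error messages that name the
    offending record.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            if line is not None:
                loc += f":{line}"
            loc += "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class RegionError(ValidationError):
    """A genomic region is malformed or out of reference bounds."""


class GenerationError(RoimethError):
    """The synthetic-data generator could not satisfy its post-conditions."""


class PipelineError(RoimethError):
    """A pipeline stage failed; message names the stage and offending item."""
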