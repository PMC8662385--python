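"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: input/format problems exit 2,
infeasible configurations exit 3.
"""


class OrthoverlapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OrthoverlapError):
    """Required configuration (lengths, groups, paths) is missing or inconsistent."""


class InputFormatError(OrthoverlapError):
    """An input file violates its declared dialect."""


class DegenerateInputError(OrthoverlapError):
    """Input is well-formed but the requested computation is undefined on it."""


class ParameterError(OrthoverlapError):
    """A numeric parameter is outside its domain; the message names it."""


class InfeasibleConfigError(OrthoverlapError):
    """A synthetic-data configuration cannot be realised exactly."""
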