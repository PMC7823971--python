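"""Exception hierarchy shared across the package.

All cytocomp errors derive from :class:`CytocompError` so callers (and the
CLI) can distinguish tool failures from programming errors.
"""


class CytocompError(Exception):
    """Base class for all cytocomp errors."""


class InputError(CytocompError):
    """A required input (file, species, directory) is missing or unusable."""


class FormatError(CytocompError):
    """Input content does not conform to the expected file format."""


class ParameterError(CytocompError, ValueError):
    """An operation was called with an invalid parameter value."""


class ContractViolation(CytocompError, ValueError):
    """A caller violated an operation pre-condition (e.g. out-of-range start)."""


class InsufficientDataError(CytocompError):
    """Too few observations to compute the requested statistic."""


class ZeroVarianceError(CytocompError):
    """A correlation is undefined because one measure is constant."""


class FetchError(CytocompError):
    """Remote retrieval failed (lookup, transfer, or verification)."""
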