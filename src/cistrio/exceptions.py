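"""Exception hierarchy shared across the package."""


class CistrioError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CistrioError, ValueError):
    """A user-supplied parameter is outside its stated domain."""


class DegenerateDataError(CistrioError, ValueError):
    """Input data lack the variation a fit requires (constant dosage,
    perfect collinearity, too few complete cases, ...)."""


class ContractError(CistrioError, ValueError):
    """A call violates an internal contract, e.g. a parameter set that
    does not match the requested pattern."""


class FormatError(CistrioError, ValueError):
    """A file does not conform to the expected dialect."""
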