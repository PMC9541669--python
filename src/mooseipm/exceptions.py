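"""Exception hierarchy for model and data validation errors."""


class MooseIPMError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MooseIPMError):
    """A model parameter is non-finite or outside its admissible range."""


class DegenerateStateError(MooseIPMError):
    """Harvest meets or exceeds production: postharvest abundance <= 0."""


class NoStableEquilibriumError(MooseIPMError):
    """Effective density dependence is non-negative; the growth map has no
    stable positive fixed point."""


class InvalidHarvestError(MooseIPMError):
    """Proportional harvest rate outside [0, 1)."""


class InvalidProbabilityError(MooseIPMError):
    """A probability (e.g. hunter success rate) outside [0, 1]."""


class InvalidSurveyError(MooseIPMError):
    """Aerial survey record with non-positive estimate or negative SE."""


class InvalidCountError(MooseIPMError):
    """Negative or non-integer count where a count is required."""


class MissingEffortError(MooseIPMError):
    """Per-day rate requested with zero or negative days of effort."""


class DegenerateCovariateError(MooseIPMError):
    """Covariate series with zero variance cannot be standardized."""


class InsufficientDataError(MooseIPMError):
    """Too few observations for the requested operation."""


class InsufficientChainsError(MooseIPMError):
    """Convergence diagnostics require at least two chains."""


class SchemaError(MooseIPMError):
    """Input table does not match the expected column schema."""
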