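"""Exception hierarchy shared across the toolbox modules."""


class ToolboxError(Exception):
    """Base class for all toolbox-specific errors."""


class SchemaError(ToolboxError):
    """A table is missing a mandatory column or has an unusable layout."""


class ReferentialError(ToolboxError):
    """A record references an identifier that does not exist."""


class DataError(ToolboxError):
    """An operation received structurally valid but unusable data."""


class DomainError(ToolboxError):
    """A numeric argument is outside the mathematical domain of an operation."""


class ParameterError(ToolboxError):
    """A configuration or hyperparameter value is invalid."""


class ConsistencyError(ToolboxError):
    """Two inputs that must agree do not (e.g. follow-up for a failed screen)."""


class InsufficientDataError(ToolboxError):
    """Not enough observations to compute the requested quantity."""


class UndefinedMetricError(ToolboxError):
    """A ratio metric whose denominator is empty."""
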