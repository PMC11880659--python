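"""Exception hierarchy shared across the package."""


class CovaryError(Exception):
    """Base class for all package errors."""


class ConfigError(CovaryError):
    """A configuration object is internally inconsistent or incomplete."""


class ValidationError(CovaryError):
    """Input data violate a structural contract (dimensions, PSD-ness, schema)."""


class DomainError(CovaryError, ValueError):
    """A numeric argument lies outside the mathematically valid domain."""


class DegenerateDataError(CovaryError):
    """Data are valid but carry no information for the requested statistic."""


class SchemaError(CovaryError):
    """A delimited file does not conform to the expected table schema."""


class InvalidRequestError(CovaryError):
    """A summary was requested for a parameter the model does not contain."""
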