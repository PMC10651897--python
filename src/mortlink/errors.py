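"""Exception hierarchy shared across the package."""


class MortlinkError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MortlinkError, ValueError):
    """An invalid specification or configuration value; message names the field."""


class SchemaError(MortlinkError, KeyError):
    """A table is missing columns required by an operation."""


class DataError(MortlinkError, ValueError):
    """Input data violate a documented invariant (e.g. death age outside window)."""


class NumericError(MortlinkError, ArithmeticError):
    """A computation lost all precision (e.g. vanishing truncation-window mass)."""


class IntegrityError(MortlinkError, ValueError):
    """Cross-table consistency violated (duplicate ids, inconsistent truth map)."""


class InfeasibleMarginError(MortlinkError, ValueError):
    """A raking margin has a zero/missing target for a level present in the sample."""


class UnsupportedRegisterError(MortlinkError, TypeError):
    """Operation not defined for this register kind (e.g. women vs a DMF-like file)."""


class DesignError(MortlinkError, ValueError):
    """A regression design matrix is rank deficient; message names the columns."""
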