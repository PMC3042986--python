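"""Exception taxonomy shared across the package."""

from __future__ import annotations


class ShootmassError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ShootmassError, ValueError):
    """A configuration value violates its invariants (bad hue band, fold count, ...)."""


class InputError(ShootmassError, ValueError):
    """User-supplied data is malformed or inconsistent (schema, lengths, missing views)."""


class DomainError(ShootmassError, ValueError):
    """A value is outside the mathematical domain of an operation (log of zero, area 0)."""


class SingularDesignError(ShootmassError, ValueError):
    """The regression design matrix is rank deficient.

    ``columns`` names the offending (linearly dependent) regressors.
    """

    def __init__(self, columns: list[str]):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; dependent column(s): "
            + ", ".join(self.columns)
        )
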