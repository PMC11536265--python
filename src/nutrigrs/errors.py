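"""Exception hierarchy shared across the package."""


class NutrigrsError(Exception):
    """Base class for all package errors."""


class ValidationError(NutrigrsError, ValueError):
    """Input data violates a schema or domain invariant."""


class DomainError(NutrigrsError, ValueError):
    """A numeric argument is outside the formula's domain."""


class FriedewaldValidityError(DomainError):
    """Triacylglycerol exceeds the validity bound of the Friedewald equation."""


class CollinearityError(NutrigrsError, ValueError):
    """A regression design matrix is rank deficient."""


class QcAbortError(NutrigrsError, RuntimeError):
    """All panel SNPs failed quality control; carries the QC report."""

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


class ConfigError(NutrigrsError, ValueError):
    """A pipeline or simulation configuration is invalid."""
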