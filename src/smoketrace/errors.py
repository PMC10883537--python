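"""Exception hierarchy shared across the package."""


class SmoketraceError(Exception):
    """Base class for all package errors."""


class SchemaError(SmoketraceError):
    """A required column or field is missing from an input file."""


class ValidationError(SmoketraceError):
    """A record or container violates a domain invariant."""


class DuplicateKeyError(ValidationError):
    """Two records share an rsid within one dataset."""


class StateError(SmoketraceError):
    """An operation was applied to data in the wrong effect-scale state."""


class DomainError(SmoketraceError):
    """A numeric argument lies outside its mathematical domain."""


class LookupMissError(SmoketraceError):
    """A variant was not found in a reference panel or dataset."""


class InsufficientInstrumentsError(SmoketraceError):
    """Too few variants survive for the requested estimator."""


class DegenerateInstrumentError(SmoketraceError):
    """All instrument-exposure effects are zero (or a single one is, for a Wald ratio)."""


class CollinearityError(SmoketraceError):
    """The weighted design matrix is rank deficient."""


class ConfigError(SmoketraceError):
    """A simulation or study configuration is internally inconsistent."""
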