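"""Exception hierarchy shared across the pipeline stages."""


class LdridgeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LdridgeError, ValueError):
    """Invalid argument values (probabilities, thresholds, labels ...)."""


class CalibrationError(LdridgeError):
    """Prevalence/intercept calibration cannot reach its target."""


class ParseError(LdridgeError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ConsistencyError(LdridgeError):
    """Cross-file or cross-table identifiers do not agree."""


class EmptyResultError(LdridgeError):
    """A filtering step removed everything."""


class DegenerateDesignError(LdridgeError):
    """Constant/monomorphic column or otherwise rank-deficient design."""


class CollinearityError(DegenerateDesignError):
    """Exact collinearity where a unique fit is required."""


class UndefinedLDError(LdridgeError):
    """LD statistics requested for a monomorphic locus."""


class DegenerateVarianceError(LdridgeError):
    """A variance needed for a test is exactly zero."""
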