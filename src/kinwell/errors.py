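"""Exception hierarchy shared across the package."""


class KinwellError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(KinwellError, ValueError):
    """A configuration object violates one of its invariants."""


class InputError(KinwellError, ValueError):
    """Malformed or inconsistent input data."""


class DegenerateSignalError(KinwellError, ValueError):
    """A signal has zero variance, so z-scores are undefined."""


class DegenerateTestError(KinwellError, ValueError):
    """A statistical test is undefined (e.g. zero-variance differences)."""


class ScoringError(KinwellError, ValueError):
    """A questionnaire response cannot be scored (e.g. missing items)."""
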