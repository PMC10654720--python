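"""Exception hierarchy shared across the pipeline stages."""


class CircfrailError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CircfrailError):
    """A simulation or pipeline configuration violates its constraints."""


class FormatError(CircfrailError):
    """An input file is malformed; the message names the offending row."""


class EligibilityError(CircfrailError):
    """A recording fails an eligibility rule (too short, too gappy, <6 cycles)."""


class DegenerateSignalError(CircfrailError):
    """A computation is undefined on this input (e.g. zero-variance series)."""


class ModelFitError(CircfrailError):
    """An association model failed to converge or is not identifiable."""
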