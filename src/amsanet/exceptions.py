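"""Exception hierarchy for amsanet."""


class AmsanetError(Exception):
    """Base class for all amsanet errors."""


class ConfigurationError(AmsanetError, ValueError):
    """A configuration value is out of its admissible range or inconsistent."""


class InvalidInputError(AmsanetError, ValueError):
    """A data input violates a precondition of the operation."""


class RecordIOError(AmsanetError, OSError):
    """A waveform record could not be read or written."""
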