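"""Exception hierarchy for the ergflash pipeline."""


class ErgError(Exception):
    """Base class for all ergflash errors."""


class FormatError(ErgError):
    """Input file does not conform to the expected table layout."""


class IntegrityError(ErgError):
    """Input parses but is internally inconsistent (e.g. ragged sweeps)."""


class ConfigurationError(ErgError):
    """A configuration value is invalid or cannot be inferred."""


class AnalysisError(ErgError):
    """A statistical or normalization step cannot proceed."""


class CalibrationError(ErgError):
    """Preset calibration failed to converge."""
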