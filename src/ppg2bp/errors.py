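"""Exception types shared across the pipeline stages."""


class Ppg2BpError(Exception):
    """Base class for all package errors."""


class FormatError(Ppg2BpError, ValueError):
    """A file or table violates the documented on-disk format."""


class DomainError(Ppg2BpError, ValueError):
    """A parameter or argument is outside its physiological/valid domain."""


class DegenerateBeatError(Ppg2BpError, ValueError):
    """A beat is degenerate (e.g. constant samples, sigma = 0)."""


class FiducialError(Ppg2BpError, ValueError):
    """Fiducial detection failed for a beat; the beat must be excluded."""


class SelectionError(Ppg2BpError, ValueError):
    """Feature selection produced a degenerate result (e.g. all-negative scores)."""


class TrainingError(Ppg2BpError, RuntimeError):
    """Model training failed (divergent loss, empty partition, schema mismatch)."""
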