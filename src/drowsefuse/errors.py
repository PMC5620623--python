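"""Exception hierarchy shared across the pipeline.

Every stage raises one of these instead of a bare ``ValueError`` so that the
pipeline driver can report which contract was violated (bad configuration,
malformed file, degenerate signal, ...) and for which subject or feature.
"""


class DrowseFuseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DrowseFuseError):
    """Invalid generator or pipeline configuration (e.g. band fractions
    that do not sum to one, modulation depth >= 0.5)."""


class ParameterError(DrowseFuseError):
    """An operation was called with out-of-range parameters
    (e.g. band edge above Nyquist, single-class training fold)."""


class FormatError(DrowseFuseError):
    """A recording file violates the expected dialect
    (missing sampling rate, ragged channels, duplicate labels)."""


class AnnotationError(DrowseFuseError):
    """An event annotation cannot be honoured (event too close to a
    recording edge, overlapping 5+5 min windows)."""


class EmptyDataError(DrowseFuseError):
    """No usable data remained after masking/filtering
    (all windows invalid, flat-line ECG, segment shorter than one hop)."""


class DegenerateInputError(DrowseFuseError):
    """Input is formally valid but statistically degenerate
    (zero-variance window, zero-variance paired differences)."""


class PipelineError(DrowseFuseError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
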