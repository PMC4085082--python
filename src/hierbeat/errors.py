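"""Exception hierarchy for hierbeat."""


class HierbeatError(Exception):
    """Base class for all package-specific errors."""


class BeatBoundaryError(HierbeatError):
    """A beat window would extend past the start or end of the signal."""


class InvalidBeatError(HierbeatError):
    """A beat cannot be used (e.g. zero-variance window)."""


class NotABeatError(HierbeatError):
    """An annotation code marks a rhythm/artifact event, not a heartbeat."""


class RecordingError(HierbeatError):
    """A recording on disk is missing, corrupt, or internally inconsistent."""


class EnsembleError(HierbeatError):
    """Invalid ensemble construction or prediction input."""
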