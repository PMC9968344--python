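"""Exception hierarchy shared across the package."""


class VimsHrvError(Exception):
    """Base class for all package errors."""


class ParameterError(VimsHrvError, ValueError):
    """A parameter or invariant violation; the message names the violated rule."""


class ConfigurationError(VimsHrvError, ValueError):
    """A study/effect configuration is incomplete or inconsistent."""


class InsufficientDataError(VimsHrvError, ValueError):
    """Not enough beats/intervals/observations for the requested operation."""


class FormatError(VimsHrvError, IOError):
    """Unknown or unreadable file format."""


class MissingChannelError(FormatError):
    """The expected ECG channel is absent from the file."""


class TruncationError(VimsHrvError, ValueError):
    """A requested analysis window extends outside the available section."""


class AlignmentError(VimsHrvError, ValueError):
    """Two maps/series that must share axes do not."""


class PairingError(VimsHrvError, ValueError):
    """Paired inputs have mismatched sizes."""
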