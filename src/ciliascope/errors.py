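"""Exception hierarchy for ciliascope."""


class CiliascopeError(Exception):
    """Base class for all ciliascope errors."""


class UnsupportedFormatError(CiliascopeError):
    """Input file is not in a supported format (only .tif/.tiff images)."""


class ChannelLayoutError(CiliascopeError):
    """Image channel layout cannot be interpreted as RGB."""


class ConfigurationError(CiliascopeError):
    """Invalid configuration key or value."""


class PlacementError(CiliascopeError):
    """Synthetic scene generation could not place all requested objects."""
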