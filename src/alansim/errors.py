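"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`AlanError`
so callers can catch one type at pipeline boundaries.
"""


class AlanError(Exception):
    """Base class for all alansim errors."""


class ParseError(AlanError, ValueError):
    """A file could not be parsed; the message names the offending line."""

    def __init__(self, path, lineno, message):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class UnsupportedPhotometryError(AlanError, ValueError):
    """The photometric file uses a feature outside the supported subset."""


class DegenerateLIDError(AlanError, ValueError):
    """An intensity web carries no flux, so no direction sampler exists."""


class InvisibleSpectrumError(AlanError, ZeroDivisionError):
    """The emission spectrum has zero overlap with the photopic band."""


class GeometryError(AlanError, ValueError):
    """Invalid input geometry (self-intersection, zero area, ...)."""


class ExtentError(AlanError, ValueError):
    """Geometry falls outside the raster extent it must sample."""


class ConfigurationError(AlanError, ValueError):
    """A scenario / scene configuration is inconsistent or incomplete."""
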