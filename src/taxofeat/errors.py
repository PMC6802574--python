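"""Exception hierarchy.

All package errors derive from :class:`TaxofeatError` so callers can catch
one base class at CLI boundaries.
"""


class TaxofeatError(Exception):
    """Base class for all package errors."""


class ManifestFormatError(TaxofeatError):
    """The manifest CSV is malformed (missing required columns, bad rows)."""


class EmptyManifestError(TaxofeatError):
    """The manifest contains no image records."""


class ImageIOError(TaxofeatError):
    """An image file could not be read; the message names the path."""


class InputError(TaxofeatError):
    """An in-memory input violates a precondition (e.g. zero-area image, NaNs)."""


class ConfigError(TaxofeatError):
    """A configuration value is invalid (e.g. image size not divisible by 32)."""


class GeometryError(TaxofeatError):
    """A feature matrix has the wrong spatial shape for the requested operation."""


class UsageError(TaxofeatError):
    """An API call broke a usage contract (dimension mismatch, mixed provenance)."""


class BackboneWeightsError(TaxofeatError):
    """Pretrained backbone weights are unavailable."""
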