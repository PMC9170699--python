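"""Exception hierarchy shared across the package."""


class RadnanoError(Exception):
    """Base class for all package errors."""


class DomainError(RadnanoError, ValueError):
    """An argument is outside its physically meaningful domain."""


class FormatError(RadnanoError, ValueError):
    """A file or table does not conform to the expected schema."""


class FitError(RadnanoError, RuntimeError):
    """A model fit failed to converge or the design is degenerate."""


class GeometryError(RadnanoError, ValueError):
    """An impossible or inconsistent simulation geometry was requested."""


class PackingError(GeometryError):
    """Sphere placement failed or the requested packing is impossible."""


class AssayError(RadnanoError, ValueError):
    """An assay-level sanity condition failed (e.g. no radiolysis signal)."""
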