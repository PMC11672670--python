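"""Exception hierarchy shared across the package."""


class NMSphereError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(NMSphereError, ValueError):
    """An argument violates a documented precondition."""


class DivergenceError(NMSphereError, ValueError):
    """A pairwise-energy term diverges (coincident points)."""


class UnsupportedDimensionError(NMSphereError, ValueError):
    """Requested hypersphere dimension has no kissing-number preset."""


class DegenerateStructureError(NMSphereError, ValueError):
    """Structure yields more rigid-body (near-zero) modes than expected."""


class TopologyError(NMSphereError, ValueError):
    """Two objects that must share an atom topology do not."""


class FormatError(NMSphereError, ValueError):
    """A file does not conform to its declared format."""
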