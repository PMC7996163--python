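"""Exception hierarchy shared across the package."""


class MitotoxError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(MitotoxError, ValueError):
    """A nanotube specification violates its invariants."""


class CapacityError(MitotoxError, ValueError):
    """More functional groups requested than rim sites available."""


class DescriptorError(MitotoxError, ValueError):
    """A descriptor cannot be computed on the given graph."""


class GeometryError(MitotoxError, ValueError):
    """Invalid 3D geometry (coincident nodes, too few nodes...)."""


class SingularDesignError(MitotoxError, ValueError):
    """Rank-deficient design matrix in a regression."""


class DegenerateImageError(MitotoxError, ValueError):
    """An image with no contrast cannot be binarized."""


class PDBFormatError(MitotoxError, ValueError):
    """Malformed or unusable PDB input."""
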