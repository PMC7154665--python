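"""Exception hierarchy.

All domain errors derive from :class:`CmpHelixError` so the CLI can map them
to a single non-zero exit status while programmatic users can catch precisely.
"""


class CmpHelixError(Exception):
    """Base class for all errors raised by cmphelix."""


class FormatError(CmpHelixError):
    """A coordinate or table file could not be parsed."""


class EmptyStructureError(CmpHelixError):
    """A parsed file contained no usable atoms/residues."""


class SerializationError(CmpHelixError):
    """A structure cannot be represented in the requested file format."""


class RegistrationError(CmpHelixError):
    """No Xxx-Yyy-Gly reading frame fits the chain (not collagen-like)."""


class BuilderError(CmpHelixError):
    """Internal-coordinate construction failed (e.g. ring closure)."""


class GeometryError(CmpHelixError):
    """Degenerate geometry: an angle or dihedral is undefined."""


class UndefinedStatisticError(CmpHelixError):
    """A circular mean/SD is undefined for the given sample."""


class ScoringError(CmpHelixError):
    """Invalid marks, weights or metrics in the suitability rubric."""


class MeltFitError(CmpHelixError):
    """Melt-curve data or fit state does not support the requested operation."""
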