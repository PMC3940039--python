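"""Exception hierarchy shared across the package."""


class ConformeqError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ConformeqError):
    """A file could not be parsed; the message names the offending line."""


class TopologyError(ConformeqError):
    """A residue is missing an atom required by its standard topology."""


class GeometryError(ConformeqError):
    """Degenerate geometry (coincident points, non-positive distances)."""


class MappingError(ConformeqError):
    """Reference atom sets or residue mappings do not correspond one-to-one."""


class ConfigurationError(ConformeqError):
    """Inconsistent inputs (mode mismatch, temperature mismatch, bad paths)."""


class InsufficientDataError(ConformeqError):
    """Fewer data points than a fit or correlation requires."""


class FitError(ConformeqError):
    """An optimization failed to converge from every start."""


class GenerationError(ConformeqError):
    """A synthetic-scene request is geometrically infeasible."""
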