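"""Exception hierarchy for reomap.

All errors raised by the package derive from :class:`ReomapError` so callers
can catch pipeline failures in one place.
"""


class ReomapError(Exception):
    """Base class for all reomap errors."""


class ConfigurationError(ReomapError):
    """Invalid simulation or pipeline configuration."""


class DomainError(ReomapError):
    """An argument is outside the mathematical domain of an operation."""


class GeometryError(ReomapError):
    """Chamber geometry is degenerate or a map has the wrong extent."""


class StructuralError(ReomapError):
    """Containers that must be structurally consistent are not (e.g. cell
    orderings differ between two population stacks)."""
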