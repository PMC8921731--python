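"""Exception hierarchy shared across the package."""


class AntkinError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(AntkinError):
    """Input violates a documented precondition (wrong size, duplicate name...)."""


class DegenerateGeometryError(AntkinError):
    """Geometric configuration admits no unique answer (coplanar cloud,
    coincident centers, parallel directions)."""


class InvalidTopologyError(AntkinError):
    """Segment graph is not a tree rooted at ground."""


class FormatError(AntkinError):
    """A motion-capture file could not be parsed."""


class UnitError(FormatError):
    """A file declares units the reader does not understand."""


class InvalidParameterError(AntkinError):
    """A numeric parameter is out of its admissible range."""
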