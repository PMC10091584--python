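"""Exception hierarchy.

Every failure mode the library promises to detect maps onto one of these
classes so callers (and the CLI) can distinguish user errors from bugs.
"""


class MyofiberError(Exception):
    """Base class for all library errors."""


class MeshFormatError(MyofiberError):
    """The mesh file is not a supported Gmsh ASCII format."""


class UnsupportedMeshError(MyofiberError):
    """The mesh content is valid but not supported (e.g. mixed tet/hex)."""


class MissingLabelsError(MyofiberError):
    """The mesh carries no labeled boundary facets."""


class MeshError(MyofiberError):
    """Geometric defect in a mesh (degenerate cell, inconsistent facet)."""


class ConfigurationError(MyofiberError):
    """A parameter value, tag or geometry/algorithm combination is invalid."""


class IllPosedError(MyofiberError):
    """The Laplace problem has no Dirichlet constraint."""


class NumericalError(MyofiberError):
    """The iterative solver failed to converge."""


class DegenerateFrameError(MyofiberError):
    """The local frame could not be built (k parallel to e_t)."""


class OutOfDomainError(MyofiberError):
    """A point to be interpolated lies outside the source mesh."""
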