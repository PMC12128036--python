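"""Exception hierarchy for micellekit."""


class MicelleKitError(Exception):
    """Base class for all micellekit errors."""


class GroParseError(MicelleKitError):
    """A GRO file violated the fixed-column layout; the message names the line."""


class UnsupportedFormatError(MicelleKitError):
    """Input uses a feature outside the supported subset (e.g. triclinic box)."""


class ConfigurationError(MicelleKitError):
    """Topology/parameter configuration is inconsistent with the requested analysis."""


class MappingError(MicelleKitError):
    """Atomistic-to-CG mapping is invalid (empty bead, out-of-range atom index)."""


class PercolationError(MicelleKitError):
    """Operation undefined for a box-percolating aggregate or surface."""


class NoSurfaceError(MicelleKitError):
    """The requested density level set is empty."""


class OpenMeshError(MicelleKitError):
    """A mesh component is not closed; carries the number of boundary edges."""

    def __init__(self, message: str, n_boundary_edges: int = 0):
        super().__init__(message)
        self.n_boundary_edges = n_boundary_edges


class NotABilayerError(MicelleKitError):
    """Surface does not have the two-leaflet structure of a bilayer."""


class DegenerateSurfaceError(MicelleKitError):
    """Surface metrics requested for a degenerate (zero-volume) surface."""


class NonEllipsoidalMomentsError(MicelleKitError):
    """Principal moments violate the triangle conditions of a solid ellipsoid."""


class SeriesTooShortError(MicelleKitError):
    """Timeseries too short for the requested equilibration analysis."""


class EmptySeriesError(MicelleKitError):
    """Property reduction produced no data after filtering."""


class PlacementError(MicelleKitError):
    """Could not place synthetic components without overlap within the retry budget."""


class EmptyInputError(MicelleKitError):
    """Pipeline invoked on an empty trajectory."""


class GridResourceError(MicelleKitError):
    """Density grid would exceed the configured cell-count cap."""
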