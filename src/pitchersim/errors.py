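"""Exception hierarchy."""


class PitcherSimError(Exception):
    """Base class for all package errors."""


class TopologyError(PitcherSimError):
    """Mesh violates a topological invariant (degenerate polygon,
    wrong edge-sharing count, holes, flipped orientation)."""


class GeometryError(PitcherSimError):
    """Geometric degeneracy (zero-length edge, non-positive area)."""


class ConfigurationError(PitcherSimError):
    """Inconsistent model configuration (e.g. missing cell identities)."""


class StabilityError(PitcherSimError):
    """Numerical integration became unstable."""


class GenerationError(PitcherSimError):
    """Procedural tissue generation failed to meet its specification."""


class DivisionError(PitcherSimError):
    """A cell division could not be executed geometrically."""
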