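"""Exception hierarchy for parchlab."""


class ParchLabError(Exception):
    """Base class for all parchlab errors."""


class FormatError(ParchLabError):
    """A structure or trajectory file could not be parsed."""


class EmptyStructureError(ParchLabError):
    """A parsed file contained no standard amino-acid residues."""


class ParameterError(ParchLabError, ValueError):
    """Invalid physical or algorithmic parameters."""


class PlacementError(ParchLabError):
    """Counterions could not be placed under the distance constraints."""


class NormalizationError(ParchLabError):
    """The lysine reference autocorrelation is unusable (e.g. zero)."""


class ConsistencyError(ParchLabError):
    """Reference and analysis trajectories were produced under different schedules."""


class DegenerateClusteringError(ParchLabError):
    """Fewer than three distinct feature vectors: zones cannot be resolved.

    Carries a single-zone fallback assignment in ``fallback`` so callers that
    opt in can proceed with every residue flagged as one undifferentiated zone.
    """

    def __init__(self, message, fallback=None):
        super().__init__(message)
        self.fallback = fallback


class DensityError(ParchLabError):
    """Sphere packing failed: requested density too high for rejection sampling."""
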