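"""Exception hierarchy for the scan-to-FEM pipeline.

Each pipeline stage raises a dedicated subclass of :class:`Scan2FemError`
so the CLI can abort with the failing stage's name.
"""


class Scan2FemError(Exception):
    """Base class for all pipeline errors."""


class NoColorError(Scan2FemError):
    """PLY file lacks red/green/blue vertex properties."""


class PlyParseError(Scan2FemError):
    """PLY file is unreadable, truncated, or an unsupported dialect."""


class EmptyCropError(Scan2FemError):
    """Crop region retained no vertices."""


class MissingAnchorWarning(UserWarning):
    """A named anchor color produced zero clusters (non-fatal)."""


class AnchorOrderError(Scan2FemError):
    """Anchor angular order is inconsistent with any belt winding direction."""


class OverfullSegmentError(Scan2FemError):
    """More candidate points than electrode slots between two anchors."""


class DegeneratePlaneError(Scan2FemError):
    """Plane fit requested on collinear or too-few points."""


class ThinBandError(Scan2FemError):
    """Fitted z-range is too short for the requested RBF kernel width."""


class RemeshNoConvergeError(Scan2FemError):
    """Force-equilibrium remeshing failed to reach equilibrium."""


class ElectrodeOverlapError(Scan2FemError):
    """Two electrode discs overlap on the surface."""


class BackendMissingError(Scan2FemError):
    """A requested external mesh-generator backend is not available."""


class LabelTransferError(Scan2FemError):
    """Electrode labels could not be transferred onto the volume boundary."""


class SolverError(Scan2FemError):
    """FEM forward system is singular or otherwise unsolvable."""


class ConfigError(Scan2FemError):
    """Invalid configuration value (e.g. non-positive Tikhonov weight)."""


class NoBreathsError(Scan2FemError):
    """Fewer than two breaths detected in an EIT recording."""


class TooFewChannelsError(Scan2FemError):
    """Channel filtering rejected too many measurement channels."""


class InsufficientCorrespondenceError(Scan2FemError):
    """Fewer than three common electrode labels for rigid alignment."""
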