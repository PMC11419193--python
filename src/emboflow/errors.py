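"""Exception hierarchy."""


class EmbofloError(Exception):
    """Base class for all package errors."""


class FormatError(EmbofloError):
    """Input file is not in the expected format (e.g. not a 3D NIfTI)."""


class EmptyCenterlineError(EmbofloError):
    """Centerline volume contains no nonzero voxels."""


class GraphError(EmbofloError):
    """Invalid vascular graph or node-role assignment."""


class SolverError(EmbofloError):
    """The flow linear system could not be solved."""


class CalibrationError(EmbofloError):
    """Parameter calibration failed or the target is unreachable."""


class StagnationError(EmbofloError):
    """Transport requested on a flow field with no motion anywhere."""


class RasterizationError(EmbofloError):
    """Synthetic tree branches collide when rasterized onto the voxel grid."""
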