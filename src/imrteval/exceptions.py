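"""Exception hierarchy for plan/dose validation and metric preconditions."""


class ImrtEvalError(Exception):
    """Base class for all package errors."""


class PlanSchemaError(ImrtEvalError):
    """A plan file is malformed; the message names the offending field."""


class GeometryError(ImrtEvalError):
    """Leaf/jaw state violates machine geometry (count, ordering, range)."""


class AlignmentError(ImrtEvalError):
    """A dose grid and a structure mask do not share voxel geometry."""


class EmptyStructureError(ImrtEvalError):
    """A structure mask contains no voxels where one is required."""


class UndefinedMetricError(ImrtEvalError):
    """A metric's precondition fails (zero-area aperture, absent isodose...)."""


class DegenerateDataError(ImrtEvalError):
    """A statistical routine received data it cannot rank (all-zero diffs)."""
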