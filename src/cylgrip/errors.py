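"""Exception types shared across the pipeline."""


class CylgripError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(CylgripError):
    """A bone or scenario dimension is non-positive or inconsistent."""


class IncompletePoseError(CylgripError):
    """A pose is missing a required (finger, joint) angle."""


class InfeasibleGripError(CylgripError):
    """The finger chain cannot wrap the requested cylinder.

    Attributes
    ----------
    min_feasible_diameter_mm : float
        Smallest cylinder diameter the chain can close around.
    """

    def __init__(self, message: str, min_feasible_diameter_mm: float):
        super().__init__(message)
        self.min_feasible_diameter_mm = float(min_feasible_diameter_mm)


class DegenerateRingError(CylgripError):
    """A landmark ring has fewer than 3 points or is collinear."""


class ZeroLengthAxisError(CylgripError):
    """Base and head centers coincide; no bone axis is defined."""


class NormalizationError(CylgripError):
    """A direction vector is too far from unit norm."""


class FrameConstructionError(CylgripError):
    """Hand coordinate frame references are degenerate."""


class UndefinedRatioError(CylgripError):
    """Coupling ratio requested with non-positive PIP angle."""


class IncompleteDesignError(CylgripError):
    """A factorial dataset is unbalanced or has empty cells."""


class IncompleteSpecError(CylgripError):
    """A cohort spec is missing a (diameter, finger, joint) cell."""


class InsufficientDataError(CylgripError):
    """Too few subjects for the requested statistical operation."""


class MissingCellError(CylgripError):
    """A requested fixed factor-level combination is absent."""
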