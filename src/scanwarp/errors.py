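"""Exception hierarchy for the scanwarp pipeline."""


class ScanwarpError(Exception):
    """Base class for all scanwarp errors."""


class DegenerateContrastError(ScanwarpError):
    """Foreground and background intensities coincide; nothing to render."""


class InvalidKernelError(ScanwarpError):
    """Match kernel has zero variance or is unusably small."""


class NoDetectionsError(ScanwarpError):
    """Thresholding the energy map produced no connected components."""

    def __init__(self, threshold: float):
        self.threshold = threshold
        super().__init__(
            f"no peaks detected at threshold {threshold}; lower the threshold "
            "or check the match kernel"
        )


class InsufficientStructureError(ScanwarpError):
    """Too few triplets could be formed to attempt a lattice fit."""


class ModelFailureError(ScanwarpError):
    """RANSAC failed to assemble a non-empty consensus set."""


class IndexingError(ScanwarpError):
    """Lattice traversal could not start (isolated anchor)."""


class DegenerateGeometryError(ScanwarpError):
    """Correspondences are collinear; affine fit is underdetermined."""


class InsufficientPointsError(ScanwarpError):
    """Too few correspondences for the requested polynomial degree."""

    def __init__(self, n_points: int, n_required: int):
        self.n_points = n_points
        self.n_required = n_required
        super().__init__(
            f"{n_points} correspondences given but the fit needs at least "
            f"{n_required}"
        )


class BoundsError(ScanwarpError):
    """A crop rectangle falls outside the field."""


class StageError(ScanwarpError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
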