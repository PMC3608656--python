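"""End-to-end distortion measurement: detect -> fit lattice -> index -> model.

The library-level entry point is :func:`run_pipeline`, which chains the
four stages on an in-memory image and returns every intermediate product.
Stage failures are wrapped in :class:`scanwarp.errors.StageError` carrying
the stage name, which the CLI maps to a nonzero exit status.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import EnergyMap, PeakSet, extract_peaks, kernel_from_image, \
    normalized_cross_correlation
from .distortion import DistortionField, DistortionStats, displacement_stats, \
    fit_distortion
from .errors import StageError
from .indexing import IndexedLattice, assign_lattice_coords, refine_lattice, \
    refined_basis
from .latticefit import LatticeBasis, build_triplets, triplet_consensus_ransac


@dataclass(frozen=True)
class PipelineResult:
    peaks: PeakSet
    basis: LatticeBasis
    indexed: IndexedLattice
    field: DistortionField
    stats: DistortionStats
    magnitude_map: np.ndarray
    energy: EnergyMap | None = None


def run_pipeline(
    image: np.ndarray,
    kernel_rect: tuple[int, int, int, int],
    threshold: float = 0.6,
    expected_angles: tuple[float, float] = (60.0, -120.0),
    angle_tol: float = 15.0,
    inlier_tol: float | None = None,
    n_iter: int = 200,
    seed: int = 0,
    degree: int = 3,
    sample_step: float = 16.0,
    crop: tuple[float, float, float, float] | None = None,
    refine: bool = True,
    keep_energy: bool = False,
) -> PipelineResult:
    """Measure the nonlinear scan distortion of a calibration image.

    ``kernel_rect`` is the manually selected (x, y, w, h) crop containing a
    single pattern unit.  The field dimensions of the distortion model are
    the image dimensions.
    """
    image = np.asarray(image, float)
    try:
        kernel = kernel_from_image(image, kernel_rect)
        energy = normalized_cross_correlation(image, kernel)
        peaks = extract_peaks(energy, threshold=threshold)
    except Exception as e:  # noqa: BLE001 - stage attribution
        raise StageError("detect", e) from e
    try:
        triplets = build_triplets(peaks, expected_angles, angle_tol)
        basis = triplet_consensus_ransac(
            triplets, peaks, inlier_tol=inlier_tol, n_iter=n_iter, seed=seed
        )
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("fit-lattice", e) from e
    try:
        indexed = assign_lattice_coords(peaks, basis)
        if refine:
            indexed = refine_lattice(indexed)
            basis = refined_basis(indexed, basis)
    except Exception as e:  # noqa: BLE001
        raise StageError("index", e) from e
    try:
        h, w = image.shape
        field = fit_distortion(
            indexed.expected, indexed.points, degree=degree,
            field_dims=(float(w), float(h)),
        )
        stats, mag = displacement_stats(field, sample_step=sample_step, crop=crop)
    except Exception as e:  # noqa: BLE001
        raise StageError("fit-distortion", e) from e
    return PipelineResult(
        peaks=peaks,
        basis=basis,
        indexed=indexed,
        field=field,
        stats=stats,
        magnitude_map=mag,
        energy=energy if keep_energy else None,
    )


def fit_from_points(
    peaks: PeakSet,
    expected_angles: tuple[float, float] = (60.0, -120.0),
    angle_tol: float = 15.0,
    inlier_tol: float | None = None,
    n_iter: int = 200,
    seed: int = 0,
    degree: int = 3,
    field_dims: tuple[float, float] | None = None,
    sample_step: float = 16.0,
    refine: bool = True,
) -> PipelineResult:
    """Pipeline from an existing point set (detections already in hand)."""
    triplets = build_triplets(peaks, expected_angles, angle_tol)
    basis = triplet_consensus_ransac(
        triplets, peaks, inlier_tol=inlier_tol, n_iter=n_iter, seed=seed
    )
    indexed = assign_lattice_coords(peaks, basis)
    if refine:
        indexed = refine_lattice(indexed)
        basis = refined_basis(indexed, basis)
    field = fit_distortion(
        indexed.expected, indexed.points, degree=degree, field_dims=field_dims
    )
    stats, mag = displacement_stats(field, sample_step=sample_step)
    return PipelineResult(
        peaks=peaks, basis=basis, indexed=indexed, field=field,
        stats=stats, magnitude_map=mag,
    )
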