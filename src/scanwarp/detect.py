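"""Pattern-unit detection by normalized cross-correlation.

A match kernel — a manually cropped patch containing one unit of the
repeated calibration pattern — is slid over the image and scored with the
Pearson correlation coefficient at every position (fast normalized
cross-correlation computed with FFT convolutions).  Local maxima of the
resulting energy map mark the image locations of the repeated units; they
are extracted by thresholding, labelling connected components, and taking
one subpixel-refined peak per component.

Spurious detections are tolerated at this stage by design: the downstream
RANSAC lattice fit is responsible for rejecting them, so no shape or score
filtering beyond the threshold is applied here.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .errors import InvalidKernelError, NoDetectionsError


@dataclass(frozen=True)
class MatchKernel:
    """An image patch representing a single pattern unit.

    ``source_rect`` records the (x, y, width, height) crop from the parent
    image, for provenance.
    """

    pixels: np.ndarray
    source_rect: tuple[int, int, int, int] | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or min(px.shape) < 3:
            raise InvalidKernelError("kernel must be 2-D and at least 3x3 px")
        if float(px.var()) <= 0.0:
            raise InvalidKernelError("kernel intensity variance is zero")
        object.__setattr__(self, "pixels", px)


def kernel_from_image(image: np.ndarray, rect: tuple[int, int, int, int]) -> MatchKernel:
    """Crop a match kernel at rect = (x, y, width, height)."""
    x, y, w, h = (int(v) for v in rect)
    img = np.asarray(image)
    if x < 0 or y < 0 or x + w > img.shape[1] or y + h > img.shape[0]:
        raise InvalidKernelError("kernel rect falls outside the image")
    return MatchKernel(pixels=img[y: y + h, x: x + w], source_rect=(x, y, w, h))


def auto_kernel(image: np.ndarray, size: int) -> MatchKernel:
    """Convenience: pick the highest-variance size×size tile as the kernel.

    Manual selection is the normal route; this exists for unattended runs.
    """
    img = np.asarray(image, float)
    h, w = img.shape
    best, best_rect = -1.0, None
    for y in range(0, h - size + 1, size):
        for x in range(0, w - size + 1, size):
            v = float(img[y: y + size, x: x + size].var())
            if v > best:
                best, best_rect = v, (x, y, size, size)
    if best_rect is None or best <= 0:
        raise InvalidKernelError("no tile with positive variance found")
    return kernel_from_image(image, best_rect)


@dataclass(frozen=True)
class EnergyMap:
    """Correlation scores, same shape as the source image.

    ``values[r, c]`` is the Pearson correlation between the kernel and the
    image window whose *center* sits at ``(c + center_shift[0],
    r + center_shift[1])``; the shift is 0 for odd kernel sides and 0.5 for
    even ones.  Positions where the window would leave the image are
    invalid (set to 0 and excluded by ``valid_mask``).
    """

    values: np.ndarray
    valid_mask: np.ndarray
    center_shift: tuple[float, float]
    kernel_shape: tuple[int, int]

    @property
    def valid_margin(self) -> tuple[int, int]:
        """(x, y) border width where correlation is undefined."""
        kh, kw = self.kernel_shape
        return ((kw - 1) // 2, (kh - 1) // 2)


def normalized_cross_correlation(image: np.ndarray, kernel: MatchKernel) -> EnergyMap:
    """Pearson correlation of the kernel with every fully-contained window.

    Windows with (numerically) zero intensity variance score 0.  Values are
    clipped to [-1, 1] to absorb FFT round-off.
    """
    img = np.asarray(image, dtype=float)
    k = kernel.pixels
    kh, kw = k.shape
    if kh > img.shape[0] or kw > img.shape[1]:
        raise InvalidKernelError("kernel must be smaller than the image")

    # Subtracting the global mean leaves every Pearson score unchanged but
    # avoids catastrophic cancellation in the running-sum variance below.
    img = img - img.mean()
    kz = k - k.mean()
    ssk = float(np.sum(kz**2))
    nk = kh * kw

    num = fftconvolve(img, kz[::-1, ::-1], mode="valid")
    ones = np.ones((kh, kw))
    win_sum = fftconvolve(img, ones, mode="valid")
    win_sum2 = fftconvolve(img**2, ones, mode="valid")
    win_var = np.maximum(win_sum2 - win_sum**2 / nk, 0.0)

    denom = np.sqrt(win_var * ssk)
    floor = 1e-10 * nk * max(float(img.var()), np.finfo(float).tiny)
    ncc = np.zeros_like(num)
    good = win_var > floor
    np.divide(num, denom, out=ncc, where=good)
    np.clip(ncc, -1.0, 1.0, out=ncc)

    oy, ox = (kh - 1) // 2, (kw - 1) // 2
    full = np.zeros_like(img)
    mask = np.zeros(img.shape, dtype=bool)
    full[oy: oy + ncc.shape[0], ox: ox + ncc.shape[1]] = ncc
    mask[oy: oy + ncc.shape[0], ox: ox + ncc.shape[1]] = True
    return EnergyMap(
        values=full,
        valid_mask=mask,
        center_shift=((kw - 1) / 2.0 - ox, (kh - 1) / 2.0 - oy),
        kernel_shape=(kh, kw),
    )


@dataclass(frozen=True)
class PeakSet:
    """Subpixel pattern-unit locations x_i with their correlation scores."""

    points: np.ndarray  # (N, 2) float, (x, y)
    scores: np.ndarray  # (N,)

    def __len__(self) -> int:
        return len(self.points)


def _quadratic_subpixel(patch: np.ndarray) -> tuple[float, float]:
    """Stationary point of a 2-D quadratic fit to a 3x3 neighborhood.

    Returns the (dx, dy) offset from the central sample, clamped to
    [-0.5, 0.5] per axis; falls back to (0, 0) if the quadratic has no
    well-defined maximum.
    """
    dy, dx = np.mgrid[-1:2, -1:2]
    g = np.column_stack(
        [np.ones(9), dx.ravel(), dy.ravel(),
         dx.ravel() ** 2, (dx * dy).ravel(), dy.ravel() ** 2]
    )
    c, *_ = np.linalg.lstsq(g, patch.ravel(), rcond=None)
    hess = np.array([[2 * c[3], c[4]], [c[4], 2 * c[5]]])
    if np.linalg.det(hess) <= 0:  # saddle or flat: keep the integer maximum
        return 0.0, 0.0
    off = np.linalg.solve(hess, -np.array([c[1], c[2]]))
    return float(np.clip(off[0], -0.5, 0.5)), float(np.clip(off[1], -0.5, 0.5))


def extract_peaks(
    energy: EnergyMap,
    threshold: float = 0.6,
    subpixel: bool = True,
    min_separation: float = 2.0,
) -> PeakSet:
    """One peak per connected component of the thresholded energy map.

    The map is binarized at ``threshold``, components are labelled with
    8-connectivity, and each component contributes a single peak at its
    correlation maximum, refined to subpixel precision by a 3×3 quadratic
    fit (disable with ``subpixel=False`` for integer-pixel behavior).
    Components touching the invalid border margin are dropped.  Peaks
    closer than ``min_separation`` px are merged, keeping the higher score.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    vals = energy.values
    binary = (vals >= threshold) & energy.valid_mask
    labels, n_comp = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n_comp == 0:
        raise NoDetectionsError(threshold)

    invalid = ~energy.valid_mask
    invalid_dilated = ndimage.binary_dilation(invalid, structure=np.ones((3, 3)))
    # components containing any pixel adjacent to the invalid margin (or on
    # the image border) cannot be trusted
    edge = np.zeros_like(invalid)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    touching = invalid_dilated | edge

    maxima = ndimage.maximum_position(vals, labels, index=np.arange(1, n_comp + 1))
    touched = ndimage.labeled_comprehension(
        touching, labels, np.arange(1, n_comp + 1), np.any, bool, False
    )

    pts, scores = [], []
    sx, sy = energy.center_shift
    for (r, c), bad in zip(maxima, touched):
        if bad:
            continue
        dx = dy = 0.0
        if subpixel and 0 < r < vals.shape[0] - 1 and 0 < c < vals.shape[1] - 1:
            dx, dy = _quadratic_subpixel(vals[r - 1: r + 2, c - 1: c + 2])
        pts.append((c + dx + sx, r + dy + sy))
        scores.append(float(vals[r, c]))
    if not pts:
        raise NoDetectionsError(threshold)

    pts_arr = np.asarray(pts, float)
    scores_arr = np.asarray(scores, float)
    order = np.argsort(-scores_arr)
    keep: list[int] = []
    for i in order:
        if all(np.hypot(*(pts_arr[i] - pts_arr[j])) >= min_separation for j in keep):
            keep.append(i)
    keep.sort()
    return PeakSet(points=pts_arr[keep], scores=scores_arr[keep])
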