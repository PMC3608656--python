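"""Synthetic calibration-lattice fixtures with known geometry and warp.

Real calibration targets for scan-distortion measurement are flat regular
arrays of square units: an IC chip with 2 µm × 2 µm elements in a hexagonal
(60°) arrangement, or a crossed diffraction-grating replica with 0.463 µm
squares on a square lattice.  This module emulates such targets: it places
unit centers on an ideal two-vector lattice, pushes them through a known
affine + low-order bivariate polynomial warp, and renders them as
anti-aliased filled squares with optional additive Gaussian noise.  Because
the injected warp is known exactly, every downstream stage (detection,
lattice fitting, indexing, distortion modelling) can be tested against
ground truth.

Coordinate convention (shared package-wide): continuous image coordinates,
x increasing rightward along columns, y increasing downward along rows,
origin at the center of pixel (0, 0).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._poly import Normalization, design_matrix, monomial_exponents, n_terms
from .errors import DegenerateContrastError


@dataclass(frozen=True)
class IdealLattice:
    """A finite regular lattice of pattern-unit centers.

    The unit at row m, column n sits at ``origin + m*basis_r + n*basis_l``.
    """

    origin: tuple[float, float]
    basis_r: tuple[float, float]
    basis_l: tuple[float, float]
    n_rows: int
    n_cols: int
    unit_side: float

    def __post_init__(self):
        br = np.asarray(self.basis_r, float)
        bl = np.asarray(self.basis_l, float)
        det = br[0] * bl[1] - br[1] * bl[0]
        if abs(det) < 1e-12 * max(1.0, float(np.hypot(*br) * np.hypot(*bl))):
            raise ValueError("basis vectors must be linearly independent")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice must have at least one row and column")
        if not (0 < self.unit_side < min(np.hypot(*br), np.hypot(*bl))):
            raise ValueError("unit_side must be positive and below the pitch")

    @property
    def spacing(self) -> float:
        """Mean basis-vector length (px)."""
        return 0.5 * (math.hypot(*self.basis_r) + math.hypot(*self.basis_l))


def hex_lattice(
    n_rows: int,
    n_cols: int,
    spacing: float,
    angle_deg: float = 60.0,
    origin: tuple[float, float] = (0.0, 0.0),
    unit_side: float | None = None,
) -> IdealLattice:
    """Equal-pitch lattice with the given inner angle between bases.

    ``angle_deg=60`` reproduces the hexagonal IC-chip arrangement,
    ``angle_deg=90`` the square grating arrangement.
    """
    theta = math.radians(angle_deg)
    if unit_side is None:
        unit_side = 0.45 * spacing
    return IdealLattice(
        origin=tuple(origin),
        basis_r=(spacing, 0.0),
        basis_l=(spacing * math.cos(theta), spacing * math.sin(theta)),
        n_rows=n_rows,
        n_cols=n_cols,
        unit_side=unit_side,
    )


def square_lattice(
    n_rows: int,
    n_cols: int,
    spacing: float,
    origin: tuple[float, float] = (0.0, 0.0),
    unit_side: float | None = None,
) -> IdealLattice:
    return hex_lattice(n_rows, n_cols, spacing, 90.0, origin, unit_side)


def generate_lattice_points(lattice: IdealLattice) -> tuple[np.ndarray, np.ndarray]:
    """Exact unit centers and their integer (m, n) labels.

    Returns ``(points, labels)`` where ``points`` is (N, 2) float and
    ``labels`` is (N, 2) int, both row-major: all columns of row 0 first.
    """
    m, n = np.meshgrid(
        np.arange(lattice.n_rows), np.arange(lattice.n_cols), indexing="ij"
    )
    labels = np.column_stack([m.ravel(), n.ravel()])
    br = np.asarray(lattice.basis_r, float)
    bl = np.asarray(lattice.basis_l, float)
    points = (
        np.asarray(lattice.origin, float)
        + labels[:, :1] * br
        + labels[:, 1:] * bl
    )
    return points, labels


@dataclass(frozen=True)
class WarpSpec:
    """A known distortion: affine composed with a bivariate polynomial.

    A point p maps to ``affine(p) + (Px(u), Py(u))`` where u is p in the
    normalized coordinates of ``norm`` and Px, Py are polynomials with
    coefficients over :func:`scanwarp._poly.monomial_exponents` order.
    The polynomial displacement must vary slowly relative to the lattice
    pitch (see :func:`validate_local_displacement`) so that the
    nearest-neighbor structure of the pattern survives the warp.
    """

    affine: np.ndarray  # (2, 3): [linear | translation]
    poly_coeff_x: np.ndarray
    poly_coeff_y: np.ndarray
    degree: int
    norm: Normalization
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        a = np.asarray(self.affine, float)
        if a.shape != (2, 3):
            raise ValueError("affine must be a 2x3 matrix [linear | translation]")
        nt = n_terms(self.degree)
        if len(self.poly_coeff_x) != nt or len(self.poly_coeff_y) != nt:
            raise ValueError(
                f"degree-{self.degree} polynomial needs {nt} coefficients per axis"
            )
        object.__setattr__(self, "affine", a)
        object.__setattr__(self, "poly_coeff_x", np.asarray(self.poly_coeff_x, float))
        object.__setattr__(self, "poly_coeff_y", np.asarray(self.poly_coeff_y, float))


def identity_warp(field_dims: tuple[float, float], degree: int = 1,
                  noise_sigma: float = 0.0, seed: int = 0) -> WarpSpec:
    nt = n_terms(degree)
    return WarpSpec(
        affine=np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
        poly_coeff_x=np.zeros(nt),
        poly_coeff_y=np.zeros(nt),
        degree=degree,
        norm=Normalization.for_field(field_dims),
        noise_sigma=noise_sigma,
        seed=seed,
    )


def polynomial_displacement(points: np.ndarray, warp: WarpSpec) -> np.ndarray:
    phi = design_matrix(np.asarray(points, float), warp.degree, warp.norm)
    return np.column_stack([phi @ warp.poly_coeff_x, phi @ warp.poly_coeff_y])


def apply_warp(points: np.ndarray, warp: WarpSpec) -> np.ndarray:
    """Map each point p to affine(p) + polynomial displacement at p."""
    p = np.asarray(points, float)
    if not np.all(np.isfinite(p)):
        raise ValueError("points must be finite")
    lin = warp.affine[:, :2]
    t = warp.affine[:, 2]
    return p @ lin.T + t + polynomial_displacement(p, warp)


def validate_local_displacement(warp: WarpSpec, lattice: IdealLattice) -> float:
    """Largest polynomial-displacement change across one lattice step.

    Returns the maximum over lattice points and both basis directions of
    ``|disp(p + basis) - disp(p)|``; values approaching half the pitch mean
    the warp folds neighbors into ambiguity and detection cannot be trusted.
    """
    pts, _ = generate_lattice_points(lattice)
    disp = polynomial_displacement(pts, warp)
    worst = 0.0
    for b in (lattice.basis_r, lattice.basis_l):
        d2 = polynomial_displacement(pts + np.asarray(b, float), warp)
        worst = max(worst, float(np.max(np.hypot(*(d2 - disp).T))))
    return worst


def render_lattice_image(
    points: np.ndarray,
    unit_side: float,
    image_dims: tuple[int, int],
    fg: float = 1.0,
    bg: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render filled squares of side ``unit_side`` centered on ``points``.

    Square edges are anti-aliased by exact area-weighted coverage of
    boundary pixels (separable in x and y for axis-aligned squares), which
    preserves subpixel position information in the rendered image.  Points
    (or parts of squares) outside the image are clipped silently.  Output is
    float64, ``image_dims`` is (width, height); identical seeds give
    bit-identical images.
    """
    w, h = int(image_dims[0]), int(image_dims[1])
    if w <= 0 or h <= 0:
        raise ValueError("image dimensions must be positive")
    if fg == bg:
        raise DegenerateContrastError("foreground equals background intensity")
    if unit_side <= 0:
        raise ValueError("unit_side must be positive")

    coverage = np.zeros((h, w), dtype=float)
    half = unit_side / 2.0
    for cx, cy in np.atleast_2d(np.asarray(points, float)):
        x0, x1 = cx - half, cx + half
        y0, y1 = cy - half, cy + half
        ix = np.arange(max(0, math.floor(x0 - 0.5)), min(w, math.ceil(x1 + 1.5)))
        iy = np.arange(max(0, math.floor(y0 - 0.5)), min(h, math.ceil(y1 + 1.5)))
        if ix.size == 0 or iy.size == 0:
            continue
        # pixel i covers [i - 0.5, i + 0.5); overlap length with [x0, x1]
        cov_x = np.clip(np.minimum(ix + 0.5, x1) - np.maximum(ix - 0.5, x0), 0.0, 1.0)
        cov_y = np.clip(np.minimum(iy + 0.5, y1) - np.maximum(iy - 0.5, y0), 0.0, 1.0)
        patch = np.outer(cov_y, cov_x)
        region = coverage[iy[0]: iy[-1] + 1, ix[0]: ix[-1] + 1]
        np.maximum(region, patch, out=region)

    image = bg + (fg - bg) * coverage
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
    return image


# ---------------------------------------------------------------------------
# Warp fixtures with a controlled affine-free distortion magnitude
# ---------------------------------------------------------------------------

def _fit_affine_lstsq(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Plain least-squares 6-parameter affine, (2, 3).  Kept local so the
    ground-truth computation shares no code with the estimation pipeline."""
    g = np.column_stack([src, np.ones(len(src))])
    coef, *_ = np.linalg.lstsq(g, dst, rcond=None)
    return coef.T  # (2, 3)


def affine_free_rms(
    warp: WarpSpec,
    lattice: IdealLattice,
    field_dims: tuple[float, float],
    step: float = 16.0,
) -> tuple[float, float]:
    """Ground-truth affine-free displacement (rms, max) of a warp.

    Defined the way the measurement itself is defined: every location in
    the field is pushed through the full warp and compared, in image
    pixels, with where the best-fit regular (affine) lattice would put it.
    Concretely, with A the least-squares affine over the true
    (ideal point -> warped point) correspondences, the displacement at an
    image-frame grid point p (midpoint sampling of pitch ``step``, box of
    ``field_dims`` centered on the centroid of the warped points) is
    ``|warp(A^-1 p) - p|``.
    """
    pts, _ = generate_lattice_points(lattice)
    warped = apply_warp(pts, warp)
    aff = _fit_affine_lstsq(pts, warped)
    w, h = field_dims
    c = warped.mean(axis=0)
    # midpoint sampling matching the measurement pipeline's quadrature
    nx, ny = max(1, round(w / step)), max(1, round(h / step))
    xs = c[0] - (w - 1) / 2.0 - 0.5 + (np.arange(nx) + 0.5) * (w / nx)
    ys = c[1] - (h - 1) / 2.0 - 0.5 + (np.arange(ny) + 0.5) * (h / ny)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    lin_inv = np.linalg.inv(aff[:, :2])
    pre_image = (grid - aff[:, 2]) @ lin_inv.T  # A^-1 applied to the grid
    resid = apply_warp(pre_image, warp) - grid
    mag = np.hypot(resid[:, 0], resid[:, 1])
    return float(np.sqrt(np.mean(mag**2))), float(np.max(mag))


def effective_basis(
    warp: WarpSpec, lattice: IdealLattice
) -> tuple[np.ndarray, np.ndarray]:
    """Generators of the best-fit regular lattice after the warp.

    Under a nonlinear warp there is no single "true" basis; the
    well-defined analogue is the generator pair of the regular (affine)
    lattice that best fits the warped unit positions in the least-squares
    sense — the quantity a basis estimate over the whole pattern targets.
    Computed as the linear part of the ideal->warped affine fit applied to
    the ideal generators.
    """
    pts, _ = generate_lattice_points(lattice)
    aff = _fit_affine_lstsq(pts, apply_warp(pts, warp))
    lin = aff[:, :2]
    return lin @ np.asarray(lattice.basis_r), lin @ np.asarray(lattice.basis_l)


def study_point_set(
    seed: int,
    n_rows: int = 30,
    n_cols: int = 30,
    field_width: float = 4000.0,
    target_rms: float | None = None,
    rms_range: tuple[float, float] = (2.5, 35.0),
    jitter_sigma: float = 0.0,
    spurious_fraction: float = 0.0,
    degree: int = 3,
) -> tuple[IdealLattice, WarpSpec, tuple[float, float], np.ndarray, int]:
    """A warped hexagonal-lattice point set under controlled conditions.

    Emulates the detections from a large calibration scan: a 60° lattice
    sized to span ``field_width``, pushed through a random affine +
    degree-3 polynomial warp with affine-free rms drawn from ``rms_range``
    (or fixed at ``target_rms``), optionally with Gaussian detection
    jitter and uniformly scattered spurious detections appended.

    Returns (lattice, warp, field_dims, points, n_true); spurious points
    occupy indices >= n_true.
    """
    rng = np.random.default_rng([seed, 0x5CA1])
    margin = field_width / 40.0
    spacing = (field_width - 2 * margin) / ((n_cols - 1) * 1.5)
    lattice = hex_lattice(n_rows, n_cols, spacing, origin=(margin, margin))
    pts, _ = generate_lattice_points(lattice)
    height = float(pts[:, 1].max()) + margin
    field_dims = (field_width, math.ceil(height / 100.0) * 100.0)
    if target_rms is None:
        target_rms = float(rng.uniform(*rms_range))
    warp = random_warp(int(rng.integers(2**31)), lattice, field_dims,
                       target_rms, degree=degree)
    warped = apply_warp(pts, warp)
    n_true = len(warped)
    if jitter_sigma > 0:
        warped = warped + rng.normal(0.0, jitter_sigma, warped.shape)
    if spurious_fraction > 0:
        m = round(spurious_fraction * n_true)
        lo, hi = warped.min(axis=0), warped.max(axis=0)
        warped = np.vstack([warped, rng.uniform(lo, hi, size=(m, 2))])
    return lattice, warp, field_dims, warped, n_true


def random_warp(
    seed: int,
    lattice: IdealLattice,
    field_dims: tuple[float, float],
    target_rms: float,
    degree: int = 3,
    noise_sigma: float = 0.0,
) -> WarpSpec:
    """Random smooth warp whose affine-free displacement rms equals
    ``target_rms`` px over ``field_dims``.

    The affine part is a mild centered rotation/scale/shear plus a small
    translation (the kind of residual an aligned scan generator leaves);
    the polynomial part is drawn at random and rescaled — legitimate
    because the affine-free residual is linear in the polynomial
    coefficients.
    """
    rng = np.random.default_rng(seed)
    w, h = field_dims
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    theta = math.radians(rng.uniform(-0.5, 0.5))
    sx, sy = 1.0 + rng.uniform(-0.005, 0.005, 2)
    shear = rng.uniform(-0.005, 0.005)
    lin = np.array(
        [
            [sx * math.cos(theta), -math.sin(theta) + shear],
            [math.sin(theta), sy * math.cos(theta)],
        ]
    )
    trans = center - lin @ center + rng.uniform(-3, 3, 2)
    affine = np.column_stack([lin, trans])

    nt = n_terms(degree)
    norm = Normalization.for_field(field_dims)
    probe = WarpSpec(
        affine=np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
        poly_coeff_x=rng.normal(0.0, 1.0, nt),
        poly_coeff_y=rng.normal(0.0, 1.0, nt),
        degree=degree,
        norm=norm,
    )
    # two calibration passes: the residual is only approximately linear in
    # the coefficients (the best-fit affine moves with them)
    step = max(8.0, w / 200)
    cx, cy = probe.poly_coeff_x, probe.poly_coeff_y
    for _ in range(2):
        trial = WarpSpec(affine=affine, poly_coeff_x=cx, poly_coeff_y=cy,
                         degree=degree, norm=norm)
        rms0, _ = affine_free_rms(trial, lattice, field_dims, step=step)
        if rms0 <= 0:
            break
        cx = cx * (target_rms / rms0)
        cy = cy * (target_rms / rms0)
    return WarpSpec(
        affine=affine,
        poly_coeff_x=cx,
        poly_coeff_y=cy,
        degree=degree,
        norm=norm,
        noise_sigma=noise_sigma,
        seed=seed,
    )
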