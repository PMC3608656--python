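"""Calibration arithmetic for serial-section EM acquisition.

Three practical calculations that accompany the distortion measurement:

* **Pixel size** from an image of a crossed diffraction-grating replica
  with known pitch (0.463 µm squares on the common standard): the fitted
  lattice basis converts pitch to nm per pixel.
* **Section thickness** by the cylindrical-mitochondria method: the ratio
  of the maximum diameter of a longitudinally sectioned cylindrical
  organelle to the number of serial sections it spans.
* **Acquisition geometry**: field dimensions, areas, imaged volume, voxel
  counts and volume per operator hour from the primary quantities
  (pixel size a, section thickness b, section count c, field pixels d,
  operator time h), plus a mosaic-tile planner for fields larger than a
  single scan.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .latticefit import LatticeBasis


@dataclass(frozen=True)
class PixelSizeResult:
    nm_per_px: float
    basis_lengths_px: tuple[float, float]
    anisotropy: float  # |len_r - len_l| / mean length
    warning: str | None = None


def pixel_size_from_grating(
    basis: LatticeBasis, known_pitch_um: float = 0.463
) -> PixelSizeResult:
    """Pixel size (nm/px) from a fitted grating-replica lattice basis.

    The grating pitch in physical units divided by the mean basis-vector
    length in pixels gives the scale.  If the two basis lengths differ by
    more than 5% an anisotropy warning is attached (and emitted), since a
    square grating should produce equal pitches in both directions.
    """
    if known_pitch_um <= 0:
        raise ValueError("known_pitch_um must be positive")
    lr = float(np.hypot(*basis.g_r))
    ll = float(np.hypot(*basis.g_l))
    mean_len = 0.5 * (lr + ll)
    aniso = abs(lr - ll) / mean_len
    msg = None
    if aniso > 0.05:
        msg = (
            f"basis lengths differ by {aniso:.1%} (|g_r|={lr:.2f}, "
            f"|g_l|={ll:.2f} px); grating fit may be unreliable"
        )
        warnings.warn(msg, stacklevel=2)
    return PixelSizeResult(
        nm_per_px=known_pitch_um * 1000.0 / mean_len,
        basis_lengths_px=(lr, ll),
        anisotropy=aniso,
        warning=msg,
    )


@dataclass(frozen=True)
class MitochondrionSpan:
    """One longitudinally sectioned cylindrical object."""

    max_diameter_nm: float
    n_sections_spanned: int

    def __post_init__(self):
        if self.max_diameter_nm <= 0 or self.n_sections_spanned <= 0:
            raise ValueError("diameter and section count must be positive")
        if not (100.0 <= self.max_diameter_nm <= 2000.0):
            warnings.warn(
                f"max diameter {self.max_diameter_nm} nm outside the plausible "
                "100-2000 nm range for mitochondria",
                stacklevel=3,
            )

    @property
    def thickness_nm(self) -> float:
        return self.max_diameter_nm / self.n_sections_spanned


@dataclass(frozen=True)
class ThicknessEstimate:
    mean_nm: float
    sd_nm: float  # sample standard deviation; NaN for a single object
    per_object_nm: tuple[float, ...]


def section_thickness(spans: list[MitochondrionSpan]) -> ThicknessEstimate:
    """Mean section thickness across cylindrical objects (unweighted)."""
    if not spans:
        raise ValueError("no mitochondrion spans given")
    per = np.array([s.thickness_nm for s in spans])
    sd = float(np.std(per, ddof=1)) if len(per) > 1 else float("nan")
    return ThicknessEstimate(
        mean_nm=float(per.mean()), sd_nm=sd, per_object_nm=tuple(per)
    )


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Primary acquisition quantities (the a-h of a platform spec sheet)."""

    pixel_size_nm: float  # a
    section_thickness_nm: float  # b
    n_sections: int  # c
    field_px_per_side: int  # d
    operator_time_hr: float | None = None  # h

    def __post_init__(self):
        vals = [self.pixel_size_nm, self.section_thickness_nm,
                self.n_sections, self.field_px_per_side]
        if any(v <= 0 for v in vals):
            raise ValueError("all geometry quantities must be positive")
        if self.operator_time_hr is not None and self.operator_time_hr <= 0:
            raise ValueError("operator time must be positive")


def sigfig(x: float, n: int = 4) -> float:
    """Round to n significant figures, half away from zero."""
    if x == 0 or not math.isfinite(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    scale = 10.0 ** (exp - n + 1)
    out = math.floor(abs(x) / scale + 0.5) * scale * (1 if x > 0 else -1)
    return round(out, max(0, n - 1 - exp))  # strip binary float noise


@dataclass(frozen=True)
class FieldMetrics:
    """Derived acquisition-geometry quantities, exact and display-rounded.

    ``volume_um3_chained`` recomputes the volume from the 4-significant-
    figure side length, matching spec-sheet practice where derived rows
    chain from already-rounded entries; the exact value is authoritative.
    """

    side_um: float  # e = a * d
    area_um2: float  # f = e^2
    volume_um3: float  # g = b * c * f
    n_voxels: float  # c * d^2
    volume_per_hour_um3: float | None  # g / h
    volume_um3_chained: float
    display: dict[str, float]


def field_metrics(geom: AcquisitionGeometry) -> FieldMetrics:
    """Exact arithmetic for the derived acquisition-geometry table."""
    a, b = geom.pixel_size_nm, geom.section_thickness_nm
    c, d = geom.n_sections, geom.field_px_per_side
    e = a * d / 1000.0  # µm per side
    f = e * e
    g = (b / 1000.0) * c * f
    voxels = float(c) * d * d
    per_hr = g / geom.operator_time_hr if geom.operator_time_hr else None
    e_disp = sigfig(e)
    g_chained = (b / 1000.0) * c * e_disp * e_disp
    display = {
        "side_um": e_disp,
        "area_um2": sigfig(f),
        "volume_um3": sigfig(g),
        "volume_um3_chained": sigfig(g_chained),
        "n_voxels": sigfig(voxels),
    }
    if per_hr is not None:
        display["volume_per_hour_um3"] = sigfig(per_hr)
    return FieldMetrics(
        side_um=e,
        area_um2=f,
        volume_um3=g,
        n_voxels=voxels,
        volume_per_hour_um3=per_hr,
        volume_um3_chained=g_chained,
        display=display,
    )


@dataclass(frozen=True)
class MosaicPlan:
    n_cols: int
    n_rows: int
    n_tiles: int
    tile_extent_um: float
    stride_um: float


def mosaic_plan(
    target_w_um: float,
    target_h_um: float,
    tile_px: int,
    pixel_size_nm: float,
    overlap_fraction: float = 0.0,
) -> MosaicPlan:
    """Number of image tiles needed to cover a target field.

    A tile covers ``tile_px * pixel_size`` µm per side; with fractional
    overlap the effective stride shrinks to (1 - overlap) of that.  A
    360 µm x 60 µm target with 32,768-px tiles at 2 nm/px and no overlap
    needs a 6 x 1 mosaic.
    """
    if min(target_w_um, target_h_um, tile_px, pixel_size_nm) <= 0:
        raise ValueError("target dimensions, tile size and pixel size must be positive")
    if not (0.0 <= overlap_fraction < 0.5):
        raise ValueError("overlap_fraction must lie in [0, 0.5)")
    if tile_px < 1:
        raise ValueError("tile must cover at least one pixel")
    tile_um = tile_px * pixel_size_nm / 1000.0
    stride = tile_um * (1.0 - overlap_fraction)
    n_cols = max(1, math.ceil(target_w_um / stride))
    n_rows = max(1, math.ceil(target_h_um / stride))
    return MosaicPlan(
        n_cols=n_cols,
        n_rows=n_rows,
        n_tiles=n_cols * n_rows,
        tile_extent_um=tile_um,
        stride_um=stride,
    )
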