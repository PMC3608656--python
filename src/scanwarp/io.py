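"""File I/O: TIFF images, peaks CSV, basis/report JSON, provenance records.

CSV dialect: comma-separated, header row, UTF-8, '.' decimal, 6-decimal
fixed format for coordinates and scores.  JSON numbers are written at full
double precision.  Every JSON artifact embeds a provenance record
(command, parameters, seed, software version) but no timestamps, so
identical runs produce bit-identical outputs.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from ._poly import Normalization
from .detect import PeakSet
from .distortion import AffineMap, DistortionField, DistortionStats
from .indexing import IndexedLattice
from .latticefit import LatticeBasis


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel grayscale image (TIFF preferred, PNG accepted)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse trivial channel axes
        arr = arr.mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a single-channel 2-D image")
    return arr.astype(float)


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32))


def provenance(command: str, params: dict[str, Any]) -> dict[str, Any]:
    return {
        "software": "scanwarp",
        "version": __version__,
        "command": command,
        "parameters": {k: _jsonable(v) for k, v in params.items()},
    }


def _jsonable(v: Any) -> Any:
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, Path):
        return str(v)
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v


def write_json(path: str | Path, payload: dict[str, Any]) -> None:
    Path(path).write_text(
        json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def peaks_to_csv(path: str | Path, peaks: PeakSet) -> None:
    df = pd.DataFrame(
        {
            "id": np.arange(len(peaks)),
            "x": peaks.points[:, 0],
            "y": peaks.points[:, 1],
            "score": peaks.scores,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def peaks_from_csv(path: str | Path) -> PeakSet:
    df = pd.read_csv(path)
    return PeakSet(
        points=df[["x", "y"]].to_numpy(float), scores=df["score"].to_numpy(float)
    )


def indexed_to_csv(path: str | Path, indexed: IndexedLattice) -> None:
    """Peaks CSV augmented with lattice coordinates and expected locations."""
    df = pd.DataFrame(
        {
            "id": indexed.peak_ids,
            "x": indexed.points[:, 0],
            "y": indexed.points[:, 1],
            "c_r": indexed.coords[:, 0],
            "c_l": indexed.coords[:, 1],
            "y_x": indexed.expected[:, 0],
            "y_y": indexed.expected[:, 1],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def indexed_from_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (expected y_i, measured x_i) correspondence arrays."""
    df = pd.read_csv(path)
    return df[["y_x", "y_y"]].to_numpy(float), df[["x", "y"]].to_numpy(float)


def basis_to_json(path: str | Path, basis: LatticeBasis,
                  prov: dict[str, Any] | None = None) -> None:
    payload: dict[str, Any] = {
        "g_r": basis.g_r,
        "g_l": basis.g_l,
        "consensus_ids": basis.consensus_ids,
        "inlier_fraction": basis.inlier_fraction,
        "inlier_tol": basis.inlier_tol,
    }
    if prov is not None:
        payload["provenance"] = prov
    write_json(path, payload)


def basis_from_json(path: str | Path) -> LatticeBasis:
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    return LatticeBasis(
        g_r=np.asarray(d["g_r"], float),
        g_l=np.asarray(d["g_l"], float),
        consensus_ids=np.asarray(d["consensus_ids"], int),
        inlier_fraction=float(d["inlier_fraction"]),
        inlier_tol=float(d["inlier_tol"]),
    )


def field_to_dict(field: DistortionField) -> dict[str, Any]:
    d: dict[str, Any] = {
        "degree": field.degree,
        "coeff_x": field.coeff_x,
        "coeff_y": field.coeff_y,
        "field_dims": field.field_dims,
        "normalization": {
            "center": field.normalization.center,
            "half": field.normalization.half,
        },
        "frame_center": field.frame_center,
        "fit_rms": field.fit_rms,
        "n_points": field.n_points,
    }
    if field.affine is not None:
        d["affine"] = {
            "linear": field.affine.linear,
            "translation": field.affine.translation,
            "fit_residual_rms": field.affine.fit_residual_rms,
        }
    return d


def field_from_dict(d: dict[str, Any]) -> DistortionField:
    affine = None
    if "affine" in d:
        affine = AffineMap(
            linear=np.asarray(d["affine"]["linear"], float),
            translation=np.asarray(d["affine"]["translation"], float),
            fit_residual_rms=float(d["affine"]["fit_residual_rms"]),
        )
    return DistortionField(
        degree=int(d["degree"]),
        coeff_x=np.asarray(d["coeff_x"], float),
        coeff_y=np.asarray(d["coeff_y"], float),
        field_dims=tuple(d["field_dims"]),
        normalization=Normalization(
            center=tuple(d["normalization"]["center"]),
            half=tuple(d["normalization"]["half"]),
        ),
        affine=affine,
        frame_center=tuple(d["frame_center"]) if d.get("frame_center") else None,
        fit_rms=float(d.get("fit_rms", 0.0)),
        n_points=int(d.get("n_points", 0)),
    )


def stats_to_dict(stats: DistortionStats) -> dict[str, Any]:
    return {
        "rms_px": stats.rms_px,
        "max_px": stats.max_px,
        "rms_percent": stats.rms_percent,
        "n_points": stats.n_points,
        "crop_rect": stats.crop_rect,
    }
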