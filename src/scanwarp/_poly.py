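"""Bivariate monomial basis over normalized coordinates.

All polynomial fits in the package evaluate monomials x^j * y^k with
j + k <= degree on coordinates rescaled to roughly [-1, 1] over the field,
which keeps the Vandermonde systems well conditioned even at degree 7.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def monomial_exponents(degree: int) -> list[tuple[int, int]]:
    """Exponent pairs (j, k), j + k <= degree, in deterministic order.

    Ordered by total degree, then descending power of x, so the constant
    term is first and pure-x terms precede pure-y terms within a degree.
    """
    if degree < 0:
        raise ValueError("degree must be >= 0")
    return [(t - k, k) for t in range(degree + 1) for k in range(t + 1)]


@dataclass(frozen=True)
class Normalization:
    """Affine map from pixel coordinates to conditioned fit coordinates.

    u = (x - center) / half, component-wise.
    """

    center: tuple[float, float]
    half: tuple[float, float]

    @classmethod
    def for_field(
        cls, field_dims: tuple[float, float], center: tuple[float, float] | None = None
    ) -> "Normalization":
        w, h = field_dims
        if w <= 1 or h <= 1:
            raise ValueError("field dimensions must exceed one pixel")
        if center is None:
            center = ((w - 1) / 2.0, (h - 1) / 2.0)
        return cls(center=(float(center[0]), float(center[1])),
                   half=((w - 1) / 2.0, (h - 1) / 2.0))

    def __call__(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return (p - np.asarray(self.center)) / np.asarray(self.half)


def design_matrix(points: np.ndarray, degree: int, norm: Normalization) -> np.ndarray:
    """Monomial design matrix (n_points, n_terms) on normalized coordinates."""
    u = norm(points)
    x, y = u[:, 0], u[:, 1]
    cols = [x**j * y**k for j, k in monomial_exponents(degree)]
    return np.column_stack(cols)


def n_terms(degree: int) -> int:
    return (degree + 1) * (degree + 2) // 2
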