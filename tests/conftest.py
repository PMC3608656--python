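import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import scanwarp as sw

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def basis_error(g_r, g_l, true_r, true_l) -> float:
    """Distance of a recovered basis pair from the true lattice generators.

    Equal-pitch lattices admit several equivalent generator pairs (for a
    60° lattice any two of {±a, ±b, ±(a-b)} at 60°/120°), so each recovered
    vector is compared to its nearest true generator, and the pair must
    preserve the cell area (|det|) so that it spans the same lattice.
    """
    a = np.asarray(true_r, float)
    b = np.asarray(true_l, float)
    cands = [a, -a, b, -b, a - b, b - a]
    err = 0.0
    for v in (np.asarray(g_r, float), np.asarray(g_l, float)):
        err = max(err, min(float(np.hypot(*(v - c))) for c in cands))
    det_true = abs(a[0] * b[1] - a[1] * b[0])
    det_rec = abs(g_r[0] * g_l[1] - g_r[1] * g_l[0])
    if abs(det_rec - det_true) > 0.05 * det_true:
        return float("inf")
    return err


@pytest.fixture
def hex5x5():
    """Noiseless 5x5 hexagonal lattice with its exact unit centers."""
    lat = sw.hex_lattice(5, 5, 40.0, origin=(80.0, 80.0))
    pts, labels = sw.generate_lattice_points(lat)
    return lat, pts, labels


@pytest.fixture
def hex5x5_image(hex5x5):
    lat, pts, labels = hex5x5
    extent = pts.max(axis=0) + 80.0
    dims = (int(np.ceil(extent[0])), int(np.ceil(extent[1])))
    img = sw.render_lattice_image(pts, lat.unit_side, dims, fg=1.0, bg=0.0)
    return lat, pts, labels, img
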