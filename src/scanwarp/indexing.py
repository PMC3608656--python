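"""Integer lattice coordinates by breadth-first traversal.

Starting from an anchor peak (the consensus peak nearest the centroid of
the consensus set — any choice works, this one is deterministic and keeps
later polynomial extrapolation centered), neighbors found within tolerance
of the four positions x ± g_r and x ± g_l are assigned column/row
coordinates differing by ±1, and the traversal continues until every
reachable peak is labelled.  The expected regular-pattern location of peak
i is then  y_i = x_0 + c_r,i * g_r + c_l,i * g_l.

Peaks reachable with two conflicting coordinate assignments indicate a
detection error and are excluded (not averaged); unreachable peaks are
excluded as well.  Both are reported with reason codes.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .detect import PeakSet
from .errors import IndexingError
from .latticefit import LatticeBasis


@dataclass(frozen=True)
class IndexedLattice:
    """Per-peak integer lattice coordinates and expected locations.

    ``peak_ids`` index into the original PeakSet; ``coords`` holds
    (c_r, c_l) per indexed peak; ``expected`` the y_i.
    """

    peak_ids: np.ndarray  # (N,) int
    points: np.ndarray  # (N, 2) measured x_i
    coords: np.ndarray  # (N, 2) int, columns (c_r, c_l)
    expected: np.ndarray  # (N, 2) y_i
    anchor_id: int  # peak id of x_0
    excluded: dict[int, str] = field(default_factory=dict)  # peak id -> reason


def assign_lattice_coords(
    peaks: PeakSet,
    basis: LatticeBasis,
    tol: float | None = None,
    anchor: int | None = None,
) -> IndexedLattice:
    """Traverse the consensus peaks and assign (c_r, c_l) to each.

    ``tol`` defaults to the RANSAC inlier tolerance carried by the basis.
    ``anchor`` may name a peak id to use as x_0; any choice only shifts all
    coordinates by a constant integer offset, the default is deterministic.
    """
    if tol is None:
        tol = basis.inlier_tol
    ids = np.asarray(basis.consensus_ids, int)
    if ids.size == 0:
        raise IndexingError("no consensus peaks to index")
    pts = peaks.points[ids]
    tree = cKDTree(pts)

    steps_probe = [basis.g_r, -basis.g_r, basis.g_l, -basis.g_l]

    def has_neighbor(i: int) -> bool:
        for g in steps_probe:
            d, j = tree.query(pts[i] + g)
            if d <= tol and int(j) != i:
                return True
        return False

    if anchor is None:
        # nearest-to-centroid consensus peak that is actually connected to
        # the lattice (a spurious consensus member may sit near the
        # centroid with no neighbors at the expected positions)
        centroid = pts.mean(axis=0)
        order = np.argsort(np.hypot(*(pts - centroid).T))
        anchor_local = -1
        for cand in order:
            if has_neighbor(int(cand)):
                anchor_local = int(cand)
                break
        if anchor_local < 0:
            raise IndexingError("no consensus peak has lattice neighbors within tol")
    else:
        matches = np.flatnonzero(ids == anchor)
        if matches.size == 0:
            raise IndexingError(f"anchor peak {anchor} is not in the consensus set")
        anchor_local = int(matches[0])

    steps = [
        (basis.g_r, (1, 0)),
        (-basis.g_r, (-1, 0)),
        (basis.g_l, (0, 1)),
        (-basis.g_l, (0, -1)),
    ]

    coords: dict[int, tuple[int, int]] = {anchor_local: (0, 0)}
    conflicts: set[int] = set()
    queue = deque([anchor_local])
    first = True
    while queue:
        i = queue.popleft()
        ci = coords[i]
        found_any = False
        for gvec, (dr, dl) in steps:
            d, j = tree.query(pts[i] + gvec)
            j = int(j)
            if d > tol or j == i:
                continue
            found_any = True
            new = (ci[0] + dr, ci[1] + dl)
            if j not in coords:
                coords[j] = new
                queue.append(j)
            elif coords[j] != new:
                conflicts.add(j)
        if first and not found_any:
            raise IndexingError("anchor peak has no lattice neighbors within tol")
        first = False

    excluded: dict[int, str] = {}
    for j in range(len(pts)):
        if j in conflicts:
            excluded[int(ids[j])] = "conflicting-coordinates"
        elif j not in coords:
            excluded[int(ids[j])] = "unreachable"
    keep = [j for j in sorted(coords) if j not in conflicts]

    coord_arr = np.array([coords[j] for j in keep], int)
    anchor_pt = pts[anchor_local]
    expected = anchor_pt + coord_arr[:, :1] * basis.g_r + coord_arr[:, 1:] * basis.g_l
    return IndexedLattice(
        peak_ids=ids[keep],
        points=pts[keep],
        coords=coord_arr,
        expected=expected,
        anchor_id=int(ids[anchor_local]),
        excluded=excluded,
    )


def refined_basis(indexed: IndexedLattice, template: LatticeBasis) -> LatticeBasis:
    """Generators re-estimated by regression over the indexed peaks.

    The closing refit of the RANSAC stage: with integer coordinates in
    hand, ``x_i ~ mu + c_r,i*g_r + c_l,i*g_l`` pools every indexed peak
    into the generator estimate instead of the consensus mean of local
    neighbor offsets.  Orientation follows the coordinate assignment (no
    canonicalization), so the generators stay consistent with ``coords``.
    """
    c = np.column_stack([indexed.coords.astype(float),
                         np.ones(len(indexed.coords))])
    beta, *_ = np.linalg.lstsq(c, indexed.points, rcond=None)
    return LatticeBasis(
        g_r=beta[0].copy(),
        g_l=beta[1].copy(),
        consensus_ids=template.consensus_ids,
        inlier_fraction=template.inlier_fraction,
        inlier_tol=template.inlier_tol,
    )


def refine_lattice(indexed: IndexedLattice) -> IndexedLattice:
    """Refit the generators over all indexed peaks and update the expected
    locations.

    The RANSAC basis is a mean of local neighbor offsets, so it carries the
    consensus sampling noise and any local warp gradient.  Regressing the
    measured locations on the integer coordinates,
    ``x_i ~ mu + c_r,i * g_r + c_l,i * g_l``, pools every peak into the
    generator estimate and makes the expected locations the best-fitting
    regular lattice in the image frame, which is the reference the
    distortion statistics are quoted against.
    """
    c = np.column_stack([indexed.coords.astype(float),
                         np.ones(len(indexed.coords))])
    beta, *_ = np.linalg.lstsq(c, indexed.points, rcond=None)
    expected = c @ beta
    return IndexedLattice(
        peak_ids=indexed.peak_ids,
        points=indexed.points,
        coords=indexed.coords,
        expected=expected,
        anchor_id=indexed.anchor_id,
        excluded=indexed.excluded,
    )
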