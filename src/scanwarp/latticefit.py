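"""Recovery of the lattice basis (g_r, g_l) from detected peaks.

Each detected unit location is paired with its nearest neighbor to form a
line segment; putative positions for a third point are constructed by
rotating that segment about the center by the expected inter-basis angles
(+60° and −120° for the hexagonal IC-chip pattern, ±90° for a square
grating), and the detection nearest the better putative position completes
a triplet.  The triplet encodes a candidate offset-vector pair
(g_right, g_left).  RANSAC then samples single triplets as lattice models;
a peak supports a model if some detection lies within tolerance of one of
its four expected neighbor positions x ± g_right, x ± g_left, and the
model with the largest consensus wins.  The final basis is the mean
sign-corrected offset pair over consensus triplets consistent with the
winning model.

A 60° equal-pitch lattice has six nearest neighbors, so the recovered pair
may be any valid 60° basis of the same lattice (e.g. (a, a−b) instead of
(a, b)); downstream indexing and distortion fitting are insensitive to
this choice because every such pair generates the same point set.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .detect import PeakSet
from .errors import InsufficientStructureError, ModelFailureError


@dataclass(frozen=True)
class Triplet:
    """Ordered trio (left, center, right) with its offset vectors."""

    center_id: int
    right_id: int
    left_id: int
    g_right: np.ndarray  # x_right - x_center, after sign correction
    g_left: np.ndarray


@dataclass(frozen=True)
class LatticeBasis:
    """Consensus offset vectors generating the regular pattern."""

    g_r: np.ndarray
    g_l: np.ndarray
    consensus_ids: np.ndarray  # peak indices in the consensus set
    inlier_fraction: float
    inlier_tol: float  # px; reused as the default indexing tolerance

    @property
    def mean_length(self) -> float:
        return 0.5 * (float(np.hypot(*self.g_r)) + float(np.hypot(*self.g_l)))


def _rot(deg: float) -> np.ndarray:
    t = math.radians(deg)
    return np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])


def _angle_between(v_from: np.ndarray, v_to: np.ndarray) -> float:
    """Signed angle (degrees) rotating v_from onto v_to."""
    cross = v_from[0] * v_to[1] - v_from[1] * v_to[0]
    dot = float(np.dot(v_from, v_to))
    return math.degrees(math.atan2(cross, dot))


def _angdiff(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def median_nn_distance(peaks: PeakSet) -> float:
    tree = cKDTree(peaks.points)
    d, _ = tree.query(peaks.points, k=2)
    return float(np.median(d[:, 1]))


def build_triplets(
    peaks: PeakSet,
    expected_angles: tuple[float, float] = (60.0, -120.0),
    angle_tol: float = 15.0,
) -> list[Triplet]:
    """Form one candidate triplet per peak where the geometry allows it.

    For peak x_i with nearest neighbor x_r, putative third-point positions
    are x_i + R(angle) (x_r - x_i) for each expected angle; the detection
    closest to the better putative position is accepted as x_l if it lies
    within ``angle_tol`` of an expected angle and within 1.5× the
    nearest-neighbor distance.  All triplets are sign-corrected so that
    g_right (and separately g_left) of every triplet points into a common
    half-plane, the first-formed triplet defining the reference.
    """
    pts = peaks.points
    if len(pts) < 3:
        raise InsufficientStructureError("need at least 3 peaks")
    tree = cKDTree(pts)
    nn_d, nn_i = tree.query(pts, k=2)

    rots = [_rot(a) for a in expected_angles]
    triplets: list[Triplet] = []
    ref_r: np.ndarray | None = None
    ref_l: np.ndarray | None = None
    for i in range(len(pts)):
        j = int(nn_i[i, 1])
        g_r = pts[j] - pts[i]
        # candidate third points at each expected angle; pick the putative
        # position whose nearest detection is closest
        best_k, best_d = -1, np.inf
        for rot in rots:
            putative = pts[i] + rot @ g_r
            d, k = tree.query(putative)
            if k in (i, j):
                continue
            if d < best_d:
                best_d, best_k = d, int(k)
        if best_k < 0:
            continue
        g_l = pts[best_k] - pts[i]
        ang = _angle_between(g_r, g_l)
        if min(_angdiff(ang, a) for a in expected_angles) > angle_tol:
            continue
        if np.hypot(*g_l) > 1.5 * nn_d[i, 1]:
            continue
        if ref_r is None:
            ref_r, ref_l = g_r, g_l
        else:
            if np.dot(g_r, ref_r) < 0:
                g_r = -g_r
            if np.dot(g_l, ref_l) < 0:
                g_l = -g_l
        triplets.append(
            Triplet(center_id=i, right_id=j, left_id=best_k, g_right=g_r, g_left=g_l)
        )
    if len(triplets) < 3:
        raise InsufficientStructureError(
            f"only {len(triplets)} triplets formed; need at least 3"
        )
    return triplets


def canonicalize_basis(g_r: np.ndarray, g_l: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic reporting form: each vector flipped to non-negative x
    (ties to positive y); g_r is the one with the larger x component
    (ties broken by larger y)."""
    vecs = []
    for v in (np.asarray(g_r, float), np.asarray(g_l, float)):
        if v[0] < 0 or (v[0] == 0 and v[1] < 0):
            v = -v
        vecs.append(v)
    a, b = vecs
    if (b[0], b[1]) > (a[0], a[1]):
        a, b = b, a
    return a, b


def _match_sign(v: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, float]:
    """Flip v toward ref; return (signed v, distance to ref)."""
    d_pos = float(np.hypot(*(v - ref)))
    d_neg = float(np.hypot(*(v + ref)))
    return (v, d_pos) if d_pos <= d_neg else (-v, d_neg)


def triplet_consensus_ransac(
    triplets: list[Triplet],
    peaks: PeakSet,
    inlier_tol: float | None = None,
    n_iter: int = 200,
    seed: int = 0,
) -> LatticeBasis:
    """RANSAC over sampled triplet models with the nearest-expected-neighbor
    certainty metric.

    Each iteration samples one triplet's (g_right, g_left) as the model.
    For each basis direction the uncertainty of peak x_j is the smallest
    distance from any detection to the expected neighbor positions
    x_j ± g_right (respectively x_j ± g_left); a peak joins the consensus
    when *both* directions are supported within ``inlier_tol``, and the
    largest consensus wins (first winner kept on ties, so results are
    deterministic for a given seed).  Requiring support along both axes —
    rather than any one of the four expected positions — keeps degenerate
    models with a single correct vector from certifying the whole pattern,
    which matters once spurious detections are common.  The returned basis is
    the mean of the consensus triplets' offset pairs after sign correction
    toward the winning model, in canonical orientation.

    ``inlier_tol`` defaults to 20% of the median nearest-neighbor distance.
    """
    if len(triplets) < 3:
        raise InsufficientStructureError("need at least 3 triplets")
    pts = peaks.points
    if inlier_tol is None:
        inlier_tol = 0.2 * median_nn_distance(peaks)
    tree = cKDTree(pts)
    rng = np.random.default_rng(seed)

    best_count = -1
    best_mask: np.ndarray | None = None
    best_model: tuple[np.ndarray, np.ndarray] | None = None
    for _ in range(n_iter):
        t = triplets[int(rng.integers(len(triplets)))]
        cand = np.concatenate(
            [pts + s * g for g in (t.g_right, t.g_left) for s in (1.0, -1.0)]
        )
        # the certainty metric looks for the *neighbor* nearest each
        # expected position: the peak itself must not count, or offset
        # vectors shorter than the tolerance would certify every peak
        d2, i2 = tree.query(cand, k=2)
        self_idx = np.tile(np.arange(len(pts)), 4)
        d = np.where(i2[:, 0] == self_idx, d2[:, 1], d2[:, 0])
        d = d.reshape(2, 2, len(pts))  # (axis, sign, peak)
        uncertainty = d.min(axis=1)  # per-axis certainty
        mask = (uncertainty <= inlier_tol).all(axis=0)
        count = int(mask.sum())
        if count > best_count:
            best_count, best_mask, best_model = count, mask, (t.g_right, t.g_left)

    if best_count <= 0 or best_mask is None or best_model is None:
        raise ModelFailureError("empty consensus set")

    # Mean offset pair over consensus triplets that agree with the winning
    # model (direct or swapped axis assignment, either sign).
    m_r, m_l = best_model
    acc_r, acc_l, n_acc = [], [], 0
    for t in triplets:
        if not best_mask[t.center_id]:
            continue
        direct_r, dr = _match_sign(t.g_right, m_r)
        direct_l, dl = _match_sign(t.g_left, m_l)
        swap_r, sr = _match_sign(t.g_left, m_r)
        swap_l, sl = _match_sign(t.g_right, m_l)
        if max(dr, dl) <= max(sr, sl):
            vr, vl, err = direct_r, direct_l, max(dr, dl)
        else:
            vr, vl, err = swap_r, swap_l, max(sr, sl)
        if err <= inlier_tol:
            acc_r.append(vr)
            acc_l.append(vl)
            n_acc += 1
    if n_acc == 0:  # fall back to the raw sampled model
        g_r, g_l = m_r, m_l
    else:
        g_r = np.mean(acc_r, axis=0)
        g_l = np.mean(acc_l, axis=0)
    g_r, g_l = canonicalize_basis(g_r, g_l)

    return LatticeBasis(
        g_r=g_r,
        g_l=g_l,
        consensus_ids=np.flatnonzero(best_mask),
        inlier_fraction=best_count / len(pts),
        inlier_tol=float(inlier_tol),
    )
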