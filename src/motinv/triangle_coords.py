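"""Symmetric triangle-shape coordinates and the closed-form rabs of a
Gaussian mixture.

A triangle with vertices A, B, C (side b = AC shortest, side c = AB
longest) is described by three numbers:

* ``drop``  = |a_v|, a_v = sqrt(3) * (centroid - B): the rescaled median
  vector from the vertex opposite the shortest side toward the centroid;
* ``short`` = |a_w|, a_w = A - C: the shortest-side vector, oriented toward
  the endpoint that belongs to the longest of the two remaining legs;
* ``theta``: the signed angle of a_v relative to a_w.

With this orientation rule a_v . a_w = (c^2 - a^2) / sqrt(3) >= 0, so
|theta| <= pi/2 always: every triangle shape has exactly one representative
in the asymmetric unit, the coordinates do not depend on the order in which
the vertices are presented, and mirroring the triangle flips only the sign
of theta.

The same scaled vectors arise naturally in the three-point function of a
mixture of N Gaussians of width R.  Writing the two displacement arguments
of b(r, s) in the symmetric combinations v = (r + s)/sqrt(3), w = r - s
diagonalises the three-Gaussian overlap, and the rotational average has the
closed form (per ordered vertex triple (j1, j2, j3), summed over all N^3):

    term = amp_j1 amp_j2 amp_j3 / (3 (2 pi R^2)^2)
           * exp( -((v - a_v)^2 + (w - a_w)^2) / (4 R^2) )
           * exp( -(v a_v + w a_w - A) / (2 R^2) ) * Ihat0( A / (2 R^2) )
    A^2  = v^2 a_v^2 + w^2 a_w^2
           + 2 v w a_v a_w cos(theta_a - theta_wv)

where a_v = sqrt(3)(mean of the triple - a_j1), a_w = a_j2 - a_j3, and
theta_a is the signed angle of a_v relative to a_w.  (The numerical
prefactors and Gaussian widths were derived by carrying out the Gaussian
integrals directly -- completing the square for the product of three atoms
gives exp(-(|e_r|^2+|e_s|^2-e_r.e_s)/(3R^2))/(3(2 pi R^2)^2) with
e_r = r - (a_j2 - a_j1), e_s = s - (a_j3 - a_j1), whose quadratic form
diagonalises to the two width-sqrt(2)R Gaussians above -- and are locked by
agreement with the brute-force grid pipeline in the test-suite.)  For small
R the landscape is a set of narrow bumps, one per triangle of the pattern,
at exactly the (drop, short, theta) coordinates above.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._conventions import signed_angle
from .patterns import PointPattern
from .two_point import i0_hat

__all__ = [
    "TriangleCoord",
    "triangle_coordinates",
    "enumerate_triangles",
    "rabs_closed_form",
    "rabs_closed_form_grid",
    "asymmetric_unit_boundary",
    "asymmetric_unit_check",
]

_SQRT3 = np.sqrt(3.0)


@dataclass(frozen=True)
class TriangleCoord:
    """(drop, short, signed angle) triple for one triangle.

    ``degenerate`` marks collinear or coincident vertices; ``tie`` marks an
    ambiguous shortest side or an isoceles leg tie, where the canonical
    choice below was applied.  ``vertices`` optionally records the indices
    of the pattern points that formed the triangle.
    """

    drop: float
    short: float
    theta: float
    degenerate: bool = False
    tie: bool = False
    vertices: tuple[int, int, int] | None = None


def _coord_for_base(pts: np.ndarray, b_idx: int, tol: float):
    """Coordinates taking side opposite vertex ``b_idx`` as the short side."""
    B = pts[b_idx]
    i, j = [m for m in range(3) if m != b_idx]
    P, Q = pts[i], pts[j]
    centroid = pts.mean(axis=0)
    a_v = _SQRT3 * (centroid - B)
    leg_P = np.linalg.norm(B - P)
    leg_Q = np.linalg.norm(B - Q)
    tie = False
    if abs(leg_P - leg_Q) <= tol * max(leg_P, leg_Q, 1e-300):
        tie = True
        # isoceles with shortest base: orient toward the lexicographically
        # larger vertex
        toward = P if tuple(P) >= tuple(Q) else Q
    else:
        toward = P if leg_P > leg_Q else Q
    away = Q if toward is P else P
    a_w = toward - away
    th = float(signed_angle(a_v, a_w))
    return float(np.linalg.norm(a_v)), float(np.linalg.norm(a_w)), th, tie


def triangle_coordinates(p1, p2, p3, tol: float = 1e-9) -> TriangleCoord:
    """Canonical (drop, short, theta) coordinates of a triangle.

    Invariant under any permutation of the vertices and any rigid motion;
    theta is negated by a reflection.  Shortest-side ties (isoceles /
    equilateral shapes, compared with relative tolerance ``tol``) are
    resolved toward the smallest |theta|, then toward theta >= 0, and
    flagged.  Coincident or collinear vertices set the ``degenerate`` flag.
    """
    pts = np.array([p1, p2, p3], dtype=float)
    if pts.shape != (3, 2) or not np.all(np.isfinite(pts)):
        raise ValueError("three finite 2D points are required")
    side = np.array(
        [
            np.linalg.norm(pts[1] - pts[2]),  # opposite vertex 0
            np.linalg.norm(pts[0] - pts[2]),  # opposite vertex 1
            np.linalg.norm(pts[0] - pts[1]),  # opposite vertex 2
        ]
    )
    scale = side.max()
    if scale <= 0.0:
        return TriangleCoord(0.0, 0.0, 0.0, degenerate=True, tie=True)
    u, v = pts[1] - pts[0], pts[2] - pts[0]
    area2 = abs(u[0] * v[1] - u[1] * v[0])  # twice the triangle area
    degenerate = area2 <= tol * scale**2 or side.min() <= tol * scale
    s_min = side.min()
    candidates = [m for m in range(3) if side[m] <= s_min * (1.0 + tol)]
    coords = [_coord_for_base(pts, m, tol) for m in candidates]
    tie = len(candidates) > 1 or any(c[3] for c in coords)
    # canonical pick: smallest |theta|, then nonnegative theta
    coords.sort(key=lambda c: (round(abs(c[2]) / tol) if tol else abs(c[2]), -c[2]))
    drop, short, th, _ = coords[0]
    if degenerate and abs(th) < np.deg2rad(90.0) * tol:
        th = 0.0
    return TriangleCoord(drop, short, th, degenerate=bool(degenerate), tie=bool(tie))


def enumerate_triangles(pattern: PointPattern) -> list[TriangleCoord]:
    """Coordinates of all C(N, 3) triangles formed by the pattern points."""
    if pattern.dim != 2:
        raise ValueError("triangle enumeration is 2D only")
    N = pattern.n_atoms
    if N < 3:
        raise ValueError("at least three points are required")
    out = []
    for i, j, k in itertools.combinations(range(N), 3):
        tc = triangle_coordinates(
            pattern.centers[i], pattern.centers[j], pattern.centers[k]
        )
        out.append(
            TriangleCoord(
                tc.drop, tc.short, tc.theta, tc.degenerate, tc.tie, (i, j, k)
            )
        )
    return out


# ---------------------------------------------------------------------------
# closed-form rabs in triangle coordinates


def rabs_closed_form(pattern: PointPattern, v, w, theta_wv) -> np.ndarray:
    """Closed-form rotationally averaged 3-point function of a Gaussian mixture.

    Arguments broadcast; the sum runs over all N^3 ordered vertex triples
    (including degenerate ones, which produce the self background near the
    v and w axes), so the result matches the grid pipeline
    ``rabs_real(rasterize(pattern))`` expressed in the skewed coordinates
    v = (r+s)/sqrt(3), w = r - s.
    """
    if pattern.dim != 2:
        raise ValueError("the closed form is implemented for D=2")
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    theta_wv = np.asarray(theta_wv, dtype=float)
    R = pattern.R
    R2 = R * R
    pref = 1.0 / (3.0 * (2.0 * np.pi * R2) ** 2)
    centers = pattern.centers
    amps = pattern.amplitudes
    N = pattern.n_atoms
    out = np.zeros(np.broadcast(v, w, theta_wv).shape)
    for j1 in range(N):
        for j2 in range(N):
            for j3 in range(N):
                mean = (centers[j1] + centers[j2] + centers[j3]) / 3.0
                av_vec = _SQRT3 * (mean - centers[j1])
                aw_vec = centers[j2] - centers[j3]
                av = np.linalg.norm(av_vec)
                aw = np.linalg.norm(aw_vec)
                th_a = (
                    float(signed_angle(av_vec, aw_vec)) if av > 0 and aw > 0 else 0.0
                )
                A2 = (
                    (v * av) ** 2
                    + (w * aw) ** 2
                    + 2.0 * v * w * av * aw * np.cos(th_a - theta_wv)
                )
                A = np.sqrt(np.clip(A2, 0.0, None))
                term = (
                    np.exp(-((v - av) ** 2 + (w - aw) ** 2) / (4.0 * R2))
                    * np.exp(-(v * av + w * aw - A) / (2.0 * R2))
                    * i0_hat(A / (2.0 * R2))
                )
                out += amps[j1] * amps[j2] * amps[j3] * term
    return pref * out


def rabs_closed_form_grid(
    pattern: PointPattern,
    v_vals: np.ndarray,
    w_vals: np.ndarray,
    thetas: np.ndarray,
):
    """Closed-form rabs evaluated on a full (v, w, theta) grid.

    Returns a :class:`motinv.three_point.RabsGrid` tagged ``space='real'``
    (the v/w lengths play the role of the two radial axes).
    """
    from .three_point import RabsGrid

    V = np.asarray(v_vals, float)[:, None, None]
    W = np.asarray(w_vals, float)[None, :, None]
    T = np.asarray(thetas, float)[None, None, :]
    vals = rabs_closed_form(pattern, V, W, T)
    return RabsGrid(
        np.asarray(v_vals, float),
        np.asarray(w_vals, float),
        np.asarray(thetas, float),
        vals,
        "real",
        {"coordinates": "(v, w, theta_wv)"},
    )


# ---------------------------------------------------------------------------
# asymmetric unit


def _vectorized_shape(pts: np.ndarray):
    """(ratio short/drop, theta) for a batch of generic triangles (n, 3, 2).

    Assumes a unique shortest side and no leg tie (measure-zero exceptions
    are irrelevant for the dense boundary scan this backs).
    """
    sides = np.stack(
        [
            np.linalg.norm(pts[:, 1] - pts[:, 2], axis=1),
            np.linalg.norm(pts[:, 0] - pts[:, 2], axis=1),
            np.linalg.norm(pts[:, 0] - pts[:, 1], axis=1),
        ],
        axis=1,
    )
    b_idx = np.argmin(sides, axis=1)
    n = len(pts)
    rows = np.arange(n)
    others = np.array([[1, 2], [0, 2], [0, 1]])[b_idx]
    B = pts[rows, b_idx]
    P = pts[rows, others[:, 0]]
    Q = pts[rows, others[:, 1]]
    centroid = pts.mean(axis=1)
    a_v = _SQRT3 * (centroid - B)
    legP = np.linalg.norm(B - P, axis=1)
    legQ = np.linalg.norm(B - Q, axis=1)
    toward_P = legP > legQ
    a_w = np.where(toward_P[:, None], P - Q, Q - P)
    th = signed_angle(a_v, a_w)
    ratio = np.linalg.norm(a_w, axis=1) / np.linalg.norm(a_v, axis=1)
    return ratio, th


@lru_cache(maxsize=4)
def asymmetric_unit_boundary(n_bins: int = 91, n_grid: int = 1200):
    """Empirical boundary max(short/drop) as a function of |theta|.

    Triangle shapes are scanned densely modulo similarity: the shortest side
    is pinned to A=(0,0), C=(1,0) and the apex B sweeps a grid over the
    region where AC remains shortest.  Returns (|theta| bin centres, maximal
    ratio per bin).  The equilateral shape attains ratio 1 at |theta|=pi/2;
    collinear shapes sit strictly inside at theta=0.
    """
    x = np.linspace(-4.0, 5.0, n_grid)
    y = np.linspace(1e-3, 6.0, n_grid)
    X, Y = np.meshgrid(x, y, indexing="ij")
    Bx, By = X.ravel(), Y.ravel()
    legA = np.hypot(Bx, By)
    legC = np.hypot(Bx - 1.0, By)
    keep = (legA >= 1.0) & (legC >= 1.0)
    pts = np.zeros((keep.sum(), 3, 2))
    pts[:, 1, 0] = 1.0  # C
    pts[:, 2, 0] = Bx[keep]
    pts[:, 2, 1] = By[keep]
    ratio, th = _vectorized_shape(pts)
    bins = np.linspace(0.0, np.pi / 2.0, n_bins + 1)
    idx = np.clip(np.digitize(np.abs(th), bins) - 1, 0, n_bins - 1)
    boundary = np.zeros(n_bins)
    np.maximum.at(boundary, idx, ratio)
    centers = 0.5 * (bins[:-1] + bins[1:])
    # guard against empty bins at the scan edges: borrow the neighbour max
    for i in range(1, n_bins):
        if boundary[i] == 0.0:
            boundary[i] = boundary[i - 1]
    for i in range(n_bins - 2, -1, -1):
        if boundary[i] == 0.0:
            boundary[i] = boundary[i + 1]
    return centers, boundary


def asymmetric_unit_check(tc: TriangleCoord, slack: float = 1.02):
    """Check that a TriangleCoord lies in the asymmetric unit.

    Verifies |theta| <= pi/2 and short/drop <= boundary(|theta|) against the
    empirically scanned boundary curve (with a small multiplicative slack
    for the finite scan).  Returns (ok, diagnostics dict).
    """
    if tc.degenerate and tc.drop == 0.0:
        return True, {"reason": "fully degenerate triangle", "ratio": 0.0}
    centers, boundary = asymmetric_unit_boundary()
    ratio = tc.short / tc.drop if tc.drop > 0 else np.inf
    bound = float(np.interp(abs(tc.theta), centers, boundary))
    ok_theta = abs(tc.theta) <= np.pi / 2.0 + 1e-12
    ok_ratio = ratio <= bound * slack
    diag = {
        "theta_ok": bool(ok_theta),
        "ratio": float(ratio),
        "bound": bound,
        "ratio_ok": bool(ok_ratio),
    }
    return bool(ok_theta and ok_ratio), diag
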