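"""Third-order motion invariants in 2D: bispectrum, RABS and rabs.

The bispectrum ``B(k, q) = F(k) F(q) F(-k-q)`` is translation invariant
because its three wavevectors sum to zero.  Averaging it over simultaneous
rotations of ``(k, q)`` gives the rotationally averaged bispectrum

    RABS(k, q, theta_qk) = < B(R_phi k, R_phi q) >_phi ,

a function of the two lengths and the signed angle between the vectors: the
resonance of the signal with Fourier triangles of a given shape.  Its
real-space sibling is the rotationally averaged three-point correlation

    rabs(r, s, theta_sr) = < b(R_phi r, R_phi s) >_phi ,
    b(r, s) = int f(t) f(t+r) f(t+s) dt ,

and the two are related by a closed transform whose kernel is a single J0:

    RABS(k, q, theta_qk) = 2 pi  int r s J0(X) rabs(r, s, theta_sr)
                           dr ds dtheta_sr ,
    X^2 = k^2 r^2 + q^2 s^2 + 2 k q r s cos(theta_qk - theta_sr).

Expanding the cosine, the argument contains the cross term
``2 (k x q).(r x s)`` which changes sign under a mirror of either space:
this is the term through which third-order invariants discriminate mirror
images (second-order invariants cannot).

Numerical notes
---------------
Off-grid wavevectors are handled by bilinear interpolation *of on-grid
bispectrum values* (16 neighbour pairs ``(k_i, q_j)``, each with
``k_i + q_j`` again on-grid).  Because every on-grid value is exactly
translation invariant, the interpolated RABS is exactly invariant under
integer-voxel translations, and exactly equivariant under 90-degree
rotations and mirrors of the input grid whenever the rotation-angle set is
a multiple of 4 and the theta grid is symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import trapezoid
from scipy.ndimage import map_coordinates
from scipy.special import j0

from .patterns import FourierSignal, GridSignal

__all__ = [
    "RabsGrid",
    "theta_grid",
    "bispectrum",
    "rabs_fourier",
    "three_point_function",
    "rabs_real",
    "rabs_kernel",
    "rabs_real_to_fourier",
    "mirror_map",
]


@dataclass
class RabsGrid:
    """RABS or rabs values over (length1, length2, signed angle).

    ``space='fourier'`` tags RABS(k, q, theta_qk); ``space='real'`` tags
    rabs(r, s, theta_sr).  ``theta`` lies in (-pi, pi]; the angle is the
    signed angle of the second vector relative to the first
    (:func:`motinv._conventions.signed_angle`).
    """

    L1: np.ndarray
    L2: np.ndarray
    theta: np.ndarray
    values: np.ndarray
    space: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.L1 = np.asarray(self.L1, dtype=float)
        self.L2 = np.asarray(self.L2, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.space not in ("real", "fourier"):
            raise ValueError("space must be 'real' or 'fourier'")
        expect = (len(self.L1), len(self.L2), len(self.theta))
        if self.values.shape != expect:
            raise ValueError(f"values shape {self.values.shape} != {expect}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")


def theta_grid(n: int) -> np.ndarray:
    """``n`` uniform angles in (-pi, pi], symmetric under negation (mod 2pi)."""
    if n % 2:
        raise ValueError("n must be even for a negation-symmetric grid")
    j = np.arange(n)
    return -np.pi + 2.0 * np.pi * (j + 1) / n


# ---------------------------------------------------------------------------
# bispectrum


def _as_vec2(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.shape[-1] != 2:
        raise ValueError("wavevectors must have a trailing axis of length 2")
    return a


def bispectrum(F: FourierSignal, k, q):
    """B(k, q) = F(k) F(q) F(-k-q), for 2-vectors or arrays of them.

    For off-grid wavevectors the value is a 4D bilinear interpolation of the
    on-grid bispectrum over the 16 neighbouring grid pairs; see the module
    docstring.  All three wavevectors must lie within the sampled band.
    """
    if F.dim != 2:
        raise ValueError("bispectrum is implemented for 2D spectra")
    kv, qv = np.broadcast_arrays(_as_vec2(k), _as_vec2(q))
    dk = F.kspacing
    n = F.values.shape[0]
    uk = kv / dk
    uq = qv / dk
    half = n // 2 - 1
    for u, name in ((uk, "k"), (uq, "q"), (uk + uq, "k+q")):
        lo = np.floor(u)
        if np.any(lo < -half) or np.any(lo + 1 > half):
            raise ValueError(f"wavevector {name} outside the sampled band")
    fk = np.floor(uk).astype(int)
    fq = np.floor(uq).astype(int)
    rk = uk - fk
    rq = uq - fq
    Fv = F.values
    out = np.zeros(kv.shape[:-1], dtype=complex)
    for dkx in (0, 1):
        wkx = rk[..., 0] if dkx else 1.0 - rk[..., 0]
        ikx = fk[..., 0] + dkx
        for dky in (0, 1):
            wk = wkx * (rk[..., 1] if dky else 1.0 - rk[..., 1])
            iky = fk[..., 1] + dky
            Fk = Fv[ikx % n, iky % n]
            for dqx in (0, 1):
                wqx = rq[..., 0] if dqx else 1.0 - rq[..., 0]
                iqx = fq[..., 0] + dqx
                for dqy in (0, 1):
                    w = wk * wqx * (rq[..., 1] if dqy else 1.0 - rq[..., 1])
                    iqy = fq[..., 1] + dqy
                    Fq = Fv[iqx % n, iqy % n]
                    Fkq = Fv[(-ikx - iqx) % n, (-iky - iqy) % n]
                    out += w * Fk * Fq * Fkq
    if out.ndim == 0:
        return complex(out)
    return out


def rabs_fourier(
    F: FourierSignal,
    k_vals: np.ndarray,
    q_vals: np.ndarray,
    thetas: np.ndarray,
    M: int = 256,
) -> RabsGrid:
    """Rotationally averaged bispectrum on a (k, q, theta) grid.

    For each triple the bispectrum is averaged over ``M`` equally spaced
    simultaneous rotations of the wavevector pair.  The imaginary part
    (round-off for spectra of real signals) is discarded; its maximum size
    relative to the modulus is recorded in ``meta['max_imag_ratio']``.
    """
    k_vals = np.asarray(k_vals, dtype=float)
    q_vals = np.asarray(q_vals, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    K = k_vals[:, None, None]
    Q = q_vals[None, :, None]
    T = thetas[None, None, :]
    acc = np.zeros((len(k_vals), len(q_vals), len(thetas)), dtype=complex)
    for phi in 2.0 * np.pi * np.arange(M) / M:
        kvec = np.stack(
            np.broadcast_arrays(K * np.cos(phi), K * np.sin(phi)), axis=-1
        )
        qvec = np.stack(
            np.broadcast_arrays(Q * np.cos(phi + T), Q * np.sin(phi + T)), axis=-1
        )
        acc += bispectrum(F, kvec, qvec)
    acc /= M
    scale = np.abs(acc).max()
    imag_ratio = 0.0 if scale == 0 else float(np.abs(acc.imag).max() / scale)
    meta = {"M": M, "max_imag_ratio": imag_ratio}
    return RabsGrid(k_vals, q_vals, thetas, acc.real, "fourier", meta)


# ---------------------------------------------------------------------------
# real-space route


def _shifted(f: GridSignal, shift_phys: np.ndarray) -> np.ndarray:
    """Sample f(t + shift) on the grid, bilinear with circular wrap."""
    n0, n1 = f.values.shape
    X, Y = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
    sx, sy = np.asarray(shift_phys, dtype=float) / f.spacing
    return map_coordinates(
        f.values, [X + sx, Y + sy], order=1, mode="grid-wrap", prefilter=False
    )


def three_point_function(f: GridSignal, r_vec, s_vec) -> float:
    """b(r, s) = int f(t) f(t+r) f(t+s) dt for one displacement pair.

    Exact (circular) for integer-voxel displacements; bilinear interpolation
    otherwise.  Quadratic in runtime, meant for oracles and spot checks.
    """
    if f.dim != 2:
        raise ValueError("three_point_function is 2D only")
    g_r = _shifted(f, np.asarray(r_vec))
    g_s = _shifted(f, np.asarray(s_vec))
    return float((f.values * g_r * g_s).sum() * f.spacing**2)


def rabs_real(
    f: GridSignal,
    r_vals: np.ndarray,
    s_vals: np.ndarray,
    thetas: np.ndarray,
    M: int = 64,
) -> RabsGrid:
    """Rotationally averaged three-point function on an (r, s, theta) grid.

    The average runs over ``M`` equally spaced rotation angles; every theta
    must be an integer multiple of 2 pi / M so that all shifted copies of
    the image can be shared across the average (a grid from
    :func:`theta_grid` with ``M % len(thetas) == 0`` qualifies).
    """
    if f.dim != 2:
        raise ValueError("rabs_real is 2D only")
    r_vals = np.asarray(r_vals, dtype=float)
    s_vals = np.asarray(s_vals, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    step = 2.0 * np.pi / M
    offsets = np.round(thetas / step).astype(int)
    if np.any(np.abs(thetas - offsets * step) > 1e-9):
        raise ValueError("every theta must be a multiple of 2*pi/M")
    offsets %= M

    n = f.values.shape[0]
    npix = n * n
    dirs = step * np.arange(M)
    cos_d, sin_d = np.cos(dirs), np.sin(dirs)

    def stack(lengths: np.ndarray) -> np.ndarray:
        S = np.empty((M, len(lengths), npix))
        for m in range(M):
            for i, ell in enumerate(lengths):
                S[m, i] = _shifted(
                    f, np.array([ell * cos_d[m], ell * sin_d[m]])
                ).ravel()
        return S

    S_r = stack(r_vals)
    S_s = S_r if np.array_equal(r_vals, s_vals) else stack(s_vals)
    A = f.values.ravel()[None, None, :] * S_r  # (M, nr, npix)
    nr, ns = len(r_vals), len(s_vals)
    # one GEMM gives all rotation pairs; the theta average is then a mean
    # over the circular diagonal m2 = m1 + offset
    C = A.reshape(M * nr, npix) @ S_s.reshape(M * ns, npix).T
    C = C.reshape(M, nr, M, ns)
    out = np.empty((nr, ns, len(thetas)))
    m1 = np.arange(M)
    for jt, off in enumerate(offsets):
        out[:, :, jt] = C[m1, :, (m1 + off) % M, :].mean(axis=0)
    out *= f.spacing**2
    meta = {"M": M, "n": n, "spacing": f.spacing}
    return RabsGrid(r_vals, s_vals, thetas, out, "real", meta)


# ---------------------------------------------------------------------------
# transform kernel and inter-space transform


def rabs_kernel(k, q, theta_qk, r, s, theta_sr) -> np.ndarray:
    """J0 kernel linking real- and Fourier-space third-order invariants.

    Ker = J0( sqrt( k^2 r^2 + q^2 s^2 + 2 k q r s cos(theta_qk - theta_sr) ) ),
    the average of e^{i(k.r' + q.s')} over joint rotations of (r, s).  The
    cosine combines the dot-dot and cross-cross terms; it is even in the
    *difference* of the two signed angles, so flipping the sign of one angle
    is exactly equivalent to flipping the other (mirror symmetry).  The
    radicand is clipped at zero against round-off.
    """
    k, q, r, s = (np.asarray(a, dtype=float) for a in (k, q, r, s))
    if np.any(k < 0) or np.any(q < 0) or np.any(r < 0) or np.any(s < 0):
        raise ValueError("lengths must be nonnegative")
    arg2 = (
        (k * r) ** 2
        + (q * s) ** 2
        + 2.0 * k * q * r * s * np.cos(np.asarray(theta_qk) - np.asarray(theta_sr))
    )
    return j0(np.sqrt(np.clip(arg2, 0.0, None)))


def rabs_real_to_fourier(
    rg: RabsGrid,
    k_vals: np.ndarray,
    q_vals: np.ndarray,
    k_thetas: np.ndarray,
) -> RabsGrid:
    """Transform a real-space rabs grid to Fourier-space RABS.

    RABS(k, q, th_qk) = 2 pi int r s J0(...) rabs(r, s, th_sr) dr ds dth_sr,
    trapezoid in r and s, periodic rectangle rule in theta (the theta grid
    must be uniform and cover 2 pi).  The 2 pi constant follows from the
    plain-mean rotational-average convention and is verified by the
    two-route consistency suite.  A non-decayed boundary is recorded as a
    warning in ``meta``.
    """
    if rg.space != "real":
        raise ValueError("input grid must be real-space rabs")
    r, s, ts = rg.L1, rg.L2, rg.theta
    dth = np.diff(ts)
    if len(ts) < 2 or not np.allclose(dth, dth[0]) or not np.isclose(
        len(ts) * dth[0], 2.0 * np.pi
    ):
        raise ValueError("theta grid must be uniform and cover 2*pi")

    def trap_w(x: np.ndarray) -> np.ndarray:
        w = np.zeros_like(x)
        w[:-1] += 0.5 * np.diff(x)
        w[1:] += 0.5 * np.diff(x)
        return w

    wr = trap_w(r) * r
    ws = trap_w(s) * s
    weighted = rg.values * wr[:, None, None] * ws[None, :, None] * dth[0]

    k_vals = np.asarray(k_vals, dtype=float)
    q_vals = np.asarray(q_vals, dtype=float)
    k_thetas = np.asarray(k_thetas, dtype=float)
    out = np.zeros((len(k_vals), len(q_vals), len(k_thetas)))
    K = k_vals[:, None, None, None, None]
    Q = q_vals[None, :, None, None, None]
    TH = k_thetas[None, None, :, None, None]
    Rg = r[None, None, None, :, None]
    Sg = s[None, None, None, None, :]
    for it, th_sr in enumerate(ts):
        ker = rabs_kernel(K, Q, TH, Rg, Sg, th_sr)
        out += np.einsum("abcrs,rs->abc", ker, weighted[:, :, it])
    out *= 2.0 * np.pi

    warnings = []
    peak = np.abs(rg.values).max()
    if peak > 0 and (
        np.abs(rg.values[-1]).max() > 1e-3 * peak
        or np.abs(rg.values[:, -1]).max() > 1e-3 * peak
    ):
        warnings.append("rabs grid has not decayed at its outer boundary")
    meta = {"warnings": warnings}
    return RabsGrid(k_vals, q_vals, k_thetas, out, "fourier", meta)


def mirror_map(rg: RabsGrid) -> RabsGrid:
    """Re-index theta -> -theta: the invariant grid of the mirrored signal.

    Requires a theta grid symmetric under negation modulo 2 pi (as produced
    by :func:`theta_grid`); applying the map twice is the identity.
    """
    ts = rg.theta
    perm = np.empty(len(ts), dtype=int)
    for j, th in enumerate(ts):
        target = -th
        diff = np.angle(np.exp(1j * (ts - target)))
        i = int(np.argmin(np.abs(diff)))
        if abs(diff[i]) > 1e-9:
            raise ValueError("theta grid is not symmetric about 0 (mod 2*pi)")
        perm[j] = i
    return RabsGrid(
        rg.L1, rg.L2, ts, rg.values[:, :, perm], rg.space, dict(rg.meta)
    )
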