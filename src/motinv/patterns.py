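"""Signal containers and synthetic pattern generators.

The package works with three kinds of objects:

* :class:`PointPattern` -- a punctate signal modelled as a sum of isotropic
  Gaussians ("atoms") of one common width ``R``.  This is the Wilson-type
  model under which all closed-form invariants in :mod:`motinv.two_point`
  and :mod:`motinv.triangle_coords` are derived.  Each atom is normalised to
  carry total mass equal to its amplitude.
* :class:`GridSignal` / :class:`FourierSignal` -- a real signal sampled on a
  regular grid and its discrete Fourier transform with the e^{+i k.r}
  convention, phases referenced to the *physical* origin (the voxel at index
  ``n//2`` along each axis), so centred even patterns have real spectra.
* :class:`PropellerVolume` -- the noisy 3D test volume used by the 4-point
  chirality scan: many copies of a 4-voxel single-turn helix dropped at
  random positions/cubic orientations into a cube, plus i.i.d. Gaussian
  noise.

Generators for the worked patterns (ring ``J0(r/R)``, angular harmonics
``cos(2m theta) J_{2m}(r/R)``, random propellers) also live here; they are
first-class tested code, not test fixtures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import j0, jv

__all__ = [
    "PointPattern",
    "GridSignal",
    "FourierSignal",
    "PropellerVolume",
    "rasterize",
    "fourier_transform",
    "fourier_transform_padded",
    "inverse_fourier_transform",
    "ring_pattern",
    "harmonic_pattern",
    "mirror_pattern",
    "mirror_signal",
    "rot90_signal",
    "translate_signal",
    "cubic_rotations",
    "helix_probe",
    "probe_voxels",
    "propeller_volume",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class PointPattern:
    """Sum of ``N`` isotropic Gaussian atoms of common width ``R``.

    Parameters
    ----------
    centers : (N, D) array of atom centres, in length units.
    R : common Gaussian width (standard deviation), ``R > 0``.
    amplitudes : per-atom total mass; default 1 for every atom.
    """

    centers: np.ndarray
    R: float
    amplitudes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.size == 0:
            self.centers = self.centers.reshape(0, 2)
        if self.centers.ndim != 2 or self.centers.shape[1] not in (2, 3):
            raise ValueError("centers must be an (N, D) array with D in {2, 3}")
        if not self.R > 0:
            raise ValueError("Gaussian width R must be positive")
        if self.amplitudes is None:
            self.amplitudes = np.ones(len(self.centers))
        else:
            self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.shape != (len(self.centers),):
            raise ValueError("amplitudes must have one entry per center")
        if not np.all(np.isfinite(self.amplitudes)) or not np.all(
            np.isfinite(self.centers)
        ):
            raise ValueError("centers and amplitudes must be finite")

    @property
    def dim(self) -> int:
        return self.centers.shape[1]

    @property
    def n_atoms(self) -> int:
        return len(self.centers)

    def pair_distances(self) -> np.ndarray:
        """Distances |a_i - a_j| for all i < j (sorted)."""
        diff = self.centers[:, None, :] - self.centers[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        iu = np.triu_indices(self.n_atoms, 1)
        return np.sort(d[iu])


@dataclass
class GridSignal:
    """Real D-dimensional signal on a regular grid.

    The physical coordinate of voxel index ``j`` along each axis is
    ``(j - origin) * spacing``; by convention ``origin = n // 2``.
    """

    values: np.ndarray
    spacing: float
    origin: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if self.origin is None:
            self.origin = tuple(n // 2 for n in self.values.shape)
        self.origin = tuple(int(o) for o in self.origin)
        for o, n in zip(self.origin, self.values.shape):
            if not 0 <= o < n:
                raise ValueError("origin must lie inside the array extent")

    @property
    def dim(self) -> int:
        return self.values.ndim

    def axis_coords(self) -> list[np.ndarray]:
        """Physical coordinates along each axis."""
        return [
            (np.arange(n) - o) * self.spacing
            for n, o in zip(self.values.shape, self.origin)
        ]

    def radius_grid(self) -> np.ndarray:
        """Radial distance of every voxel from the physical origin."""
        ax = self.axis_coords()
        grids = np.meshgrid(*ax, indexing="ij")
        return np.sqrt(sum(g**2 for g in grids))


@dataclass
class FourierSignal:
    """Discrete Fourier transform (e^{+i k.r} convention) of a GridSignal.

    ``values`` is complex, laid out in ``numpy.fft`` frequency order; the
    wavevector of entry ``m`` along each axis is ``2*pi*fftfreq(n, spacing)``.
    ``spacing`` and ``origin`` describe the real-space grid the transform
    came from, so the inverse transform is well defined.
    """

    values: np.ndarray
    spacing: float
    origin: tuple[int, ...]
    sign: int = +1  # sign of the exponent in the forward transform

    @property
    def dim(self) -> int:
        return self.values.ndim

    @property
    def kspacing(self) -> float:
        n = self.values.shape[0]
        if any(m != n for m in self.values.shape):
            raise ValueError("kspacing is only scalar for square grids")
        return 2.0 * np.pi / (n * self.spacing)

    def k_axes(self) -> list[np.ndarray]:
        return [
            2.0 * np.pi * np.fft.fftfreq(n, d=self.spacing)
            for n in self.values.shape
        ]

    def k_radius_grid(self) -> np.ndarray:
        grids = np.meshgrid(*self.k_axes(), indexing="ij")
        return np.sqrt(sum(g**2 for g in grids))

    def conjugate_symmetry_error(self) -> float:
        """max |F(-k) - conj F(k)| / max|F|; ~0 for transforms of real input."""
        flipped = self.values.copy()
        for ax in range(self.dim):
            flipped = np.flip(flipped, axis=ax)
            flipped = np.roll(flipped, 1, axis=ax)
        denom = np.abs(self.values).max()
        if denom == 0:
            return 0.0
        return float(np.abs(flipped - np.conj(self.values)).max() / denom)


# ---------------------------------------------------------------------------
# Fourier transform plumbing


def fourier_transform(signal: GridSignal) -> FourierSignal:
    """Discrete approximation of F(k) = int f(r) e^{+i k.r} dr.

    Phases are referenced to the physical origin voxel, i.e. the factor
    ``e^{+i k.r_j}`` uses ``r_j = (j - origin) * spacing``.  Implemented
    exactly (to round-off) by circularly shifting the origin voxel to index
    0 and scaling an inverse FFT; round-trips with
    :func:`inverse_fourier_transform` to ~1e-15.
    """
    f = signal.values
    axes = tuple(range(f.ndim))
    shifted = np.roll(f, tuple(-o for o in signal.origin), axis=axes)
    scale = signal.spacing**f.ndim * np.prod(f.shape)
    vals = np.fft.ifftn(shifted) * scale
    return FourierSignal(
        values=vals, spacing=signal.spacing, origin=signal.origin, sign=+1
    )


def inverse_fourier_transform(F: FourierSignal, warn_tol: float = 1e-8):
    """Inverse of :func:`fourier_transform`; returns a real GridSignal.

    The imaginary residue (nonzero only through round-off for spectra of
    real signals) is discarded; its maximum relative size is returned in
    the signal's ``meta`` through the second return value.
    """
    vals = np.fft.fftn(F.values)
    axes = tuple(range(vals.ndim))
    vals = np.roll(vals, F.origin, axis=axes)
    scale = (F.spacing * np.asarray(F.values.shape)).prod()
    vals = vals / scale
    denom = np.abs(vals).max()
    imag_ratio = 0.0 if denom == 0 else float(np.abs(vals.imag).max() / denom)
    return GridSignal(vals.real, F.spacing, F.origin), imag_ratio


def fourier_transform_padded(signal: GridSignal, pad: int) -> FourierSignal:
    """Fourier transform on a ``pad``-times finer wavevector grid.

    Zero-pads the physical box by ``pad`` along each axis (preserving the
    sample positions relative to the origin), so the returned values are
    *exact* samples of the same discrete-time Fourier transform on a grid
    ``pad`` times finer.  All exactness properties of the on-grid spectrum
    (translation phases, closure under wavevector addition, 90-degree
    rotations) carry over; downstream interpolation error drops ~pad^-2.
    The returned signal's real-space origin is index 0.
    """
    if pad < 1 or int(pad) != pad:
        raise ValueError("pad must be a positive integer")
    shape = signal.values.shape
    big_shape = tuple(pad * n for n in shape)
    big = np.zeros(big_shape)
    idx = [
        (np.arange(n) - o) % N
        for n, o, N in zip(shape, signal.origin, big_shape)
    ]
    big[np.ix_(*idx)] = signal.values
    scale = signal.spacing ** signal.dim * np.prod(big_shape)
    vals = np.fft.ifftn(big) * scale
    return FourierSignal(
        values=vals,
        spacing=signal.spacing,
        origin=tuple(0 for _ in shape),
        sign=+1,
    )


def translate_signal(signal: GridSignal, shift: tuple[int, ...]) -> GridSignal:
    """Circularly translate by an integer number of voxels (exact)."""
    vals = np.roll(signal.values, shift, axis=tuple(range(signal.dim)))
    return GridSignal(vals, signal.spacing, signal.origin)


def rot90_signal(signal: GridSignal) -> GridSignal:
    """Rotate a 2D signal by +90 degrees about its physical origin voxel.

    This is an exact permutation of voxels: the new value at physical
    coordinates (x, y) is the old value at (y, -x), with circular wrap.
    (``numpy.rot90`` rotates about the array centre, which for even n is
    half a voxel away from the physical origin.)
    """
    if signal.dim != 2:
        raise ValueError("rot90_signal is 2D only")
    n0, n1 = signal.values.shape
    c0, c1 = signal.origin
    i, j = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
    # (x, y) -> pull from old point (y, -x)
    src0 = (c0 + (j - c1)) % n0
    src1 = (c1 - (i - c0)) % n1
    return GridSignal(signal.values[src0, src1], signal.spacing, signal.origin)


def mirror_signal(signal: GridSignal, axis: int = 1) -> GridSignal:
    """Reflect a signal across the hyperplane through the origin normal to ``axis``."""
    n = signal.values.shape[axis]
    c = signal.origin[axis]
    idx = (2 * c - np.arange(n)) % n
    vals = np.take(signal.values, idx, axis=axis)
    return GridSignal(vals, signal.spacing, signal.origin)


# ---------------------------------------------------------------------------
# pattern generators


def rasterize(pattern: PointPattern, n: int, spacing: float) -> GridSignal:
    """Sample a Gaussian mixture on an ``n^D`` grid of step ``spacing``.

    Each atom contributes ``amp * exp(-|r-a|^2 / 2R^2) / (2 pi R^2)^{D/2}``
    so its integrated mass equals its amplitude.  All centres must fall
    inside the physical box.
    """
    D = pattern.dim
    origin = tuple(n // 2 for _ in range(D))
    lo = -(n // 2) * spacing
    hi = (n - 1 - n // 2) * spacing
    for c in pattern.centers:
        if np.any(c < lo) or np.any(c > hi):
            raise ValueError(
                f"center {tuple(c)} lies outside the physical box [{lo}, {hi}]^{D}"
            )
    ax = [(np.arange(n) - n // 2) * spacing for _ in range(D)]
    grids = np.meshgrid(*ax, indexing="ij")
    vals = np.zeros((n,) * D)
    norm = (2.0 * np.pi * pattern.R**2) ** (D / 2.0)
    for c, a in zip(pattern.centers, pattern.amplitudes):
        r2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        vals += a * np.exp(-r2 / (2.0 * pattern.R**2)) / norm
    return GridSignal(vals, spacing, origin)


def _edge_apodization(signal_shape: tuple[int, ...], spacing: float) -> np.ndarray:
    """Raised-cosine window over the outer 10% of the inscribed box radius."""
    n = signal_shape[0]
    ax = [(np.arange(m) - m // 2) * spacing for m in signal_shape]
    grids = np.meshgrid(*ax, indexing="ij")
    r = np.sqrt(sum(g**2 for g in grids))
    r_max = (n // 2) * spacing
    r_in = 0.9 * r_max
    w = np.ones_like(r)
    band = (r > r_in) & (r < r_max)
    w[band] = 0.5 * (1.0 + np.cos(np.pi * (r[band] - r_in) / (r_max - r_in)))
    w[r >= r_max] = 0.0
    return w


def ring_pattern(R: float, n: int, spacing: float) -> GridSignal:
    """2D pattern f(r) = J0(r / R): Fourier support concentrated on |k| = 1/R.

    The sampled image is apodized by a raised cosine over the outer 10% of
    the box radius (J0 decays only like r^{-1/2}, so a hard truncation would
    ring).  Raises if the ring radius 1/R is at or above Nyquist.
    """
    k_ring = 1.0 / R
    if k_ring >= np.pi / spacing:
        raise ValueError("ring radius 1/R is not below the Nyquist wavenumber")
    ax = (np.arange(n) - n // 2) * spacing
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2)
    vals = j0(r / R) * _edge_apodization((n, n), spacing)
    return GridSignal(vals, spacing, (n // 2, n // 2))


def harmonic_pattern(m: int, R: float, n: int, spacing: float) -> GridSignal:
    """2D angular harmonic f(r, theta) = cos(2 m theta) J_{2m}(r / R).

    These patterns share the ring pattern's Fourier support |k| = 1/R but
    carry a pure angular harmonic of order 2m; their rotationally averaged
    bispectrum vanishes identically in the continuum.
    """
    if m < 1 or int(m) != m:
        raise ValueError("m must be a positive integer")
    k_ring = 1.0 / R
    if k_ring >= np.pi / spacing:
        raise ValueError("ring radius 1/R is not below the Nyquist wavenumber")
    ax = (np.arange(n) - n // 2) * spacing
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2)
    theta = np.arctan2(Y, X)
    vals = np.cos(2 * m * theta) * jv(2 * m, r / R)
    vals *= _edge_apodization((n, n), spacing)
    return GridSignal(vals, spacing, (n // 2, n // 2))


def mirror_pattern(pattern: PointPattern, axis: int = 0) -> PointPattern:
    """Reflect all centres across the hyperplane normal to coordinate ``axis``.

    Width and amplitudes are unchanged; applying the same mirror twice
    returns the original pattern.
    """
    if not 0 <= axis < pattern.dim:
        raise ValueError(f"axis {axis} invalid for dimension {pattern.dim}")
    centers = pattern.centers.copy()
    centers[:, axis] *= -1.0
    return PointPattern(centers, pattern.R, pattern.amplitudes.copy())


# ---------------------------------------------------------------------------
# propeller volumes (3D, 4-point helix test objects)


def cubic_rotations() -> list[np.ndarray]:
    """The 24 proper rotations of the cube as integer matrices (det = +1)."""
    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            M = np.zeros((3, 3), dtype=int)
            for row, (p, s) in enumerate(zip(perm, signs)):
                M[row, p] = s
            if round(np.linalg.det(M)) == 1:
                mats.append(M)
    assert len(mats) == 24
    return mats


def helix_probe(radius: float, pitch: float) -> np.ndarray:
    """Four points on one turn of a helix about z, centred at their centroid.

    Point ``k`` (k = 0..3) sits at azimuth ``k*pi/2`` on a circle of the
    given radius, at height ``k*pitch/4``.  The sign of ``pitch`` is the
    handedness: negating it mirrors the stencil through the xy-plane.
    """
    if not radius > 0:
        raise ValueError("radius must be positive (radius=0 is a collinear stencil)")
    k = np.arange(4)
    pts = np.stack(
        [
            radius * np.cos(np.pi * k / 2.0),
            radius * np.sin(np.pi * k / 2.0),
            pitch * k / 4.0,
        ],
        axis=1,
    )
    return pts - pts.mean(axis=0)


def probe_voxels(radius: float, pitch: float) -> np.ndarray:
    """Helix probe rounded to the nearest voxel (integer offsets).

    Rounding is half-up (floor(x + 1/2)), not banker's rounding, so the
    stencil is reproducible across platforms.  The same rounded stencil is
    used by the volume generator and by the scan, so a noise-free probe
    matches an inserted propeller voxel-for-voxel.
    """
    return np.floor(helix_probe(radius, pitch) + 0.5).astype(int)


@dataclass
class PropellerVolume:
    """A cube of propellers-plus-noise and the ground truth that made it."""

    values: np.ndarray
    truth: dict = field(default_factory=dict)

    @property
    def box(self) -> int:
        return self.values.shape[0]


def propeller_volume(
    n_copies: int = 100,
    box: int = 32,
    radius: float = 2.0,
    pitch: float = 4.0,
    noise_sigma: float = 0.45,
    seed: int | None = None,
) -> PropellerVolume:
    """Insert ``n_copies`` 4-point helical propellers into a ``box^3`` volume.

    Each copy is the rounded helix stencil rotated by one of the 24 cubic
    rotations (uniform) and placed at a uniform random integer translation
    that keeps all four points inside the box; its voxels are *assigned*
    value 1 (collisions with already-set voxels are counted in
    ``truth['collisions']``).  I.i.d. Gaussian noise of standard deviation
    ``noise_sigma`` is then added to every voxel.  A seed is mandatory for
    reproducibility: the same seed yields a bit-identical volume.
    """
    if seed is None:
        raise ValueError("seed is mandatory for propeller_volume")
    rng = np.random.default_rng(seed)
    rots = cubic_rotations()
    base = probe_voxels(radius, pitch)
    span = base.max(axis=0) - base.min(axis=0)
    if np.any(span >= box):
        raise ValueError("probe does not fit in the box")
    vol = np.zeros((box, box, box))
    collisions = 0
    for _ in range(n_copies):
        Q = rots[rng.integers(len(rots))]
        off = base @ Q.T
        lo = off.min(axis=0)
        hi = off.max(axis=0)
        t = np.array([rng.integers(-l, box - h) for l, h in zip(lo, hi)])
        for o in off:
            p = tuple(t + o)
            if vol[p] == 1.0:
                collisions += 1
            vol[p] = 1.0
    if noise_sigma > 0:
        vol = vol + noise_sigma * rng.standard_normal(vol.shape)
    truth = {
        "radius": radius,
        "pitch": pitch,
        "n_copies": n_copies,
        "noise_sigma": noise_sigma,
        "seed": seed,
        "collisions": collisions,
    }
    return PropellerVolume(vol, truth)
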