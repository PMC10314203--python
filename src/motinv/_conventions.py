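"""Shared geometric conventions.

Every rotational average in this package is a *plain mean over directions*
(no surface-area prefactors), so that the same constant conventions cancel
in all transform round trips.  The one signed-angle convention used by both
the bispectrum grids and the triangle coordinates lives here.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gamma

__all__ = ["sphere_surface_area", "signed_angle", "rotation_matrix_2d"]


def sphere_surface_area(dim: int) -> float:
    """Surface area Omega_D of the unit sphere S^{D-1} embedded in R^D.

    Omega_2 = 2*pi (circle), Omega_3 = 4*pi, Omega_4 = 2*pi**2.
    """
    return float(2.0 * np.pi ** (dim / 2.0) / gamma(dim / 2.0))


def signed_angle(u: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Signed angle by which ``ref`` must be rotated counterclockwise to reach ``u``.

    Both arguments are 2-vectors (last axis of length 2); broadcasting over
    leading axes is supported.  The result lies in (-pi, pi].  Under a
    reflection of the plane the cross product flips sign while the dot
    product is preserved, so the angle is negated -- this is the single
    convention through which "mirroring = angle sign flip" enters the
    package.
    """
    u = np.asarray(u, dtype=float)
    ref = np.asarray(ref, dtype=float)
    cross = ref[..., 0] * u[..., 1] - ref[..., 1] * u[..., 0]
    dot = ref[..., 0] * u[..., 0] + ref[..., 1] * u[..., 1]
    return np.arctan2(cross, dot)


def rotation_matrix_2d(phi: float) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, -s], [s, c]])
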