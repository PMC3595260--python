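"""Surface Laplacian (current source density) by spherical splines.

The scalp potential is interpolated on a sphere with spherical splines:
the interpolant is ``U(E) = c0 + sum_i c_i g(cos(E, E_i))`` where

    g(x) = (1/4pi) sum_{n=1..n_max} (2n+1) / (n (n+1))**m  P_n(x)

with ``P_n`` the Legendre polynomials and ``m`` the spline stiffness.
The surface Laplacian of each kernel term follows from the eigenfunction
property of spherical harmonics (the Laplace-Beltrami operator multiplies
degree-n terms by ``-n(n+1)/r**2``), giving the companion kernel

    h(x) = (1/4pi) sum_{n=1..n_max} (2n+1) / (n (n+1))**(m-1)  P_n(x).

The CSD reported here is the *negative* surface Laplacian of the
interpolant, ``(1/r**2) sum_i c_i h(cos(E, E_i))``, so that a focal
source under an electrode appears positive.  Units are µV/cm² and the
transform is reference-free (adding a constant to all channels changes
nothing).  Defaults: stiffness m=3, n_max=15 Legendre terms, head radius
10 cm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import eval_legendre

from .containers import Evoked
from .montage import Montage

__all__ = ["SplineConfig", "spline_kernels", "csd_transform"]


@dataclass(frozen=True)
class SplineConfig:
    """Spherical-spline parameters.

    m : spline stiffness order (>= 2)
    n_max : maximum Legendre degree in the kernel series
    r_head_cm : sphere radius in cm (affects only the 1/r**2 scale)
    smoothing : Tikhonov term added to the spline system diagonal
    """

    m: int = 3
    n_max: int = 15
    r_head_cm: float = 10.0
    smoothing: float = 1e-5

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("spline stiffness m must be >= 2")
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.r_head_cm <= 0:
            raise ValueError("r_head_cm must be positive")
        if self.smoothing < 0:
            raise ValueError("smoothing must be >= 0")


def spline_kernels(cos_theta, cfg: SplineConfig = SplineConfig()):
    """Evaluate the spline kernels g and h at ``cos_theta``.

    Parameters
    ----------
    cos_theta : scalar or array in [-1, 1]
        Cosine of the angular distance between two points on the sphere.
    cfg : SplineConfig

    Returns
    -------
    (g, h) : ndarrays (or scalars) of the interpolation kernel and its
        Laplacian companion kernel.
    """
    x = np.asarray(cos_theta, float)
    if np.any(np.abs(x) > 1.0 + 1e-12):
        raise ValueError("cos_theta must lie in [-1, 1]")
    x = np.clip(x, -1.0, 1.0)
    g = np.zeros_like(x)
    h = np.zeros_like(x)
    for n in range(1, cfg.n_max + 1):
        Pn = eval_legendre(n, x)
        denom = (n * (n + 1.0)) ** cfg.m
        g += (2 * n + 1.0) / denom * Pn
        h += (2 * n + 1.0) / ((n * (n + 1.0)) ** (cfg.m - 1)) * Pn
    g /= 4.0 * np.pi
    h /= 4.0 * np.pi
    if np.isscalar(cos_theta):
        return float(g), float(h)
    return g, h


def _solve_coefficients(G: np.ndarray, v: np.ndarray, smoothing: float):
    """Solve the spline system with the mean-constraint row.

    [[G + lambda I, 1], [1', 0]] [c; c0] = [v; 0]
    """
    n = G.shape[0]
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = G + smoothing * np.eye(n)
    M[:n, n] = 1.0
    M[n, :n] = 1.0
    rhs = np.zeros((n + 1,) + v.shape[1:])
    rhs[:n] = v
    try:
        sol = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular spline system: duplicate or colinear electrodes?"
        ) from err
    return sol[:n], sol[n]


def csd_transform(
    ev: Evoked,
    montage: Montage,
    cfg: SplineConfig = SplineConfig(),
) -> Evoked:
    """Current source density of an averaged waveform.

    Scalp channels are interpolated with spherical splines and the
    negative surface Laplacian is evaluated at the same electrodes; the
    result keeps the input time axis with units µV/cm².  Non-scalp (EOG)
    channels are dropped from the output.
    """
    scalp = ev.picks("eeg")
    if scalp.size < 8:
        raise ValueError("need at least 8 scalp channels for the CSD")
    labels = [ev.ch_names[i] for i in scalp]
    try:
        pos = np.stack([montage.positions[montage.index(c)] for c in labels])
    except KeyError as err:
        raise ValueError(f"channel missing from montage: {err}") from err
    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    if np.any(cosang[~np.eye(len(labels), dtype=bool)] > 1.0 - 1e-12):
        raise ValueError("singular spline system: duplicate electrode positions")
    G, H = spline_kernels(cosang, cfg)
    v = ev.data[scalp]  # (n_scalp, n_times)
    c, _c0 = _solve_coefficients(G, v, cfg.smoothing)
    csd = (H @ c) / cfg.r_head_cm**2
    return Evoked(
        data=csd, times_ms=ev.times_ms.copy(), fs=ev.fs, lock=ev.lock,
        nave=ev.nave, ch_names=labels, ch_types=["eeg"] * len(labels),
        units="uV/cm^2",
    )
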