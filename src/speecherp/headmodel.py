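"""Three-shell concentric-sphere volume conductor and dipole forward fields.

The head is modeled as three concentric spherical shells (brain, skull,
scalp).  For a current dipole inside the innermost shell, the scalp
potential is expanded in Legendre harmonics; within every shell the radial
part of each degree-``n`` harmonic is ``A r**n + B r**(-n-1)``, so the
boundary-value problem (continuity of potential and of radial current at
the two inner interfaces, vanishing radial current at the scalp surface)
reduces to a small linear system per degree.  This keeps the model honest
for arbitrary shell radii/conductivities instead of hard-coding a closed
form.

Units: electrode/dipole geometry in cm, conductivities in S/m, dipole
moments in nAm, potentials in µV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HeadModel", "forward_gain", "forward_matrix"]

_N_TERMS = 60  # series truncation; terms decay like (b / r_brain)**n


@dataclass(frozen=True)
class HeadModel:
    """Concentric three-shell conductor.

    Parameters
    ----------
    radii_frac : tuple of float
        Outer radius of each shell as a fraction of the head radius,
        strictly increasing, last equal to 1 (brain, skull, scalp).
    conductivities : tuple of float
        Conductivity of each shell in S/m.  The default 1:1/80:1 ratio is
        the textbook skull-to-soft-tissue contrast.
    r_head_cm : float
        Scalp sphere radius in cm.
    """

    radii_frac: tuple = (0.87, 0.92, 1.0)
    conductivities: tuple = (0.33, 0.33 / 80.0, 0.33)
    r_head_cm: float = 10.0

    def __post_init__(self):
        r = np.asarray(self.radii_frac, float)
        s = np.asarray(self.conductivities, float)
        if r.shape != s.shape or r.ndim != 1 or r.size < 2:
            raise ValueError("need matching radii and conductivities (>= 2 shells)")
        if not np.all(np.diff(r) > 0):
            raise ValueError("shell radii must be strictly increasing")
        if not np.all(s > 0):
            raise ValueError("conductivities must be positive")
        if not self.r_head_cm > 0:
            raise ValueError("r_head_cm must be positive")

    @property
    def radii_cm(self) -> np.ndarray:
        return np.asarray(self.radii_frac, float) * self.r_head_cm

    @property
    def brain_radius_cm(self) -> float:
        return float(self.radii_cm[0])


def _shell_transfer(head: HeadModel, n_terms: int) -> np.ndarray:
    """Per-degree surface transfer coefficients.

    For each harmonic degree ``n`` return ``S_n`` such that a primary
    (infinite-medium) potential term ``rho**(-n-1)`` sourced in the
    innermost shell produces the surface potential ``S_n`` at the scalp.
    Radii are normalized to the scalp radius (Laplace's equation is
    scale-invariant), which keeps the linear systems well-conditioned; the
    physical 1/R**2 scale is restored by the caller.
    """
    radii = np.asarray(head.radii_frac, float)
    sig = np.asarray(head.conductivities, float)
    n_shells = radii.size
    out = np.empty(n_terms + 1)
    out[0] = 0.0
    for n in range(1, n_terms + 1):
        # unknowns: A_1, (A_i, B_i) for i = 2..n_shells
        n_unk = 1 + 2 * (n_shells - 1)
        M = np.zeros((n_unk, n_unk))
        rhs = np.zeros(n_unk)

        def a_cols(i):  # column indices of (A_i, B_i); B_1 is the source term
            return (0, None) if i == 0 else (1 + 2 * (i - 1), 2 + 2 * (i - 1))

        row = 0
        for i in range(n_shells - 1):  # interface between shell i and i+1
            r = radii[i]
            ai, bi = a_cols(i)
            aj, bj = a_cols(i + 1)
            # potential continuity
            M[row, ai] += r**n
            M[row, aj] -= r**n
            M[row, bj] -= r ** (-n - 1)
            if bi is not None:
                M[row, bi] += r ** (-n - 1)
            else:
                rhs[row] -= r ** (-n - 1)  # primary source term (coef 1)
            row += 1
            # radial current continuity: sigma * dV/dr
            M[row, ai] += sig[i] * n * r ** (n - 1)
            M[row, aj] -= sig[i + 1] * n * r ** (n - 1)
            M[row, bj] += sig[i + 1] * (n + 1) * r ** (-n - 2)
            if bi is not None:
                M[row, bi] -= sig[i] * (n + 1) * r ** (-n - 2)
            else:
                rhs[row] += sig[i] * (n + 1) * r ** (-n - 2)
            row += 1
        # outer boundary: no radial current
        r = radii[-1]
        aN, bN = a_cols(n_shells - 1)
        M[row, aN] = n * r ** (n - 1)
        M[row, bN] = -(n + 1) * r ** (-n - 2)
        sol = np.linalg.solve(M, rhs)
        aN_v = sol[aN]
        bN_v = sol[bN]
        out[n] = aN_v * r**n + bN_v * r ** (-n - 1)
    return out


_TRANSFER_CACHE: dict = {}


def _transfer(head: HeadModel) -> np.ndarray:
    key = (head.radii_frac, head.conductivities, head.r_head_cm)
    if key not in _TRANSFER_CACHE:
        _TRANSFER_CACHE[key] = _shell_transfer(head, _N_TERMS)
    return _TRANSFER_CACHE[key]


def forward_gain(
    head: HeadModel,
    montage,
    location_cm: np.ndarray,
    moment_nAm: np.ndarray,
    average_reference: bool = True,
) -> np.ndarray:
    """Scalp potential (µV) of one dipole at every montage electrode.

    Parameters
    ----------
    head : HeadModel
    montage : Montage
        Electrodes are evaluated at the scalp sphere surface along their
        unit directions.
    location_cm : array-like, shape (3,)
        Dipole location (cm), strictly inside the innermost shell.
    moment_nAm : array-like, shape (3,)
        Dipole moment vector in nAm.
    average_reference : bool
        If True (default), subtract the mean over scalp channels so the
        gain has zero mean across the scalp.

    Returns
    -------
    ndarray, shape (n_channels,)
        Potential in µV at each montage electrode.
    """
    g = forward_matrix(head, montage, np.asarray(location_cm, float)[None, :],
                       average_reference=average_reference)
    return g @ np.asarray(moment_nAm, float)


def forward_matrix(
    head: HeadModel,
    montage,
    locations_cm: np.ndarray,
    average_reference: bool = True,
) -> np.ndarray:
    """Gain matrix (µV per nAm) for free-orientation dipoles.

    Returns shape ``(n_channels, 3 * n_dipoles)``; columns are grouped per
    dipole as (x, y, z) unit moments.
    """
    locs = np.atleast_2d(np.asarray(locations_cm, float))
    radii_cm = np.linalg.norm(locs, axis=1)
    if np.any(radii_cm >= head.brain_radius_cm):
        raise ValueError("dipole location outside the innermost (brain) shell")
    S = _transfer(head)
    n_terms = S.size - 1
    epos = montage.positions  # (n_ch, 3) unit
    n_ch, n_loc = epos.shape[0], locs.shape[0]

    rho_b = radii_cm / head.r_head_cm  # eccentricity relative to scalp
    R_m = head.r_head_cm / 100.0
    bhat = np.where(
        radii_cm[:, None] > 1e-9,
        locs / np.where(radii_cm[:, None] > 1e-9, radii_cm[:, None], 1.0),
        np.array([0.0, 0.0, 1.0]),
    )
    x = np.clip(bhat @ epos.T, -1.0, 1.0)  # (n_loc, n_ch) cos of angle
    sig1 = head.conductivities[0]

    # Legendre recurrence over the whole (n_loc, n_ch) grid, accumulating
    # the radial-moment sum and the tangential-moment sum per degree.
    rad_sum = np.zeros((n_loc, n_ch))
    tan_sum = np.zeros((n_loc, n_ch))
    s2 = np.clip(1.0 - x**2, 0.0, None)
    inv_s = np.where(s2 > 1e-24, 1.0 / np.sqrt(np.where(s2 > 1e-24, s2, 1.0)), 0.0)
    P_prev = np.ones_like(x)  # P_0
    P_cur = x.copy()  # P_1
    bpow = np.ones(n_loc)  # rho_b**(n-1), with 0**0 := 1 at n = 1
    scale = 1.0 / (4.0 * np.pi * sig1 * R_m**2)
    for n in range(1, n_terms + 1):
        pref = S[n] * bpow * scale  # (n_loc,)
        P1 = n * (P_prev - x * P_cur) * inv_s  # assoc. Legendre P_n^1
        rad_sum += (pref * n)[:, None] * P_cur
        tan_sum += pref[:, None] * P1
        P_next = ((2 * n + 1) * x * P_cur - n * P_prev) / (n + 1)
        P_prev, P_cur = P_cur, P_next
        bpow = bpow * rho_b

    # tangential electrode directions in each dipole frame: (n_loc, n_ch, 3)
    tan_vec = epos[None, :, :] - x[:, :, None] * bhat[:, None, :]
    tn = np.linalg.norm(tan_vec, axis=2)
    that = np.where(tn[:, :, None] > 1e-12,
                    tan_vec / np.where(tn[:, :, None] > 1e-12, tn[:, :, None], 1.0),
                    0.0)

    G = np.empty((n_ch, 3 * n_loc))
    eye = np.eye(3)
    for ax in range(3):
        q_r = bhat @ eye[ax]  # (n_loc,)
        q_t_vec = eye[ax][None, :] - q_r[:, None] * bhat  # (n_loc, 3)
        cosb_qt = np.einsum("lcj,lj->lc", that, q_t_vec)  # |q_t| cos(beta)
        v = q_r[:, None] * rad_sum + cosb_qt * tan_sum  # (n_loc, n_ch)
        G[:, ax::3] = v.T
    G *= 1e-9 * 1e6  # nAm -> Am, V -> µV
    if average_reference:
        sp = montage.scalp_picks
        G -= G[sp].mean(axis=0, keepdims=True)
    return G
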