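"""Analytic EEG forward model for concentric spherical shells.

The potential of a current dipole inside a layered spherical conductor is a
Legendre series whose per-degree gain factors follow from the continuity of
potential and radial current density at each shell interface plus the
insulating boundary at the scalp.  For a homogeneous sphere the series sums
in closed form, which serves as an independent oracle in the test suite.

Units: positions in meters, conductivities in S/m, dipole moments in nA*m,
potentials in microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import HeadGeometry, Montage, SourceSpace

__all__ = [
    "LeadField",
    "RigidTransform",
    "align_montage",
    "dipole_potential",
    "homogeneous_sphere_potential",
    "compute_leadfield",
    "average_reference_matrix",
]

# nA*m dipole in meters/Siemens geometry yields volts * 1e-9; report microvolts.
_UNIT_SCALE = 1e-9 * 1e6


def average_reference_matrix(n: int) -> np.ndarray:
    """Centering matrix H = I - (1/n) 11^T implementing the average reference."""
    return np.eye(n) - np.full((n, n), 1.0 / n)


@dataclass(frozen=True)
class LeadField:
    """Average-referenced gain matrix, channels x (3 * n_sources).

    Columns are ordered grid-major with x, y, z moment components within
    each grid point; entries are microvolts per nA*m.
    """

    gain: np.ndarray
    channel_names: list[str]
    n_sources: int
    truncation_L: int
    reference: str = "average"

    def block(self, j: int) -> np.ndarray:
        """3-column gain block of grid point ``j``."""
        return self.gain[:, 3 * j : 3 * j + 3]


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation (+ optional isotropic scale): y = s R x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * points @ self.rotation.T + self.translation


def align_montage(
    montage: Montage,
    measured_fiducials: dict[str, np.ndarray],
    head_fiducials: dict[str, np.ndarray],
    allow_scale: bool = False,
) -> tuple[RigidTransform, Montage, float]:
    """Rigidly align measured electrode positions into head coordinates.

    Solves the least-squares orthogonal Procrustes problem (Umeyama/Kabsch)
    over the fiducial landmarks shared by both dictionaries and applies the
    recovered transform to all electrodes.  Returns the transform, the
    aligned montage, and the residual fiducial RMS in meters.
    """
    shared = sorted(set(measured_fiducials) & set(head_fiducials))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared fiducials for alignment")
    src = np.array([np.asarray(measured_fiducials[k], float) for k in shared])
    dst = np.array([np.asarray(head_fiducials[k], float) for k in shared])
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    # collinearity check: second singular value of the centered source cloud
    sv = np.linalg.svd(src_c, compute_uv=False)
    if sv[1] < 1e-12 * max(sv[0], 1e-30):
        raise ValueError("fiducials are collinear; alignment is underdetermined")
    cov = dst_c.T @ src_c
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    if allow_scale:
        var_src = np.sum(src_c**2)
        scale = float(np.sum(S * np.diag(D)) / var_src)
    else:
        scale = 1.0
    t = dst.mean(axis=0) - scale * R @ src.mean(axis=0)
    xf = RigidTransform(R, t, scale)
    resid = xf.apply(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    aligned = Montage(
        list(montage.labels),
        xf.apply(montage.positions),
        list(montage.coronal),
        list(montage.sagittal),
    )
    return xf, aligned, rms


def _degree_gains(head: HeadGeometry, L: int) -> np.ndarray:
    """Per-degree surface gain g_n for a unit interior-source coefficient.

    In each shell the degree-n potential is a_k rho^n + b_k rho^-(n+1)
    (rho = r / outer radius).  With the source term fixed at b_1 = 1 the
    interface continuity conditions and the insulating scalp boundary give a
    small linear system per degree; g_n = a_N + b_N evaluated at rho = 1.
    For equal conductivities g_n = (2n + 1) / n, the homogeneous result.
    """
    radii = head.shell_radii / head.outer_radius
    cond = head.shell_conductivities
    N = head.n_shells
    gains = np.empty(L + 1)
    gains[0] = 0.0
    if N == 1:
        n = np.arange(1, L + 1)
        gains[1:] = (2 * n + 1) / n
        return gains
    for n in range(1, L + 1):
        # unknowns: a_1, (a_2, b_2), ..., (a_N, b_N)
        m = 2 * N - 1
        A = np.zeros((m, m))
        rhs = np.zeros(m)

        def col_a(k):  # shell index k = 0..N-1
            return 0 if k == 0 else 2 * k - 1

        def col_b(k):
            return 2 * k

        for k in range(N - 1):  # interface between shell k and k+1 at radii[k]
            rho = radii[k]
            pa, pb = rho**n, rho ** -(n + 1)
            da, db = n * rho ** (n - 1), -(n + 1) * rho ** -(n + 2)
            row_v, row_j = 2 * k, 2 * k + 1
            A[row_v, col_a(k)] += pa
            A[row_j, col_a(k)] += cond[k] * da
            if k == 0:
                rhs[row_v] -= pb
                rhs[row_j] -= cond[k] * db
            else:
                A[row_v, col_b(k)] += pb
                A[row_j, col_b(k)] += cond[k] * db
            A[row_v, col_a(k + 1)] -= pa
            A[row_v, col_b(k + 1)] -= pb
            A[row_j, col_a(k + 1)] -= cond[k + 1] * da
            A[row_j, col_b(k + 1)] -= cond[k + 1] * db
        # insulating outer boundary at rho = 1
        A[-1, col_a(N - 1)] = n
        A[-1, col_b(N - 1)] = -(n + 1)
        sol = np.linalg.solve(A, rhs)
        gains[n] = sol[col_a(N - 1)] + sol[col_b(N - 1)]
    return gains


def _legendre_pair(x: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
    """P_n(x) and the associated term sin(theta) * P_n'(x) for n = 0..L.

    Returns arrays of shape (L+1, len(x)).  The second array is the
    positive-convention associated Legendre function of order 1.
    """
    x = np.asarray(x, float)
    P = np.zeros((L + 1,) + x.shape)
    dP = np.zeros_like(P)
    P[0] = 1.0
    if L >= 1:
        P[1] = x
        dP[1] = 1.0
    for n in range(1, L):
        P[n + 1] = ((2 * n + 1) * x * P[n] - n * P[n - 1]) / (n + 1)
        dP[n + 1] = dP[n - 1] + (2 * n + 1) * P[n]
    sin_t = np.sqrt(np.clip(1.0 - x**2, 0.0, None))
    return P, sin_t * dP


def dipole_potential(
    head: HeadGeometry,
    dipole_position: np.ndarray,
    dipole_moment: np.ndarray,
    electrode_positions: np.ndarray,
    truncation_L: int = 60,
    _gains: np.ndarray | None = None,
) -> np.ndarray:
    """Scalp potential of a current dipole in the layered sphere.

    Electrodes are projected radially onto the outer shell (the analytic
    solution requires on-sphere sensors).  Returns the raw (un-referenced)
    potential at each electrode in microvolts for a moment in nA*m.
    """
    if truncation_L < 1:
        raise ValueError("truncation degree L must be >= 1")
    r0 = np.asarray(dipole_position, float)
    m = np.asarray(dipole_moment, float)
    b = np.linalg.norm(r0)
    if b >= head.inner_radius:
        raise ValueError("dipole must lie strictly inside the innermost shell")
    elec = np.asarray(electrode_positions, float)
    R = head.outer_radius
    e_unit = elec / np.linalg.norm(elec, axis=1, keepdims=True)
    gains = _degree_gains(head, truncation_L) if _gains is None else _gains

    if b < 1e-12:
        # central dipole: only degree 1 survives; direction of m is radial
        g1 = gains[1]
        V = g1 * (e_unit @ m) / R**2 / (4 * np.pi * head.shell_conductivities[0])
        return V * _UNIT_SCALE

    eb = r0 / b
    x = e_unit @ eb  # cos(gamma) per electrode
    f = b / R
    n = np.arange(truncation_L + 1)
    P, P1 = _legendre_pair(x, truncation_L)
    w = gains * f ** np.maximum(n - 1, 0)  # g_n f^(n-1), degree 0 unused
    w[0] = 0.0
    m_r = float(m @ eb)
    # tangential unit vector toward each electrode in the (eb, e) plane
    t_vec = e_unit - np.outer(x, eb)
    t_norm = np.linalg.norm(t_vec, axis=1)
    safe = t_norm > 1e-12
    t_hat = np.zeros_like(t_vec)
    t_hat[safe] = t_vec[safe] / t_norm[safe, None]
    m_t = t_hat @ m
    radial = (w * n) @ P
    tangential = w @ P1
    V = (m_r * radial + m_t * tangential) / (
        4 * np.pi * head.shell_conductivities[0] * R**2
    )
    return V * _UNIT_SCALE


def homogeneous_sphere_potential(
    radius: float,
    conductivity: float,
    dipole_position: np.ndarray,
    dipole_moment: np.ndarray,
    electrode_positions: np.ndarray,
) -> np.ndarray:
    """Closed-form surface potential for a dipole in a homogeneous sphere.

    The Legendre series sums exactly via generating-function identities;
    this closed form is independent of the truncated-series path and is
    used as its oracle.  Same units as :func:`dipole_potential`.
    """
    r0 = np.asarray(dipole_position, float)
    m = np.asarray(dipole_moment, float)
    elec = np.asarray(electrode_positions, float)
    R = radius
    e_unit = elec / np.linalg.norm(elec, axis=1, keepdims=True)
    b = np.linalg.norm(r0)
    if b < 1e-14:
        return 3.0 * (e_unit @ m) / (4 * np.pi * conductivity * R**2) * _UNIT_SCALE
    eb = r0 / b
    f = b / R
    x = e_unit @ eb
    u = np.sqrt(1.0 - 2.0 * f * x + f * f)
    sin_g = np.sqrt(np.clip(1.0 - x * x, 0.0, None))
    t_vec = e_unit - np.outer(x, eb)
    t_norm = np.linalg.norm(t_vec, axis=1)
    safe = t_norm > 1e-12
    t_hat = np.zeros_like(t_vec)
    t_hat[safe] = t_vec[safe] / t_norm[safe, None]
    m_r = float(m @ eb)
    m_t = t_hat @ m
    radial = 2.0 * (x - f) / u**3 + (1.0 / u - 1.0) / f
    tangential = sin_g * (2.0 / u**3 + (1.0 + u) / (u * (1.0 - f * x + u)))
    V = (m_r * radial + m_t * tangential) / (4 * np.pi * conductivity * R**2)
    return V * _UNIT_SCALE


def compute_leadfield(
    head: HeadGeometry,
    source_space: SourceSpace,
    montage: Montage,
    truncation_L: int = 60,
) -> LeadField:
    """Average-referenced lead field for a source grid and montage.

    For each grid point the three columns are the potentials of unit x, y, z
    moments (1 nA*m), computed by the layered-sphere series and then
    centered row-wise so each column sums to zero across channels.
    """
    pos = source_space.positions
    r_in = head.inner_radius
    bad = np.flatnonzero(np.linalg.norm(pos, axis=1) >= r_in)
    if bad.size:
        raise ValueError(f"grid point {bad[0]} lies outside the innermost shell")
    n_chan = montage.n_electrodes
    if n_chan < 2:
        raise ValueError("lead field requires at least 2 channels")
    gains = _degree_gains(head, truncation_L)
    G = np.empty((n_chan, 3 * source_space.n_sources))
    eye = np.eye(3)
    for j in range(source_space.n_sources):
        for a in range(3):
            G[:, 3 * j + a] = dipole_potential(
                head, pos[j], eye[a], montage.positions, truncation_L, _gains=gains
            )
    H = average_reference_matrix(n_chan)
    G = H @ G
    return LeadField(G, list(montage.labels), source_space.n_sources, truncation_L)
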