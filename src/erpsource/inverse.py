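"""eLORETA inverse solution and current-density (CDR) scoring.

eLORETA is a weighted minimum-norm inverse whose depth weights are chosen
self-consistently so that noiseless point sources are localized without
error.  Each grid point j carries a symmetric positive-definite 3x3 weight
block W_j satisfying the fixed point

    W_j = ( K_j^T M K_j )^(1/2),
    M   = pinv( sum_j K_j W_j^(-1) K_j^T  +  alpha * c * H ),

with K_j the 3-column lead-field block, H the average-reference centering
matrix and c a trace-based scale making alpha dimensionless.  The inverse
operator is T = W^(-1) K^T M.

CDR scores: Euclidean norm of the 3-component moment vector per sample,
averaged over the component window (nA*m).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import EpochsSet
from .erp import ComponentWindow
from .forward import LeadField, average_reference_matrix
from .geometry import RoiMaskSet

__all__ = [
    "InverseOperator",
    "eloreta_weights",
    "make_inverse_operator",
    "apply_inverse_window",
    "cdr_scores",
    "roi_aggregate",
]


@dataclass
class InverseOperator:
    """Linear operator from channel potentials to dipole moments (nA*m)."""

    operator: np.ndarray  # (3M, channels)
    weights: np.ndarray  # (M, 3, 3) SPD blocks
    alpha: float
    n_iter: int
    converged: bool

    @property
    def n_sources(self) -> int:
        return self.operator.shape[0] // 3


def _pinv_sym(A: np.ndarray, rel_floor: float = 1e-12) -> np.ndarray:
    """Pseudo-inverse of a symmetric matrix via eigendecomposition with a
    relative eigenvalue floor."""
    w, V = np.linalg.eigh(A)
    thresh = rel_floor * np.max(np.abs(w))
    inv_w = np.where(np.abs(w) > thresh, 1.0 / w, 0.0)
    return (V * inv_w) @ V.T


def _sqrtm_spd(A: np.ndarray) -> np.ndarray:
    """Symmetric square root of a symmetric PSD 3x3 block."""
    w, V = np.linalg.eigh(A)
    return (V * np.sqrt(np.clip(w, 0.0, None))) @ V.T


def eloreta_weights(
    leadfield: LeadField,
    alpha: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, int, bool]:
    """Iterate the eLORETA weight fixed point to convergence.

    Returns (weights (M,3,3), n_iter, converged).  Convergence is the
    maximum relative Frobenius change of any block falling below ``tol``;
    non-convergence emits a warning and returns the best iterate.
    """
    K = leadfield.gain
    if not np.all(np.isfinite(K)):
        raise ValueError("lead field contains non-finite entries")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if tol <= 0:
        raise ValueError("tol must be positive")
    n_chan = K.shape[0]
    M_src = leadfield.n_sources
    Kb = K.reshape(n_chan, M_src, 3)
    H = average_reference_matrix(n_chan)
    W = np.tile(np.eye(3), (M_src, 1, 1))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Winv = np.linalg.inv(W)
        # C = sum_j K_j W_j^-1 K_j^T
        KW = np.einsum("cjx,jxy->cjy", Kb, Winv)
        C = np.einsum("cjy,djy->cd", KW, Kb)
        if alpha > 0:
            c_scale = np.trace(C) / n_chan
            Mmat = _pinv_sym(C + alpha * c_scale * H)
        else:
            Mmat = _pinv_sym(C)
        # W_j <- (K_j^T M K_j)^(1/2)
        MK = np.einsum("cd,djy->cjy", Mmat, Kb)
        S = np.einsum("cjx,cjy->jxy", Kb, MK)
        W_new = np.stack([_sqrtm_spd(S[j]) for j in range(M_src)])
        denom = np.linalg.norm(W, axis=(1, 2))
        denom[denom == 0] = 1.0
        change = np.linalg.norm(W_new - W, axis=(1, 2)) / denom
        W = W_new
        if np.max(change) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"eLORETA weights did not converge in {max_iter} iterations "
            f"(max relative change {np.max(change):.2e})",
            RuntimeWarning,
        )
    return W, it, converged


def make_inverse_operator(
    leadfield: LeadField,
    weights: np.ndarray | None = None,
    alpha: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> InverseOperator:
    """Assemble T = W^(-1) K^T M from converged eLORETA weights."""
    if weights is None:
        weights, n_iter, converged = eloreta_weights(leadfield, alpha, tol, max_iter)
    else:
        n_iter, converged = 0, True
    K = leadfield.gain
    n_chan = K.shape[0]
    M_src = leadfield.n_sources
    if weights.shape != (M_src, 3, 3):
        raise ValueError("weights shape does not match the lead field")
    Kb = K.reshape(n_chan, M_src, 3)
    H = average_reference_matrix(n_chan)
    Winv = np.linalg.inv(weights)
    KW = np.einsum("cjx,jxy->cjy", Kb, Winv)
    C = np.einsum("cjy,djy->cd", KW, Kb)
    if alpha > 0:
        c_scale = np.trace(C) / n_chan
        Mmat = _pinv_sym(C + alpha * c_scale * H)
    else:
        Mmat = _pinv_sym(C)
    # T = W^-1 K^T M, assembled blockwise: T_j = W_j^-1 K_j^T M
    T = np.einsum("jxy,cjy,cd->jxd", Winv, Kb, Mmat).reshape(3 * M_src, n_chan)
    return InverseOperator(T, weights, alpha, n_iter, converged)


def apply_inverse_window(
    operator: InverseOperator,
    epochs: EpochsSet,
    window: ComponentWindow,
    condition: str,
) -> np.ndarray:
    """Project the condition's trial-average ERP over the component window
    through the inverse operator.

    Returns moments of shape (M, 3, n_window_samples) in nA*m.
    """
    sel = epochs.pick_condition(condition)
    mask = epochs.time_mask(window.start_ms, window.stop_ms)
    if not np.any(mask):
        raise ValueError("component window lies outside the epoch")
    erp = sel.data.astype(float).mean(axis=0)[:, mask]  # channels x samples
    if operator.operator.shape[1] != erp.shape[0]:
        raise ValueError("operator channel count does not match the data")
    mom = operator.operator @ erp  # (3M, samples)
    return mom.reshape(operator.n_sources, 3, -1)


def cdr_scores(moment_series: np.ndarray) -> np.ndarray:
    """Per-grid CDR: mean over window samples of the per-sample Euclidean
    norm of the 3-component moment vector."""
    if moment_series.ndim != 3 or moment_series.shape[1] != 3:
        raise ValueError("expected moments of shape (M, 3, n_samples)")
    if moment_series.shape[2] == 0:
        raise ValueError("empty component window")
    return np.linalg.norm(moment_series, axis=1).mean(axis=1)


def roi_aggregate(cdr: np.ndarray, masks: RoiMaskSet) -> dict[str, float]:
    """Arithmetic mean CDR over each ROI's member grid points."""
    out = {}
    for m in masks:
        if m.indices.size == 0:
            raise ValueError(f"ROI {m.name!r} is empty")
        if m.indices.max() >= cdr.size:
            raise ValueError(f"ROI {m.name!r} indexes outside the source grid")
        out[m.name] = float(cdr[m.indices].mean())
    return out
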