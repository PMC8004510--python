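"""Source localization filters (weighted minimum-norm family).

All operators share the form ``K = G^-1 L^T (L G^-1 L^T + alpha H)^+`` with
``L`` the average-referenced leadfield, ``H`` a noise covariance and
``alpha > 0`` the Tikhonov regularization parameter:

* ``mne``      — minimum-norm estimate, ``G = I``;
* ``eloreta``  — exact low-resolution electromagnetic tomography: ``G`` is
  block-diagonal with per-voxel 3×3 weights ``W_v = (L_v^T M L_v)^(1/2)``
  found by fixed-point iteration (``M`` the regularized pseudoinverse of
  the weighted Gram matrix); gives zero localization error for noiseless
  point sources;
* ``sloreta``  — minimum-norm with per-voxel standardization by the 3×3
  diagonal blocks of the resolution matrix.

The regularizer enters as ``alpha * trace(L G^-1 L^T)/n_E * H_unit`` where
``H_unit`` is the trace-normalized noise covariance, so alpha is a
dimensionless fraction of mean signal power (default 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .forward import Leadfield
from .geometry import SourceGrid

__all__ = ["InverseResult", "compute_inverse_filter", "downsample_filter_to_rois"]

logger = logging.getLogger(__name__)

PINV_RTOL = 1e-10  # singular values below rtol * sigma_max are zeroed


class ELORETAConvergenceError(RuntimeError):
    pass


class EmptyROIError(ValueError):
    pass


@dataclass(frozen=True)
class InverseResult:
    """Inverse filter ``K`` ``(3 n_V, n_E)`` plus the per-voxel weights used."""

    K: np.ndarray
    method: str
    alpha: float
    G_blocks: np.ndarray | None = None  # (n_V, 3, 3) eLORETA weights / sLORETA scalers
    iterations: int = 0


def _sym_pinv(M: np.ndarray, rtol: float = PINV_RTOL) -> np.ndarray:
    w, V = np.linalg.eigh((M + M.T) / 2)
    keep = w > rtol * w.max()
    return (V[:, keep] / w[keep]) @ V[:, keep].T


def _block_sqrt(blocks: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root of stacked 3x3 blocks."""
    w, V = np.linalg.eigh((blocks + blocks.transpose(0, 2, 1)) / 2)
    w = np.clip(w, 0, None)
    return np.einsum("vij,vj,vkj->vik", V, np.sqrt(w), V)


def _block_inv(blocks: np.ndarray, rtol: float = 1e-12) -> np.ndarray:
    w, V = np.linalg.eigh((blocks + blocks.transpose(0, 2, 1)) / 2)
    wmax = w.max(axis=1, keepdims=True)
    winv = np.where(w > rtol * wmax, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return np.einsum("vij,vj,vkj->vik", V, winv, V)


def _normalize_noise_cov(H: np.ndarray | None, n_e: int) -> np.ndarray:
    if H is None:
        return np.eye(n_e)
    H = np.asarray(H, float)
    tr = np.trace(H)
    if tr <= 0:
        raise ValueError("noise covariance must have positive trace")
    return H * (n_e / tr)


def compute_inverse_filter(
    lf: Leadfield,
    H: np.ndarray | None = None,
    alpha: float = 0.05,
    method: str = "eloreta",
    tol: float = 1e-6,
    max_iter: int = 100,
) -> InverseResult:
    """Build the source localization filter ``K`` for the requested method."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not lf.referenced:
        raise ValueError("leadfield must be average-referenced")
    method = method.lower()
    L = lf.gain
    n_e = L.shape[0]
    n_v = lf.n_voxels
    Hn = _normalize_noise_cov(H, n_e)

    def gram_and_reg(Ginv_blocks=None):
        if Ginv_blocks is None:
            gram = L @ L.T
        else:
            LG = np.einsum(
                "evi,vij->evj", L.reshape(n_e, n_v, 3), Ginv_blocks
            ).reshape(n_e, 3 * n_v)
            gram = LG @ L.T
        lam = alpha * np.trace(gram) / n_e
        return gram, lam

    if method == "mne":
        gram, lam = gram_and_reg()
        K = L.T @ _sym_pinv(gram + lam * Hn)
        return InverseResult(K, "mne", alpha)

    if method == "sloreta":
        gram, lam = gram_and_reg()
        Minv = _sym_pinv(gram + lam * Hn)
        K = L.T @ Minv
        # resolution blocks: (K L)_vv = L_v^T Minv L_v
        Lv = L.reshape(n_e, n_v, 3)
        res = np.einsum("evi,ef,fvj->vij", Lv, Minv, Lv)
        scal = _block_sqrt(_block_inv(res))
        Kb = np.einsum("vij,vje->vie", scal, K.reshape(n_v, 3, n_e))
        return InverseResult(Kb.reshape(3 * n_v, n_e), "sloreta", alpha, G_blocks=scal)

    if method != "eloreta":
        raise ValueError(f"unknown inverse method: {method}")

    # eLORETA fixed-point iteration on the per-voxel weight blocks
    Lv = L.reshape(n_e, n_v, 3)
    Ginv = np.tile(np.eye(3), (n_v, 1, 1))
    history = []
    for it in range(1, max_iter + 1):
        gram, lam = gram_and_reg(Ginv)
        M = _sym_pinv(gram + lam * Hn)
        Wv = _block_sqrt(np.einsum("evi,ef,fvj->vij", Lv, M, Lv))
        Ginv_new = _block_inv(Wv)
        num = np.linalg.norm(Ginv_new - Ginv)
        den = np.linalg.norm(Ginv)
        change = num / den if den > 0 else np.inf
        history.append(change)
        Ginv = Ginv_new
        if change < tol:
            break
    else:
        raise ELORETAConvergenceError(
            f"eLORETA weights not converged after {max_iter} iterations; "
            f"relative changes: {['%.2e' % h for h in history[-5:]]}"
        )
    gram, lam = gram_and_reg(Ginv)
    M = _sym_pinv(gram + lam * Hn)
    # rows 3v..3v+2 of K are Ginv_v @ L_v^T @ M
    K = np.einsum("vij,evj,ef->vif", Ginv, Lv, M).reshape(3 * n_v, n_e)
    return InverseResult(K, "eloreta", alpha, G_blocks=Ginv, iterations=it)


def downsample_filter_to_rois(
    K: np.ndarray,
    grid: SourceGrid,
    rois: list[tuple],
    mode: str = "nearest",
) -> tuple[np.ndarray, list[int]]:
    """Restrict ``K`` to spherical ROIs, three rows (x/y/z) per ROI.

    Each ROI is ``(center_mm, radius_mm)``. In ``nearest`` mode the
    representative voxel is the in-radius grid voxel closest to the ROI
    center and its 3 rows are extracted; in ``mean`` mode the rows are
    averaged over all in-radius voxels. Returns ``(K_R, voxel_indices)``
    where ``K_R`` is ``(3 n_R, n_E)`` and ``voxel_indices`` holds the
    representative voxel per ROI.
    """
    if K.shape[0] != 3 * grid.n_voxels:
        raise ValueError("K row count does not match the grid")
    out_rows = []
    reps = []
    for r, (center, radius) in enumerate(rois):
        d = np.linalg.norm(grid.voxel_positions - np.asarray(center, float), axis=1)
        inside = np.where(d <= radius)[0]
        if inside.size == 0:
            raise EmptyROIError(
                f"ROI {r} at {np.asarray(center).tolist()} (radius {radius} mm) "
                "contains no grid voxel"
            )
        rep = int(inside[np.argmin(d[inside])])
        reps.append(rep)
        if mode == "nearest":
            out_rows.append(K[3 * rep : 3 * rep + 3])
        elif mode == "mean":
            blocks = np.stack([K[3 * v : 3 * v + 3] for v in inside])
            out_rows.append(blocks.mean(axis=0))
        else:
            raise ValueError(f"unknown ROI mode: {mode}")
    return np.vstack(out_rows), reps
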