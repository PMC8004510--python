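"""Calibration: estimate every spatial filter from a resting recording.

Order of operations (each product of the earlier stages feeds the next):

1. bad-channel detection -> correction matrix ``C`` and average-reference
   matrix ``R``; ``X_q = C R X``;
2. band-pass to the analysis band -> ``X_q~``;
3. FastICA on ``X_q~``; artifact ICs flagged from aux-channel power
   correlation, 1/f spectral fit and kurtosis -> ``W_A``;
4. artifact attenuation filter
   ``F0 = I − X_q~ S_A^T (S_A S_A^T)^−1 W_A`` with ``S_A = W_A X_q~``,
   which annihilates the artifact subspace: ``W_A F0 X_q~ = 0``;
5. noise covariance ``H`` from the cleaned data ``X_p~ = F0 X_q~``;
6. inverse filter ``K`` (eLORETA by default) from the leadfield and ``H``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .forward import Leadfield
from .geometry import ElectrodeSet
from .ica import ICADecomposition, ICFeatureTable, classify_artifact_ics, fit_ica
from .inverse import compute_inverse_filter, downsample_filter_to_rois
from .preprocess import (
    BadChannelReport,
    apply_sensor_filters,
    bandpass,
    build_adjacency,
    build_correction_matrix,
    build_reference_matrix,
    detect_bad_channels,
)
from .recording import Recording

__all__ = [
    "CalibrationConfig",
    "SpatialFilterSet",
    "CalibrationReport",
    "build_artifact_filter",
    "estimate_noise_covariance",
    "run_calibration",
    "save_filters",
    "load_filters",
]

logger = logging.getLogger(__name__)

RIDGE_CONDITION_LIMIT = 1e12


@dataclass(frozen=True)
class CalibrationConfig:
    """User-facing calibration parameters (mirrors the acquisition GUI fields)."""

    band: tuple[float, float] = (1.0, 50.0)
    method: str = "eloreta"
    alpha: float = 0.05
    adjacency_mm: float = 40.0
    n_components: int | None = None  # None -> effective rank
    ic_thresholds: dict = field(default_factory=dict)
    noise_cov: str = "data"  # "data": sample covariance of cleaned calibration;
    # "identity": H = R, the average-reference projector. The data estimate is
    # contaminated by neural sources, which the regularizer then penalizes, so
    # "identity" is preferable when the inverse feeds source power analyses.
    seed: int = 0
    artifact_removal: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class SpatialFilterSet:
    """All calibration products needed by the real-time engine."""

    C: np.ndarray
    R: np.ndarray
    W_A: np.ndarray  # (n_A, n_E); empty (0, n_E) when no artifact ICs
    F0: np.ndarray
    H: np.ndarray
    K: np.ndarray  # (3 n_V, n_E) or (3 n_R, n_E) after ROI downsampling
    method: str
    alpha: float
    band: tuple[float, float]
    labels: tuple[str, ...]
    bad_channels: tuple[str, ...] = ()
    G_blocks: np.ndarray | None = None
    config_hash: str = ""

    def __post_init__(self) -> None:
        n_e = len(self.labels)
        for name in ("C", "R", "F0", "H"):
            m = getattr(self, name)
            if m.shape != (n_e, n_e):
                raise ValueError(f"{name} must be ({n_e}, {n_e})")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.W_A.ndim != 2 or self.W_A.shape[1] != n_e:
            raise ValueError("W_A must be (n_A, n_E)")
        if self.K.shape[1] != n_e or self.K.shape[0] % 3:
            raise ValueError("K must be (3*n, n_E)")
        w = np.linalg.eigvalsh((self.H + self.H.T) / 2)
        if w.min() < -1e-8 * max(w.max(), 1e-30):
            raise ValueError("H must be positive semidefinite")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def with_K(self, K: np.ndarray) -> "SpatialFilterSet":
        from dataclasses import replace

        return replace(self, K=np.asarray(K, float))

    def restrict_to_rois(self, grid, rois, mode="nearest") -> "SpatialFilterSet":
        K_r, _ = downsample_filter_to_rois(self.K, grid, rois, mode)
        return self.with_K(K_r)


@dataclass(frozen=True)
class CalibrationReport:
    bad_channels: BadChannelReport
    ic_features: ICFeatureTable
    ica: ICADecomposition
    eloreta_iterations: int


def regress_out(X: np.ndarray, S_A: np.ndarray, W_A: np.ndarray) -> np.ndarray:
    """The artifact attenuation filter ``I − X S_A^T (S_A S_A^T)^−1 W_A``.

    Falls back to a ridge-stabilised solve when ``S_A S_A^T`` is nearly
    singular (condition number above 1e12).
    """
    n_e = X.shape[0]
    if S_A.shape[0] == 0:
        return np.eye(n_e)
    # data (numerically) orthogonal to the artifact rows: nothing to remove
    scale = np.linalg.norm(W_A) * np.linalg.norm(X)
    if np.linalg.norm(S_A) <= 1e-10 * max(scale, 1e-300):
        return np.eye(n_e)
    gram = S_A @ S_A.T
    w = np.linalg.eigvalsh((gram + gram.T) / 2)
    if w.min() <= 0 or w.max() / w.min() > RIDGE_CONDITION_LIMIT:
        ridge = 1e-8 * np.trace(gram) / gram.shape[0]
        logger.warning(
            "artifact regression gram matrix ill-conditioned; adding ridge %.3e", ridge
        )
        gram = gram + ridge * np.eye(gram.shape[0])
    coef = np.linalg.solve(gram, S_A @ X.T).T  # X S_A^T (S_A S_A^T)^-1
    return np.eye(n_e) - coef @ W_A


def build_artifact_filter(xq: Recording | np.ndarray, ica: ICADecomposition) -> np.ndarray:
    """Eq.-for-eq. artifact filter ``F0`` from the calibration data and flagged ICs.

    With no artifactual ICs returns the identity (with a warning).
    """
    X = xq.eeg if isinstance(xq, Recording) else np.asarray(xq, float)
    if not ica.artifact_indices:
        logger.warning("no artifactual ICs flagged; F0 = identity")
        return np.eye(X.shape[0])
    W_A = ica.W_A
    S_A = W_A @ X
    return regress_out(X, S_A, W_A)


def estimate_noise_covariance(
    xp: Recording | np.ndarray, R: np.ndarray | None = None
) -> np.ndarray:
    """Trace-normalized, average-reference-projected sample covariance of the
    cleaned calibration data.

    With fewer samples than channels a diagonal shrinkage (Ledoit-Wolf style
    blend toward the scaled identity, weight n/(n+p)) is applied and logged.
    """
    X = xp.eeg if isinstance(xp, Recording) else np.asarray(xp, float)
    n_e, n_t = X.shape
    Xc = X - X.mean(axis=1, keepdims=True)
    H = Xc @ Xc.T / max(n_t - 1, 1)
    if n_t < n_e:
        lam = n_t / (n_t + n_e)
        target = np.trace(H) / n_e * np.eye(n_e)
        logger.warning("fewer samples (%d) than channels (%d); shrinking covariance", n_t, n_e)
        H = lam * H + (1 - lam) * target
    H = (H + H.T) / 2
    if R is None:
        R = build_reference_matrix(n_e)
    H = R @ H @ R
    H = (H + H.T) / 2
    tr = np.trace(H)
    if tr <= 0:
        raise ValueError("degenerate (zero) noise covariance")
    return H * (n_e / tr)


def run_calibration(
    rec: Recording,
    lf: Leadfield,
    electrodes: ElectrodeSet,
    config: CalibrationConfig = CalibrationConfig(),
) -> tuple[SpatialFilterSet, CalibrationReport]:
    """Run the full calibration chain on a resting recording.

    ``electrodes`` supplies co-registered positions for the neighbour rule;
    its labels must match the recording's EEG labels and the leadfield's
    electrode order. Deterministic for a fixed ``config.seed``.
    """
    labels = rec.eeg_labels
    if tuple(electrodes.labels) != labels or tuple(lf.electrode_order) != labels:
        raise ValueError("electrode / leadfield / recording label order mismatch")

    report_bad = detect_bad_channels(rec, band=config.band)
    adjacency = build_adjacency(electrodes, report_bad.bad_list, config.adjacency_mm)
    C = build_correction_matrix(adjacency, report_bad.bad_list)
    R = build_reference_matrix(len(labels))

    xq = apply_sensor_filters(rec, C, R)
    xq_f = bandpass(xq, config.band)

    n_comp = config.n_components
    ica = fit_ica(xq_f, n_components=n_comp, seed=config.seed)
    ica, feats = classify_artifact_ics(ica, xq_f, config.ic_thresholds, band=config.band)

    if config.artifact_removal:
        F0 = build_artifact_filter(xq_f, ica)
    else:
        F0 = np.eye(len(labels))
    xp = F0 @ xq_f.eeg
    if config.noise_cov == "identity":
        H = R.copy()
    elif config.noise_cov == "data":
        H = estimate_noise_covariance(xp, R)
    else:
        raise ValueError(f"unknown noise_cov: {config.noise_cov}")

    inv = compute_inverse_filter(lf, H, alpha=config.alpha, method=config.method)
    filters = SpatialFilterSet(
        C=C,
        R=R,
        W_A=ica.W_A if config.artifact_removal else np.empty((0, len(labels))),
        F0=F0,
        H=H,
        K=inv.K,
        method=inv.method,
        alpha=config.alpha,
        band=tuple(config.band),
        labels=labels,
        bad_channels=report_bad.bad_list,
        G_blocks=inv.G_blocks,
        config_hash=config.config_hash(),
    )
    report = CalibrationReport(report_bad, feats, ica, inv.iterations)
    return filters, report


def save_filters(filters: SpatialFilterSet, path) -> None:
    """Write the spatial-filter archive (single HDF5 container)."""
    import h5py

    with h5py.File(path, "w", track_order=True) as f:
        for name in ("C", "R", "W_A", "F0", "H", "K"):
            f.create_dataset(name, data=getattr(filters, name), track_times=False)
        if filters.G_blocks is not None:
            f.create_dataset("G_blocks", data=filters.G_blocks, track_times=False)
        f.create_dataset(
            "labels", data=np.array(filters.labels, dtype="S32"), track_times=False
        )
        f.create_dataset(
            "bad_channels",
            data=np.array(filters.bad_channels, dtype="S32"),
            track_times=False,
        )
        f.attrs["method"] = filters.method
        f.attrs["alpha"] = filters.alpha
        f.attrs["band"] = filters.band
        f.attrs["config_hash"] = filters.config_hash


def load_filters(path) -> SpatialFilterSet:
    import h5py

    with h5py.File(path, "r") as f:
        kw = {name: f[name][()] for name in ("C", "R", "W_A", "F0", "H", "K")}
        return SpatialFilterSet(
            **kw,
            method=str(f.attrs["method"]),
            alpha=float(f.attrs["alpha"]),
            band=tuple(float(b) for b in f.attrs["band"]),
            labels=tuple(s.decode() for s in f["labels"][()]),
            bad_channels=tuple(s.decode() for s in f["bad_channels"][()]),
            G_blocks=f["G_blocks"][()] if "G_blocks" in f else None,
            config_hash=str(f.attrs["config_hash"]),
        )
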