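"""ICA decomposition and artifact-component classification.

The calibration data ``X_q~`` (repaired, re-referenced, band-passed) are
decomposed as ``X_q~ = A @ S`` with unmixing ``S = W @ X_q~`` using
fixed-point FastICA (deflation, tanh contrast). A component is artifactual
when at least one of three features exceeds its threshold:

1. maximum absolute correlation of its power envelope with the power
   envelopes of the auxiliary vEOG/hEOG/EMG channels;
2. coefficient of determination of a 1/f fit to its power spectrum
   (log-power regressed on log-frequency);
3. excess kurtosis of its time course.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .recording import Recording

__all__ = [
    "ICADecomposition",
    "ICFeatureTable",
    "fit_ica",
    "classify_artifact_ics",
    "power_envelope",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {"power_corr": 0.3, "one_over_f_r2": 0.8, "kurtosis": 10.0}


class ICAConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ICADecomposition:
    """FastICA mixing/unmixing matrices and component time courses.

    ``A`` is ``(n_E, n_S)``, ``W`` is ``(n_S, n_E)`` with ``W @ A ≈ I`` and
    ``S = W @ X``; components are unit variance. ``artifact_indices`` is
    filled by :func:`classify_artifact_ics`.
    """

    A: np.ndarray
    W: np.ndarray
    S: np.ndarray
    artifact_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.W.shape[0] != self.A.shape[1] or self.W.shape[1] != self.A.shape[0]:
            raise ValueError("W must be (n_S, n_E) and A (n_E, n_S)")
        err = np.abs(self.W @ self.A - np.eye(self.n_components)).max()
        if err > 1e-6:
            raise ValueError(f"W @ A deviates from identity by {err:.2e}")
        if any(not 0 <= i < self.n_components for i in self.artifact_indices):
            raise ValueError("artifact index out of range")

    @property
    def n_components(self) -> int:
        return self.W.shape[0]

    @property
    def W_A(self) -> np.ndarray:
        """Unmixing rows of the artifactual components, ``(n_A, n_E)``."""
        return self.W[list(self.artifact_indices)]

    def with_artifacts(self, indices) -> "ICADecomposition":
        return ICADecomposition(self.A, self.W, self.S, tuple(int(i) for i in indices))


@dataclass(frozen=True)
class ICFeatureTable:
    """Per-component artifact features, thresholds and flags."""

    table: pd.DataFrame
    thresholds: dict[str, float]

    @property
    def artifact_indices(self) -> tuple[int, ...]:
        return tuple(self.table.index[self.table["artifact"]])


def effective_rank(X: np.ndarray, rel_tol: float = 1e-8) -> int:
    s = np.linalg.svd(X - X.mean(axis=1, keepdims=True), compute_uv=False)
    return int(np.sum(s > rel_tol * s[0]))


def fit_ica(
    rec: Recording,
    n_components: int | None = None,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    strict: bool = False,
) -> ICADecomposition:
    """Fixed-point FastICA (deflation approach, tanh contrast) on the EEG rows.

    ``n_components`` defaults to the effective rank of the data (average
    reference and bad-channel repair each remove one rank). Deterministic
    for a fixed ``seed``. With ``strict`` a component that fails to converge
    within ``max_iter`` raises :class:`ICAConvergenceError`; otherwise the
    partially converged estimate is kept and a warning logged (deflation on
    near-Gaussian residual components routinely stalls without harming the
    dominant, artifact-carrying ones).
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning
    import warnings

    X = rec.eeg
    rank = effective_rank(X)
    if n_components is None:
        n_components = rank
    elif n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds effective rank {rank}")
    ica = FastICA(
        n_components=n_components,
        algorithm="deflation",
        fun="logcosh",  # derivative of log cosh is tanh, the contrast used here
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error" if strict else "always", ConvergenceWarning)
        try:
            ica.fit(X.T)
        except ConvergenceWarning as exc:
            raise ICAConvergenceError(
                f"FastICA did not converge in {max_iter} iterations "
                f"(n_components={n_components}, tol={tol}): {exc}"
            ) from None
    W = ica.components_
    A = ica.mixing_
    S = W @ X
    return ICADecomposition(A, W, S)


def power_envelope(x: np.ndarray, fs: float, smooth_s: float = 1.0) -> np.ndarray:
    """Squared signal smoothed with a moving average of ``smooth_s`` seconds."""
    n = max(int(round(smooth_s * fs)), 1)
    kernel = np.full(n, 1.0 / n)
    return np.apply_along_axis(
        lambda v: np.convolve(v, kernel, mode="same"), -1, np.atleast_2d(x) ** 2
    ).reshape(np.shape(x))


def _one_over_f_r2(s: np.ndarray, fs: float, band=(1.0, 45.0)) -> float:
    """R² of a log-log linear fit of the Welch spectrum (2 s windows, 50% overlap)."""
    nper = min(int(2 * fs), s.size)
    f, p = signal.welch(s, fs=fs, nperseg=nper)
    keep = (f >= band[0]) & (f <= band[1]) & (p > 0)
    if keep.sum() < 4:
        return float("nan")
    res = stats.linregress(np.log(f[keep]), np.log(p[keep]))
    return float(res.rvalue**2)


def classify_artifact_ics(
    ica: ICADecomposition,
    rec: Recording,
    thresholds: dict[str, float] | None = None,
    band: tuple[float, float] | None = None,
) -> tuple[ICADecomposition, ICFeatureTable]:
    """Score every IC on the three artifact features and flag with the OR rule.

    Auxiliary channels absent from the recording simply drop the
    power-correlation feature (logged). ``band`` bounds the 1/f fit; it
    defaults to the recording's band tag or 1–45 Hz.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    fs = rec.sampling_rate
    fit_band = band or rec.band or (1.0, 45.0)
    fit_band = (max(fit_band[0], 0.5), min(fit_band[1], 0.98 * fs / 2))

    aux_envs = {}
    for name, row in rec.aux_map.items():
        aux_envs[name] = power_envelope(rec.data[row], fs)
    if not aux_envs:
        logger.warning("no auxiliary channels: power-correlation feature unavailable")

    rows = []
    for i in range(ica.n_components):
        s = ica.S[i]
        env = power_envelope(s, fs)
        if aux_envs:
            pc = max(
                abs(float(np.corrcoef(env, a)[0, 1])) if a.std() > 0 and env.std() > 0 else 0.0
                for a in aux_envs.values()
            )
        else:
            pc = float("nan")
        r2 = _one_over_f_r2(s, fs, fit_band)
        kurt = float(stats.kurtosis(s, fisher=True))
        flag = (
            (np.isfinite(pc) and pc > thr["power_corr"])
            or (np.isfinite(r2) and r2 > thr["one_over_f_r2"])
            or kurt > thr["kurtosis"]
        )
        rows.append(
            {"power_corr": pc, "one_over_f_r2": r2, "kurtosis": kurt, "artifact": flag}
        )
    table = pd.DataFrame(rows)
    feats = ICFeatureTable(table, thr)
    return ica.with_artifacts(feats.artifact_indices), feats
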