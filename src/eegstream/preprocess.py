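"""Sensor-space preprocessing: bad-channel handling, re-referencing, band-pass.

The two calibration projectors are

* the bad-channel correction matrix ``C``: identity on good channels, and on
  each bad channel's row a uniform convex combination of its good
  neighbours, ``c_ij = d_ij / sum_j d_ij``;
* the average-reference matrix ``R = I - (1/n_E) 11^T`` with entries
  ``(n_E - 1)/n_E`` on the diagonal and ``-1/n_E`` off it.

Filtered data are produced as ``X_q = C @ R @ X`` (in that order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .geometry import ElectrodeSet
from .recording import Recording

__all__ = [
    "BadChannelReport",
    "ChannelAdjacency",
    "detect_bad_channels",
    "build_adjacency",
    "build_correction_matrix",
    "build_reference_matrix",
    "apply_sensor_filters",
    "bandpass",
    "bandpass_array",
]

logger = logging.getLogger(__name__)

NOISE_BAND = (200.0, 250.0)  # Hz; EEG content is negligible here
OUTLIER_SD = 4.0


class InsufficientChannelsError(ValueError):
    pass


class IsolatedBadChannelError(ValueError):
    pass


@dataclass(frozen=True)
class BadChannelReport:
    """Per-channel quality parameters and the resulting bad-channel list.

    ``min_correlation`` is the minimum in-band Pearson correlation of each
    channel against every other channel (−1 sentinel for constant channels);
    ``noise_variance`` is the 200–250 Hz variance in uV² (NaN when the
    sampling rate cannot resolve that band).
    """

    labels: tuple[str, ...]
    min_correlation: np.ndarray
    noise_variance: np.ndarray
    corr_mean: float
    corr_sd: float
    var_mean: float
    var_sd: float
    bad_list: tuple[str, ...]

    @property
    def bad_indices(self) -> np.ndarray:
        return np.array([self.labels.index(b) for b in self.bad_list], dtype=int)


@dataclass(frozen=True)
class ChannelAdjacency:
    """Binary symmetric neighbour matrix with bad rows/columns zeroed.

    ``distances`` keeps the full inter-electrode distance matrix so that
    bad-channel repair can still find each bad channel's *good* neighbours
    (the zeroed rows record that bad channels never serve as neighbours).
    """

    D: np.ndarray
    labels: tuple[str, ...]
    neighbour_rule: float
    distances: np.ndarray | None = None
    bad: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        D = np.asarray(self.D)
        if not np.array_equal(D, D.T) or np.any(np.diag(D) != 0):
            raise ValueError("adjacency must be symmetric with zero diagonal")

    def good_neighbours_of(self, i: int) -> np.ndarray:
        """Indices of good channels within the distance rule of channel ``i``."""
        if self.distances is None:
            return np.where(self.D[i] > 0)[0]
        bad_idx = {self.labels.index(b) for b in self.bad}
        close = np.where(
            (self.distances[i] <= self.neighbour_rule)
            & (np.arange(len(self.labels)) != i)
        )[0]
        return np.array([j for j in close if j not in bad_idx], dtype=int)


def _filter_sos(band, fs, order=4):
    low, high = band
    nyq = fs / 2.0
    if not (0 < low < high) or low >= nyq:
        raise ValueError(f"band {band} outside (0, Nyquist={nyq}) for fs={fs}")
    if high >= 0.99 * nyq:
        # upper edge at/above Nyquist (e.g. 1-50 Hz at fs=100): high-pass only
        return signal.butter(order, low, btype="highpass", fs=fs, output="sos")
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_array(data: np.ndarray, band, fs, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    sos = _filter_sos(band, fs, order)
    return signal.sosfiltfilt(sos, data, axis=-1)


def bandpass(rec: Recording, band, order: int = 4) -> Recording:
    """Zero-phase band-pass of the EEG rows; aux rows pass through untouched."""
    filt = bandpass_array(rec.eeg, band, rec.sampling_rate, order)
    return rec.with_eeg(filt, band=tuple(band))


def detect_bad_channels(
    rec: Recording,
    band=(1.0, 80.0),
    n_sd: float = OUTLIER_SD,
) -> BadChannelReport:
    """Flag channels with outlying quality parameters.

    A channel is bad iff its in-band minimum correlation falls below
    ``mean − n_sd·sd`` or its 200–250 Hz noise variance rises above
    ``mean + n_sd·sd`` of the across-channel distributions. Constant
    channels have undefined correlation (sentinel −1 recorded) and are
    flagged outright. The noise-variance parameter needs a sampling rate
    ≥ 500 Hz and is skipped (with a warning) otherwise.
    """
    eeg = rec.eeg
    labels = rec.eeg_labels
    n_ch = eeg.shape[0]
    if n_ch < 3:
        raise InsufficientChannelsError("bad-channel detection needs >= 3 channels")

    filt = bandpass_array(eeg, band, rec.sampling_rate)
    sd = filt.std(axis=1)
    constant = sd < 1e-12 * max(sd.max(), 1e-30)
    min_corr = np.full(n_ch, -1.0)
    ok = ~constant
    if ok.sum() >= 2:
        corr = np.corrcoef(filt[ok])
        np.fill_diagonal(corr, np.nan)
        min_corr[ok] = np.nanmin(corr, axis=1)
        # a good channel correlates near zero with a constant one; keep the
        # sentinel on the constant channel only
    if rec.sampling_rate >= 2 * NOISE_BAND[1]:
        noise = bandpass_array(eeg, NOISE_BAND, rec.sampling_rate)
        noise_var = noise.var(axis=1)
    else:
        logger.warning(
            "sampling rate %.0f Hz cannot resolve the %s Hz noise band; "
            "noise-variance parameter skipped",
            rec.sampling_rate,
            NOISE_BAND,
        )
        noise_var = np.full(n_ch, np.nan)

    # across-channel statistics exclude degenerate (constant) channels: a
    # channel whose correlation is undefined is bad outright, and its -1
    # sentinel must not drag the outlier thresholds
    assessed = min_corr[ok] if ok.any() else min_corr
    cm, cs = float(np.mean(assessed)), float(np.std(assessed))
    finite_v = noise_var[np.isfinite(noise_var) & ok]
    vm = float(np.mean(finite_v)) if finite_v.size else float("nan")
    vs = float(np.std(finite_v)) if finite_v.size else float("nan")

    bad = constant | (min_corr < cm - n_sd * cs)
    if finite_v.size:
        bad |= np.isfinite(noise_var) & (noise_var > vm + n_sd * vs)
    bad_list = tuple(labels[i] for i in np.where(bad)[0])
    return BadChannelReport(
        tuple(labels), min_corr, noise_var, cm, cs, vm, vs, bad_list
    )


def build_adjacency(
    electrodes: ElectrodeSet,
    bad: tuple[str, ...] = (),
    threshold_mm: float = 40.0,
) -> ChannelAdjacency:
    """Distance-rule neighbour matrix: ``d_ij = 1`` iff the electrodes are
    within ``threshold_mm`` of each other and neither is bad."""
    P = electrodes.positions
    dist = np.linalg.norm(P[:, None] - P[None, :], axis=2)
    D = (dist <= threshold_mm).astype(int)
    np.fill_diagonal(D, 0)
    bad_idx = [electrodes.labels.index(b) for b in bad]
    D[bad_idx, :] = 0
    D[:, bad_idx] = 0
    return ChannelAdjacency(D, electrodes.labels, threshold_mm, dist, tuple(bad))


def build_correction_matrix(adjacency: ChannelAdjacency, bad: tuple[str, ...]) -> np.ndarray:
    """Bad-channel correction matrix ``C`` (identity on good channels,
    neighbour averages on bad rows)."""
    labels = adjacency.labels
    n = len(labels)
    bad_idx = [labels.index(b) for b in bad]
    C = np.eye(n)
    for i in bad_idx:
        neigh = adjacency.good_neighbours_of(i)
        if neigh.size == 0:
            raise IsolatedBadChannelError(
                f"bad channel {labels[i]!r} has no good neighbours"
            )
        C[i] = 0.0
        C[i, neigh] = 1.0 / neigh.size
    return C


def build_reference_matrix(n_e: int) -> np.ndarray:
    """Average-reference projector ``R = I − (1/n_E) 11ᵀ``."""
    if n_e < 2:
        raise ValueError("average reference needs at least 2 channels")
    return np.eye(n_e) - np.full((n_e, n_e), 1.0 / n_e)


def apply_sensor_filters(rec: Recording, C: np.ndarray, R: np.ndarray) -> Recording:
    """Apply ``X_q = C @ R @ X`` to the EEG rows (aux untouched)."""
    eeg = rec.eeg
    n_e = eeg.shape[0]
    if C.shape != (n_e, n_e) or R.shape != (n_e, n_e):
        raise ValueError("C/R shape does not match the recording's EEG channel count")
    return rec.with_eeg(C @ (R @ eeg))
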