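"""Online engine: rolling buffer, adaptive artifact filter, source stream.

Per incoming sample the engine (after the buffer first fills):

1. band-passes the current ``n_T``-sample window and applies ``C R``
   (``X_q~(tau) = C R X~(tau)``);
2. estimates the in-buffer artifact signals ``S_A(tau) = W_A X_q~(tau)``
   and the adaptive filter
   ``F(tau) = I − X_q~(tau) S_A^T (S_A S_A^T)^−1 W_A``, whose regression
   weights are re-fit per buffer to track non-stationary artifacts;
3. extracts the newest cleaned sample ``Y(t)`` of
   ``X_p~(tau) = F(tau) X_q~(tau)``;
4. localizes it: ``B(t) = K Y(t)``.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator

import numpy as np

from .calibration import SpatialFilterSet, regress_out
from .preprocess import bandpass_array
from .recording import Recording, read_recording

__all__ = [
    "StreamBuffer",
    "RealtimeConfig",
    "StreamOutput",
    "push_sample",
    "process_buffer",
    "extract_latest",
    "localize",
    "replay_recording",
    "run_stream",
    "StreamWriter",
    "offline_clean",
]

logger = logging.getLogger(__name__)


class StreamBuffer:
    """Rolling FIFO window of the ``n_T`` most recent samples."""

    def __init__(self, n_channels: int, n_samples: int):
        if n_samples < 4:
            raise ValueError("buffer must hold at least 4 samples")
        self.n_channels = int(n_channels)
        self.n_samples = int(n_samples)
        self._data = np.zeros((n_channels, n_samples))
        self._cursor = 0
        self.samples_seen = 0

    @property
    def full(self) -> bool:
        return self.samples_seen >= self.n_samples

    def push(self, sample: np.ndarray) -> None:
        sample = np.asarray(sample, float).ravel()
        if sample.size != self.n_channels:
            raise ValueError(
                f"sample has {sample.size} channels, buffer expects {self.n_channels}"
            )
        self._data[:, self._cursor] = sample
        self._cursor = (self._cursor + 1) % self.n_samples
        self.samples_seen += 1

    def window(self) -> np.ndarray:
        """Chronologically ordered copy, oldest to newest."""
        return np.roll(self._data, -self._cursor, axis=1)


def push_sample(buffer: StreamBuffer, sample) -> StreamBuffer:
    buffer.push(sample)
    return buffer


@dataclass(frozen=True)
class RealtimeConfig:
    """Streaming parameters; the buffer holds ``round(buffer_ms*fs/1000)`` samples."""

    sampling_rate: float = 100.0
    buffer_ms: float = 500.0
    band: tuple[float, float] = (1.0, 50.0)
    output_mode: str = "voxels"  # or "rois"
    refresh_stride: int = 1
    artifact_removal: bool = True
    filter_mode: str = "streaming"  # causal, persistent state; or "per-buffer"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.band[0] < self.band[1]) or self.band[0] >= self.sampling_rate / 2:
            raise ValueError("band must lie within (0, Nyquist)")
        if self.refresh_stride < 1:
            raise ValueError("refresh_stride must be >= 1")
        if self.filter_mode not in ("streaming", "per-buffer"):
            raise ValueError("filter_mode must be 'streaming' or 'per-buffer'")

    @property
    def n_buffer(self) -> int:
        return max(int(round(self.buffer_ms * self.sampling_rate / 1000.0)), 4)


@dataclass(frozen=True)
class StreamOutput:
    """One cleaned sensor sample and its source projection."""

    timestamp: int  # sample index in the input stream
    Y: np.ndarray  # (n_E,) cleaned sensor sample, uV
    B: np.ndarray  # (3 n_V,) or (3 n_R,) source sample
    latency_samples: int


def process_buffer(
    window: np.ndarray,
    filters: SpatialFilterSet,
    cfg: RealtimeConfig,
    apply_artifact_filter: bool | None = None,
    pre_filtered: bool = False,
) -> np.ndarray:
    """Clean one full buffer: band-pass, C·R, adaptive artifact regression.

    Returns the cleaned window ``X_p~(tau)``; ``W_A @ result`` is zero to
    machine precision whenever the artifact filter is applied. With
    ``pre_filtered`` (the streaming-filter engine path) the in-buffer
    band-pass is skipped because the samples already carry it.
    """
    if pre_filtered:
        xf = window
    else:
        xf = bandpass_array(window, cfg.band, cfg.sampling_rate)
    xq = filters.C @ (filters.R @ xf)
    if apply_artifact_filter is None:
        apply_artifact_filter = cfg.artifact_removal
    if not apply_artifact_filter or filters.W_A.shape[0] == 0:
        return xq
    S_A = filters.W_A @ xq
    F = regress_out(xq, S_A, filters.W_A)
    return F @ xq


def extract_latest(cleaned_window: np.ndarray) -> np.ndarray:
    """The newest cleaned sensor sample ``Y(t)`` (last column)."""
    return cleaned_window[:, -1].copy()


def localize(Y: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Source-space sample ``B(t) = K @ Y(t)``."""
    Y = np.asarray(Y, float)
    if K.shape[1] != Y.shape[-1]:
        raise ValueError(f"K expects {K.shape[1]} channels, got {Y.shape[-1]}")
    return K @ Y


def replay_recording(source, paced: bool = False) -> Iterator[np.ndarray]:
    """Yield EEG samples (columns) of a recording or file path, in order.

    With ``paced`` the iterator sleeps to approximate the sampling rate;
    replay is otherwise as fast as possible.
    """
    rec = source if isinstance(source, Recording) else read_recording(source)
    dt = 1.0 / rec.sampling_rate
    eeg = rec.eeg
    for t in range(rec.n_samples):
        if paced:
            _time.sleep(dt)
        yield eeg[:, t].copy()


class StreamWriter:
    """File sink: float32 matrices for Y and B plus a JSON sidecar."""

    def __init__(self, out_dir, filters: SpatialFilterSet, cfg: RealtimeConfig):
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self._y, self._b, self._t = [], [], []
        self._filters = filters
        self._cfg = cfg

    def __call__(self, out: StreamOutput) -> None:
        self._y.append(out.Y.astype("<f4"))
        self._b.append(out.B.astype("<f4"))
        self._t.append(out.timestamp)

    def close(self) -> dict:
        Y = np.stack(self._y, axis=1) if self._y else np.empty((0, 0), "<f4")
        B = np.stack(self._b, axis=1) if self._b else np.empty((0, 0), "<f4")
        Y.astype("<f4").tofile(self.out_dir / "sensor_stream.f32")
        B.astype("<f4").tofile(self.out_dir / "source_stream.f32")
        sidecar = {
            "labels": list(self._filters.labels),
            "n_outputs": len(self._t),
            "first_timestamp": self._t[0] if self._t else None,
            "sensor_shape": list(Y.shape),
            "source_shape": list(B.shape),
            "sampling_rate": self._cfg.sampling_rate,
            "band": list(self._cfg.band),
            "config_hash": self._filters.config_hash,
        }
        (self.out_dir / "stream.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
        return sidecar


def run_stream(
    source: Iterable[np.ndarray],
    filters: SpatialFilterSet,
    cfg: RealtimeConfig,
    sinks: tuple[Callable[[StreamOutput], None], ...] = (),
    collect: bool = True,
) -> list[StreamOutput]:
    """Drive the per-sample pipeline push -> process -> extract -> localize.

    Emits exactly one :class:`StreamOutput` per input sample once the buffer
    has filled (warm-up produces no output). ``refresh_stride > 1`` reuses
    the last adaptive filter between recomputations. Sink exceptions are
    logged and do not stop the stream.
    """
    from scipy import signal as _sps

    from .preprocess import _filter_sos

    n_e = filters.n_channels
    buf = StreamBuffer(n_e, cfg.n_buffer)
    outputs: list[StreamOutput] = []
    streaming = cfg.filter_mode == "streaming"
    if streaming:
        sos = _filter_sos(cfg.band, cfg.sampling_rate)
        zi = np.zeros((sos.shape[0], 2, n_e))
    cleaned: np.ndarray | None = None
    last_F: np.ndarray | None = None
    t = -1
    for t, sample in enumerate(source):
        if streaming:
            filtered, zi = _sps.sosfilt(sos, np.asarray(sample, float)[None, :], zi=zi, axis=0)
            buf.push(filtered[0])
        else:
            buf.push(sample)
        if not buf.full:
            continue
        window = buf.window()
        if streaming:
            xf = window
        else:
            xf = bandpass_array(window, cfg.band, cfg.sampling_rate)
        xq = filters.C @ (filters.R @ xf)
        apply_f = cfg.artifact_removal and filters.W_A.shape[0] > 0
        refresh = (t - (cfg.n_buffer - 1)) % cfg.refresh_stride == 0 or last_F is None
        if apply_f:
            if refresh:
                S_A = filters.W_A @ xq
                last_F = regress_out(xq, S_A, filters.W_A)
            cleaned = last_F @ xq
        else:
            cleaned = xq
        Y = extract_latest(cleaned)
        B = localize(Y, filters.K)
        out = StreamOutput(timestamp=t, Y=Y, B=B, latency_samples=0)
        if collect:
            outputs.append(out)
        for sink in sinks:
            try:
                sink(out)
            except Exception:  # noqa: BLE001 — a failing sink must not kill the stream
                logger.exception("sink failed at sample %d; continuing", t)
    logger.info("stream finished: %d samples in, %d outputs", t + 1, len(outputs))
    return outputs


def offline_clean(
    rec: Recording, filters: SpatialFilterSet, phase: str = "zero"
) -> np.ndarray:
    """Calibration-style cleaning of a full recording with the frozen F0.

    Band-pass -> C·R -> F0; the offline counterpart of the per-buffer
    adaptive pipeline. ``phase="zero"`` uses the calibration pipeline's
    zero-phase band-pass; ``phase="forward"`` uses the same causal filter as
    the streaming engine, so online/offline comparisons isolate the
    adaptive-regression difference instead of filter phase.
    """
    from scipy import signal as _sps

    from .preprocess import _filter_sos

    if phase == "zero":
        xf = bandpass_array(rec.eeg, filters.band, rec.sampling_rate)
    elif phase == "forward":
        sos = _filter_sos(filters.band, rec.sampling_rate)
        xf = _sps.sosfilt(sos, rec.eeg, axis=-1)
    else:
        raise ValueError("phase must be 'zero' or 'forward'")
    xq = filters.C @ (filters.R @ xf)
    return filters.F0 @ xq
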