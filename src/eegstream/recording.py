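"""Multichannel recordings and file I/O.

A :class:`Recording` holds EEG channels plus auxiliary reference channels
(vEOG/hEOG/EMG) in a single ``(n_channels, n_samples)`` float array in uV.
Supported on-disk formats: EDF and BrainVision (read, via MNE-Python) and a
neutral fixture format (JSON header + raw little-endian float32 matrix)
that round-trips exactly and is used for simulator output and tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Recording", "read_recording", "write_recording_fixture", "read_recording_fixture"]

AUX_DEFAULT_NAMES = ("vEOG", "hEOG", "EMG")


@dataclass(frozen=True)
class Recording:
    """Sensor time series with auxiliary channels.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` array in uV; EEG rows first is customary
        but not required — ``aux_map`` names the auxiliary rows.
    labels
        Unique channel names.
    sampling_rate
        Sampling frequency in Hz.
    aux_map
        Mapping of auxiliary role (e.g. ``"vEOG"``) to row index. Rows in
        ``aux_map`` are excluded from EEG processing and passed through
        spatial filters untouched.
    band
        Optional provenance tag: the (low, high) band in Hz the data were
        filtered to, or None for raw data.
    """

    data: np.ndarray
    labels: tuple[str, ...]
    sampling_rate: float
    aux_map: dict[str, int] = field(default_factory=dict)
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        if d.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if len(self.labels) != d.shape[0]:
            raise ValueError("labels length must match data rows")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(d)):
            raise ValueError("data must be finite")
        aux = {str(k): int(v) for k, v in self.aux_map.items()}
        if len(set(aux.values())) != len(aux):
            raise ValueError("aux rows must be disjoint")
        for k, v in aux.items():
            if not 0 <= v < d.shape[0]:
                raise ValueError(f"aux channel {k} row {v} out of range")
        object.__setattr__(self, "aux_map", aux)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def eeg_rows(self) -> np.ndarray:
        """Indices of the EEG (non-auxiliary) rows, in order."""
        aux = set(self.aux_map.values())
        return np.array([i for i in range(self.data.shape[0]) if i not in aux])

    @property
    def eeg_labels(self) -> tuple[str, ...]:
        return tuple(self.labels[i] for i in self.eeg_rows)

    @property
    def eeg(self) -> np.ndarray:
        """The ``(n_E, n_T)`` EEG submatrix (a view when rows are contiguous)."""
        return self.data[self.eeg_rows]

    def aux(self, name: str) -> np.ndarray:
        """Time course of an auxiliary channel by role name."""
        return self.data[self.aux_map[name]]

    def with_eeg(self, eeg: np.ndarray, band=None) -> "Recording":
        """Return a copy whose EEG rows are replaced (aux passed through)."""
        eeg = np.asarray(eeg, dtype=float)
        rows = self.eeg_rows
        if eeg.shape != (len(rows), self.n_samples):
            raise ValueError("replacement EEG shape mismatch")
        data = self.data.copy()
        data[rows] = eeg
        return replace(self, data=data, band=band if band is not None else self.band)


def write_recording_fixture(rec: Recording, path) -> None:
    """Write the neutral fixture format: ``<path>.json`` header + ``<path>.f32`` matrix."""
    path = Path(path)
    header = {
        "labels": list(rec.labels),
        "sampling_rate": rec.sampling_rate,
        "aux_map": rec.aux_map,
        "band": list(rec.band) if rec.band else None,
        "n_channels": rec.data.shape[0],
        "n_samples": rec.data.shape[1],
        "dtype": "<f4",
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1, sort_keys=True))
    rec.data.astype("<f4").tofile(path.with_suffix(".f32"))


def read_recording_fixture(path) -> Recording:
    """Read the neutral fixture format written by :func:`write_recording_fixture`."""
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    n_ch, n_s = header["n_channels"], header["n_samples"]
    raw = np.fromfile(path.with_suffix(".f32"), dtype=header.get("dtype", "<f4"))
    if raw.size != n_ch * n_s:
        raise ValueError(
            f"truncated fixture {path.with_suffix('.f32')}: expected "
            f"{n_ch * n_s} values ({4 * n_ch * n_s} bytes), found {raw.size} "
            f"({4 * raw.size} bytes)"
        )
    return Recording(
        raw.reshape(n_ch, n_s).astype(float),
        tuple(header["labels"]),
        float(header["sampling_rate"]),
        {k: int(v) for k, v in header.get("aux_map", {}).items()},
        tuple(header["band"]) if header.get("band") else None,
    )


def _aux_map_from_labels(labels, aux_names) -> dict[str, int]:
    lower = {l.lower(): i for i, l in enumerate(labels)}
    return {name: lower[name.lower()] for name in aux_names if name.lower() in lower}


def read_recording(path, aux_names=AUX_DEFAULT_NAMES) -> Recording:
    """Read a recording from EDF, BrainVision (.vhdr) or the fixture format.

    Channels whose label matches an entry of ``aux_names`` (case-insensitive)
    are registered as auxiliary channels.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".json", ".f32", ""}:
        return read_recording_fixture(path)
    if suffix == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif suffix == ".vhdr":
        import mne

        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported recording format: {path.suffix}")
    data = raw.get_data() * 1e6  # MNE uses volts internally
    labels = tuple(raw.ch_names)
    return Recording(
        data, labels, float(raw.info["sfreq"]), _aux_map_from_labels(labels, aux_names)
    )
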