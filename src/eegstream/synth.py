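"""Ground-truth simulator for calibration and task recordings.

Generates multichannel EEG with the statistical structure the pipeline
assumes: band-limited dipolar cortical sources mixed through the leadfield,
task-locked beta-band desynchronization in a 6 s move / 6 s rest trial
design, stylized blink (EOG-correlated) and muscle (EMG-correlated)
artifact components with declared topographies, and white sensor noise.
Every recording is accompanied by a :class:`GroundTruth` carrying the
exact source and artifact time courses, onsets and injected bad channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .forward import Leadfield, compute_leadfield
from .geometry import (
    ElectrodeSet,
    SourceGrid,
    SphericalHeadModel,
    build_source_grid,
)
from .preprocess import bandpass_array
from .recording import Recording

__all__ = [
    "SourceSpec",
    "BlinkSpec",
    "EMGArtifactSpec",
    "SimulationSpec",
    "GroundTruth",
    "fibonacci_montage",
    "example_setup",
    "make_task_modulation",
    "simulate_recording",
    "inject_bad_channel",
    "calibration_spec",
    "task_spec",
]


def fibonacci_montage(
    n: int = 32,
    model: SphericalHeadModel | None = None,
    cap_fraction: float = 0.6,
) -> ElectrodeSet:
    """Quasi-uniform synthetic montage on the upper scalp (Fibonacci lattice).

    Covers the spherical cap ``z/r > 1 - 2*cap_fraction``; fiducials are the
    canonical scalp landmarks, so the montage is already in model space.
    """
    model = model or SphericalHeadModel()
    golden = (1 + 5**0.5) / 2
    i = np.arange(n)
    z = 1.0 - (i + 0.5) / n * 2 * cap_fraction  # top of sphere downwards
    phi = 2 * np.pi * i / golden
    rho = np.sqrt(1 - z**2)
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    positions = model.center + model.r_scalp * pts
    labels = tuple(f"E{i + 1:03d}" for i in range(n))
    return ElectrodeSet(labels, positions, model.scalp_fiducials())


def example_setup(
    n_electrodes: int = 32,
    spacing: float = 20.0,
    model: SphericalHeadModel | None = None,
) -> tuple[ElectrodeSet, SphericalHeadModel, SourceGrid, Leadfield]:
    """Desk-scale default study setup: 32-channel montage, 20 mm source grid."""
    model = model or SphericalHeadModel()
    electrodes = fibonacci_montage(n_electrodes, model)
    grid = build_source_grid(model, spacing=spacing)
    lf = compute_leadfield(model, electrodes, grid)
    return electrodes, model, grid, lf


@dataclass(frozen=True)
class SourceSpec:
    """One band-limited dipolar cortical source.

    ``amplitude_uv`` sets the RMS sensor footprint (uV across channels) at
    rest; during move windows the amplitude is scaled by
    ``modulation_depth`` in (0, 1], so the expected beta ERD is
    ``(depth² − 1)·100 %``.
    """

    voxel: int
    orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    band: tuple[float, float] = (13.0, 30.0)
    amplitude_uv: float = 10.0
    modulation_depth: float = 1.0
    carrier: str = "comb"  # "comb": random-phase harmonic comb; "noise": filtered noise

    def __post_init__(self) -> None:
        if not 0 < self.modulation_depth <= 1:
            raise ValueError("modulation_depth must be in (0, 1]")
        if self.carrier not in ("comb", "noise"):
            raise ValueError("carrier must be 'comb' or 'noise'")


@dataclass(frozen=True)
class BlinkSpec:
    """Stylized ocular artifact: Poisson train of 300 ms biphasic pulses
    projected through a frontal-superior topography."""

    rate_per_min: float = 18.0  # spontaneous blink rates run ~12-20/min
    duration_s: float = 0.3
    amplitude_uv: float = 150.0  # frontal blink deflections are ~100-300 uV peak


@dataclass(frozen=True)
class EMGArtifactSpec:
    """Muscle artifact: in-band (20–50 Hz) noise bursts on an edge-channel
    topography, not removable by band-pass alone."""

    rate_per_min: float = 8.0
    duration_s: float = 1.0
    band: tuple[float, float] = (20.0, 50.0)
    amplitude_uv: float = 8.0
    n_edge_channels: int = 6


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one simulated recording.

    ``background_uv`` sets the total sensor RMS footprint of ubiquitous,
    spatially incoherent background beta activity (independent weak
    generators at every grid voxel). It is what makes simulated ERD maps
    focal: without it, every voxel's beta content is a scaled copy of the
    one focal source and the ERD map is flat.
    """

    sources: tuple[SourceSpec, ...]
    duration_s: float
    sampling_rate: float = 100.0
    move_s: float = 6.0
    rest_s: float = 6.0
    n_trials: int = 0  # 0 -> resting recording, no task structure
    blink: BlinkSpec | None = None
    emg: EMGArtifactSpec | None = None
    noise_sd_uv: float = 1.0
    background_uv: float = 2.0
    background_band: tuple[float, float] = (13.0, 30.0)
    bad_channels: tuple[tuple[str, str], ...] = ()  # (label, mode) pairs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials:
            need = self.n_trials * (self.move_s + self.rest_s)
            if self.duration_s < need - 1e-9:
                raise ValueError(
                    f"duration {self.duration_s}s too short for {self.n_trials} trials"
                )


@dataclass(frozen=True)
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    source_timecourses: np.ndarray  # (n_sources, n_samples), uV sensor scale
    source_voxels: tuple[int, ...]
    blink_reference: np.ndarray | None
    blink_topography: np.ndarray | None
    emg_reference: np.ndarray | None
    emg_topography: np.ndarray | None
    onsets: np.ndarray  # sample indices of movement onsets
    bad_channels: tuple[str, ...]


def make_task_modulation(
    n_samples: int,
    fs: float,
    onsets: np.ndarray,
    depth: float,
    move_s: float,
    ramp_s: float = 0.25,
) -> np.ndarray:
    """Amplitude envelope: 1 at rest, ``depth`` throughout each move window.

    The desynchronizing raised-cosine ramp is *centred on the onset marker*
    (cortical beta suppression is already underway at the EMG-defined
    movement onset); the recovery ramp is centred on the move-window end.
    """
    if not 0 < depth <= 1:
        raise ValueError("depth must be in (0, 1]")
    onsets = np.asarray(onsets, dtype=int)
    move_n = int(round(move_s * fs))
    ramp_n = max(int(round(ramp_s * fs)), 1)
    if np.any(np.diff(onsets) < move_n + 2 * ramp_n):
        raise ValueError("overlapping move windows")
    env = np.ones(n_samples)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))  # 0 -> 1
    half = ramp_n // 2

    def paste(start: int, values: np.ndarray) -> None:
        lo, hi = max(start, 0), min(start + len(values), n_samples)
        if lo < hi:
            env[lo:hi] = values[lo - start : hi - start]

    for o in onsets:
        end = o + move_n
        paste(o - half, 1 + (depth - 1) * ramp)
        env[max(o - half + ramp_n, 0) : min(end - half, n_samples)] = depth
        paste(end - half, depth + (1 - depth) * ramp)
    return env


def _narrowband_noise(rng, n, fs, band) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band``."""
    x = bandpass_array(rng.standard_normal(n), band, fs)
    return x / x.std()


def _harmonic_comb(rng, n, fs, band, df: float = 1.0) -> np.ndarray:
    """Unit-RMS random-phase harmonic comb spanning ``band``.

    A stationary band-limited rhythm whose power is nearly constant over
    analysis windows (unlike filtered noise, whose windowed power
    fluctuates with ~1/sqrt(2BT) relative spread).
    """
    freqs = np.arange(band[0], min(band[1], 0.49 * fs) + 1e-9, df)
    t = np.arange(n) / fs
    phases = rng.uniform(0, 2 * np.pi, size=len(freqs))
    x = np.sum(np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]), axis=0)
    return x / x.std()


def _pulse_train(rng, n, fs, rate_per_min, template) -> tuple[np.ndarray, np.ndarray]:
    """Poisson train of template pulses; returns (signal, event start indices)."""
    sig = np.zeros(n)
    rate_hz = rate_per_min / 60.0
    events = []
    t = rng.exponential(1 / rate_hz) if rate_hz > 0 else np.inf
    min_gap = len(template) / fs
    while t * fs < n - len(template):
        i = int(t * fs)
        sig[i : i + len(template)] += template
        events.append(i)
        t += max(rng.exponential(1 / rate_hz), min_gap)
    return sig, np.array(events, dtype=int)


def _blink_template(fs: float, duration_s: float) -> np.ndarray:
    n = max(int(round(duration_s * fs)), 4)
    t = np.linspace(0, 1, n, endpoint=False)
    # biphasic: dominant positive lobe with a shallow negative rebound
    return np.sin(np.pi * t) ** 2 * np.where(t < 0.7, 1.0, -0.6)


def _unit_rms(v: np.ndarray) -> np.ndarray:
    rms = np.sqrt(np.mean(v**2))
    if rms == 0:
        raise ValueError("zero topography")
    return v / rms


def simulate_recording(
    spec: SimulationSpec, lf: Leadfield
) -> tuple[Recording, GroundTruth]:
    """Simulate one recording through the leadfield; deterministic per seed.

    Sensor model: ``X = sum_s topo_s a_s(t) + blink + emg + noise`` with each
    source topography drawn from the leadfield block of its voxel and
    normalized to unit RMS across channels. Auxiliary channels carry the
    artifact reference signals plus independent noise; in task mode the EMG
    channel additionally carries movement bursts aligned to the true onsets.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    n = int(round(spec.duration_s * fs))
    n_e = lf.n_electrodes
    for s in spec.sources:
        if not 0 <= s.voxel < lf.n_voxels:
            raise ValueError(f"source voxel {s.voxel} outside leadfield grid")

    if spec.n_trials:
        trial_n = int(round((spec.move_s + spec.rest_s) * fs))
        onsets = (np.arange(spec.n_trials) * trial_n + int(round(spec.rest_s * fs)))
    else:
        onsets = np.array([], dtype=int)

    X = np.zeros((n_e, n))
    truths = []
    for s in spec.sources:
        if s.carrier == "comb":
            carrier = _harmonic_comb(rng, n, fs, s.band)
        else:
            carrier = _narrowband_noise(rng, n, fs, s.band)
        env = (
            make_task_modulation(n, fs, onsets, s.modulation_depth, spec.move_s)
            if onsets.size and s.modulation_depth < 1
            else np.ones(n)
        )
        course = s.amplitude_uv * env * carrier
        topo = _unit_rms(lf.voxel_block(s.voxel) @ np.asarray(s.orientation, float))
        X += topo[:, None] * course[None, :]
        truths.append(course)

    if spec.background_uv > 0:
        nv = lf.n_voxels
        bband = (spec.background_band[0], min(spec.background_band[1], 0.45 * fs))
        bg = bandpass_array(rng.standard_normal((nv, n)), bband, fs)
        bg /= bg.std(axis=1, keepdims=True)
        G3 = lf.gain.reshape(n_e, nv, 3)
        pos = lf.grid.voxel_positions - lf.grid.voxel_positions.mean(0)
        norms = np.linalg.norm(pos, axis=1)
        U = np.where(norms[:, None] > 1e-9, pos / np.maximum(norms, 1e-9)[:, None], [0, 0, 1.0])
        topo_bg = np.einsum("evd,vd->ev", G3, U)
        Xbg = topo_bg @ bg
        Xbg *= spec.background_uv / np.sqrt(np.mean(Xbg**2))
        X += Xbg

    blink_ref = blink_topo = None
    if spec.blink is not None and spec.blink.rate_per_min > 0:
        template = _blink_template(fs, spec.blink.duration_s)
        blink_ref, _ = _pulse_train(rng, n, fs, spec.blink.rate_per_min, template)
        # topography: leadfield block of the most frontal-superior voxel plus
        # a declared frontal gradient over the electrodes (average-reference span)
        pos = lf.grid.voxel_positions
        v_front = int(np.argmax(pos[:, 1] + pos[:, 2]))
        v_ant = int(np.argmax(pos[:, 1]))
        col = _unit_rms(lf.voxel_block(v_front) @ np.array([0.0, 0.7, 0.7]))
        grad = _unit_rms(lf.voxel_block(v_ant) @ np.array([0.0, 1.0, 0.0]))
        blink_topo = _unit_rms(0.7 * col + 0.3 * grad) * spec.blink.amplitude_uv
        X += blink_topo[:, None] * blink_ref[None, :]

    emg_ref = emg_topo = None
    if spec.emg is not None and spec.emg.rate_per_min > 0:
        burst_n = int(round(spec.emg.duration_s * fs))
        burst_env = np.sin(np.pi * np.linspace(0, 1, burst_n, endpoint=False)) ** 2
        gate, _ = _pulse_train(rng, n, fs, spec.emg.rate_per_min, burst_env)
        # clamp the burst band inside Nyquist for low sampling rates
        eband = (spec.emg.band[0], min(spec.emg.band[1], 0.45 * fs))
        emg_ref = gate * _narrowband_noise(rng, n, fs, eband)
        edge = np.argsort(np.linalg.norm(lf.gain, axis=1))[: spec.emg.n_edge_channels]
        emg_topo = np.zeros(n_e)
        emg_topo[edge] = 1.0 + 0.5 * rng.random(spec.emg.n_edge_channels)
        emg_topo -= emg_topo.mean()  # keep artifact in average-reference span
        emg_topo = _unit_rms(emg_topo) * spec.emg.amplitude_uv
        X += emg_topo[:, None] * emg_ref[None, :]

    X += spec.noise_sd_uv * rng.standard_normal((n_e, n))

    # emulate common-reference acquisition: every recorded channel is the
    # scalp potential minus the reference-site potential (approximated as
    # the mean of the three most superior channels). The average-reference
    # projector R removes this common mode exactly; before re-referencing
    # it gives raw channels the positive inter-correlations real
    # common-referenced recordings show, which the bad-channel detector
    # relies on.
    if lf.electrode_positions is not None:
        ref_rows = np.argsort(lf.electrode_positions[:, 2])[-3:]
    else:
        ref_rows = np.arange(min(3, n_e))
    X = X - X[ref_rows].mean(axis=0, keepdims=True)

    # auxiliary channels: artifact references plus independent noise
    aux_rows = []
    veog = 50.0 * (blink_ref if blink_ref is not None else np.zeros(n))
    veog = veog + 2.0 * rng.standard_normal(n)
    heog = (15.0 * blink_ref if blink_ref is not None else np.zeros(n)) + 2.0 * rng.standard_normal(n)
    emg_aux = 20.0 * (emg_ref if emg_ref is not None else np.zeros(n))
    if onsets.size:
        move_env = 1.0 - make_task_modulation(n, fs, onsets, 1e-9, spec.move_s)
        emg_aux = emg_aux + 40.0 * move_env * _narrowband_noise(
            rng, n, fs, (20.0, 0.45 * fs)
        )
    emg_aux = emg_aux + 2.0 * rng.standard_normal(n)
    aux_rows = [veog, heog, emg_aux]

    labels = list(lf.electrode_order) + ["vEOG", "hEOG", "EMG"]
    data = np.vstack([X] + [a[None, :] for a in aux_rows])
    aux_map = {"vEOG": n_e, "hEOG": n_e + 1, "EMG": n_e + 2}
    rec = Recording(data, tuple(labels), fs, aux_map)

    truth = GroundTruth(
        source_timecourses=np.array(truths) if truths else np.empty((0, n)),
        source_voxels=tuple(s.voxel for s in spec.sources),
        blink_reference=blink_ref,
        blink_topography=blink_topo,
        emg_reference=emg_ref,
        emg_topography=emg_topo,
        onsets=onsets,
        bad_channels=tuple(b for b, _ in spec.bad_channels),
    )
    for label, mode in spec.bad_channels:
        rec = inject_bad_channel(rec, label, mode, seed=spec.seed + 7)
    return rec, truth


def inject_bad_channel(rec: Recording, channel: str, mode: str, seed: int = 0) -> Recording:
    """Replace one EEG channel by a flat trace or by strong broadband noise
    (dominating the 200–250 Hz quality band)."""
    if channel in rec.aux_map:
        raise ValueError("cannot inject a bad auxiliary channel")
    idx = rec.labels.index(channel)
    rng = np.random.default_rng(seed)
    data = rec.data.copy()
    if mode == "flat":
        data[idx] = 0.0
    elif mode == "hf-noise":
        scale = 10.0 * max(np.std(rec.eeg), 1.0)
        data[idx] = scale * rng.standard_normal(rec.n_samples)
    else:
        raise ValueError(f"unknown bad-channel mode: {mode}")
    return replace(rec, data=data)


def study_sources(lf: Leadfield, seed: int = 0) -> tuple[SourceSpec, ...]:
    """The resting repertoire of the simulated brain: a beta (13–30 Hz), an
    alpha (8–12 Hz) and a theta (4–7 Hz) rhythm at well-separated mid-depth
    voxels. The beta source (index 0) is the one modulated by the task.

    The same repertoire must appear in both the calibration and the task
    recording: the artifact unmixing rows learned by ICA are orthogonal
    only to topographies present in the calibration mixture, exactly as
    with real resting rhythms.
    """
    voxels = _spread_voxels(lf, 3, seed)
    # alpha capped at 11 Hz: the 4th-order beta-band (13-30 Hz) filter edge
    # still passes appreciable 12 Hz power, which would alias alpha activity
    # into beta-band maps
    bands = [(13.0, 30.0), (8.0, 11.0), (4.0, 7.0)]
    return tuple(
        SourceSpec(voxel=v, orientation=_radialish(lf, v), band=b)
        for v, b in zip(voxels, bands)
    )


def calibration_spec(
    lf: Leadfield,
    duration_s: float = 60.0,
    seed: int = 0,
    with_artifacts: bool = True,
) -> SimulationSpec:
    """Resting calibration recording: the study's source repertoire plus
    blinks and muscle artifacts, no task structure."""
    return SimulationSpec(
        sources=study_sources(lf, seed),
        duration_s=duration_s,
        blink=BlinkSpec() if with_artifacts else None,
        emg=EMGArtifactSpec() if with_artifacts else None,
        seed=seed,
    )


def task_spec(
    lf: Leadfield,
    n_trials: int = 20,
    modulation_depth: float = 0.5,
    seed: int = 0,
    with_blinks: bool = True,
) -> SimulationSpec:
    """Task recording paired with :func:`calibration_spec` at the same seed.

    Same source repertoire; the beta source's amplitude drops to
    ``modulation_depth`` during each 6 s move window (expected beta ERD
    ``(depth²−1)·100 %``), 6 s rest between, blinks on, and movement bursts
    on the EMG auxiliary channel aligned to the true onsets. The sensor
    muscle-artifact generator is off: during the task the EMG channel is
    dominated by movement itself.
    """
    sources = study_sources(lf, seed)
    sources = (replace(sources[0], modulation_depth=modulation_depth),) + sources[1:]
    return SimulationSpec(
        sources=sources,
        duration_s=n_trials * 12.0,
        n_trials=n_trials,
        blink=BlinkSpec() if with_blinks else None,
        emg=None,
        seed=seed + 1,  # a different realization of the same generators
    )


def _spread_voxels(lf: Leadfield, k: int, seed: int) -> list[int]:
    """Deterministic well-separated mid-depth voxels with strong gain."""
    pos = lf.grid.voxel_positions
    r = np.linalg.norm(pos - pos.mean(0), axis=1)
    mid = np.where((r > 0.4 * r.max()) & (r < 0.8 * r.max()))[0]
    rng = np.random.default_rng(seed)
    chosen = [int(mid[rng.integers(len(mid))])]
    while len(chosen) < k:
        d = np.min(
            np.linalg.norm(pos[mid][:, None] - pos[chosen][None, :], axis=2), axis=1
        )
        chosen.append(int(mid[np.argmax(d)]))
    return chosen


def _radialish(lf: Leadfield, voxel: int) -> tuple[float, float, float]:
    """Outward radial orientation (strong scalp projection) for a voxel."""
    p = lf.grid.voxel_positions[voxel]
    center = lf.grid.voxel_positions.mean(0)
    v = p - center
    nv = np.linalg.norm(v)
    if nv < 1e-9:
        return (0.0, 0.0, 1.0)
    u = v / nv
    return (float(u[0]), float(u[1]), float(u[2]))
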