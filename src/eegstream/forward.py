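"""Forward model: analytic three-shell spherical leadfield.

The scalp potential obeys the linear forward relation ``theta(t) = L @ J(t)``
where ``L`` is the ``(n_E, 3 n_V)`` gain matrix over a regular volumetric
source grid and ``J`` stacks the three Cartesian dipole-moment components
per voxel. The gain is computed from the classical series solution for a
current dipole inside three concentric conducting shells (brain, skull,
scalp): per Legendre degree ``n`` the boundary-value problem reduces to a
small linear system whose solution gives a transfer coefficient ``tau_n``;
the potential at a scalp electrode is the dipole's multipole expansion
weighted by these coefficients.

Units: positions mm, dipole moments nA*m, potentials uV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ElectrodeSet, SourceGrid, SphericalHeadModel

__all__ = ["Leadfield", "compute_leadfield", "save_leadfield", "load_leadfield"]


class ConvergenceError(RuntimeError):
    """The Legendre series did not reach the requested tolerance."""


class CompatibilityError(ValueError):
    """A stored leadfield does not match the current electrode set or grid."""


@dataclass(frozen=True)
class Leadfield:
    """Gain matrix ``(n_E, 3 n_V)`` with its electrode ordering and grid.

    ``gain[e, 3*v + d]`` is the potential at electrode ``e`` for a unit
    dipole at voxel ``v`` along Cartesian axis ``d`` (x fastest voxel
    ordering inherited from the grid). If ``referenced`` the columns are in
    average reference (zero mean across electrodes).
    """

    gain: np.ndarray
    electrode_order: tuple[str, ...]
    grid: SourceGrid
    referenced: bool = True
    model: SphericalHeadModel | None = None
    electrode_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.gain, dtype=float)
        object.__setattr__(self, "gain", g)
        object.__setattr__(self, "electrode_order", tuple(self.electrode_order))
        if g.ndim != 2:
            raise ValueError("gain must be 2-D")
        if g.shape[0] != len(self.electrode_order):
            raise ValueError("gain row count must match electrode_order")
        if g.shape[1] != 3 * self.grid.n_voxels:
            raise CompatibilityError(
                f"gain has {g.shape[1]} columns, grid implies {3 * self.grid.n_voxels}"
            )
        if not np.all(np.isfinite(g)):
            raise ValueError("gain must be finite")
        if self.referenced:
            col_mean = np.abs(g.mean(axis=0))
            scale = np.abs(g).max() or 1.0
            if col_mean.max() > 1e-12 * scale:
                raise ValueError("referenced leadfield columns must have zero mean")

    @property
    def n_electrodes(self) -> int:
        return self.gain.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.grid.n_voxels

    def voxel_block(self, v: int) -> np.ndarray:
        """The ``(n_E, 3)`` gain block of voxel ``v``."""
        return self.gain[:, 3 * v : 3 * v + 3]


def _shell_transfer(model: SphericalHeadModel, n_max: int) -> np.ndarray:
    """Transfer coefficients tau_n, n = 1..n_max, for the three-shell sphere.

    Radii are normalised by the scalp radius. The primary (infinite-medium)
    dipole potential contributes a term ``rho**-(n+1)`` in the innermost
    layer with unit coefficient; tau_n is the resulting total potential at
    the scalp surface. For equal conductivities tau_n = (2n+1)/n, the
    homogeneous-sphere response.
    """
    a = model.r_brain / model.r_scalp
    b = model.r_skull / model.r_scalp
    s1, s2, s3 = model.conductivities
    taus = np.empty(n_max + 1)
    taus[0] = 0.0
    for n in range(1, n_max + 1):
        # unknowns: A1, A2, B2, A3, B3 (layer potentials A r^n + B r^-(n+1))
        an, ain = a**n, a ** -(n + 1)
        bn, bin_ = b**n, b ** -(n + 1)
        M = np.array(
            [
                [an, -an, -ain, 0.0, 0.0],
                [s1 * n * an, -s2 * n * an, s2 * (n + 1) * ain, 0.0, 0.0],
                [0.0, bn, bin_, -bn, -bin_],
                [0.0, s2 * n * bn, -s2 * (n + 1) * bin_, -s3 * n * bn, s3 * (n + 1) * bin_],
                [0.0, 0.0, 0.0, n, -(n + 1)],
            ]
        )
        rhs = np.array([-ain, s1 * (n + 1) * ain, 0.0, 0.0, 0.0])
        # row equilibration keeps the solve well-scaled at large n
        scale = np.abs(M).max(axis=1)
        sol = np.linalg.solve(M / scale[:, None], rhs / scale)
        taus[n] = sol[3] + sol[4]  # A3 + B3 at rho = 1
    return taus


def _dipole_potentials(
    elec_unit: np.ndarray,
    dip_pos: np.ndarray,
    model: SphericalHeadModel,
    taus: np.ndarray,
    tol: float,
) -> np.ndarray:
    """Potentials (uV) at scalp electrodes for unit x/y/z dipoles (nA*m) at one voxel.

    Returns an ``(n_E, 3)`` array. ``elec_unit`` holds unit vectors from the
    sphere center to each electrode.
    """
    R = model.r_scalp
    sigma1 = model.conductivities[0]
    rel = np.asarray(dip_pos, float) - model.center
    bnorm = np.linalg.norm(rel)
    if bnorm >= model.r_brain:
        raise ValueError("dipole lies outside the brain shell")
    t = bnorm / R
    r0_hat = rel / bnorm if bnorm > 0 else np.array([0.0, 0.0, 1.0])
    x = np.clip(elec_unit @ r0_hat, -1.0, 1.0)  # cos(gamma) per electrode

    n_max = len(taus) - 1
    nE = elec_unit.shape[0]
    # Legendre recurrences: P_n(x) and P_n'(x)
    p_prev = np.ones(nE)  # P_0
    p_cur = x.copy()  # P_1
    dp_prev = np.zeros(nE)  # P_0'
    dp_cur = np.ones(nE)  # P_1'
    s_rad = np.zeros(nE)  # sum tau_n * n * t^(n-1) * P_n
    s_tan = np.zeros(nE)  # sum tau_n * t^(n-1) * P_n'
    tpow = 1.0  # t^(n-1)
    converged = False
    for n in range(1, n_max + 1):
        term_r = taus[n] * n * tpow * p_cur
        term_t = taus[n] * tpow * dp_cur
        s_rad += term_r
        s_tan += term_t
        tail = taus[n] * tpow * n * (n + 1)  # bound on both angular factors
        ref = max(np.abs(s_rad).max(), np.abs(s_tan).max(), 1e-300)
        if n >= 10 and tail < tol * ref * (1.0 - t):
            converged = True
            break
        # advance recurrences to degree n+1
        p_next = ((2 * n + 1) * x * p_cur - n * p_prev) / (n + 1)
        dp_next = dp_prev + (2 * n + 1) * p_cur
        p_prev, p_cur = p_cur, p_next
        dp_prev, dp_cur = dp_cur, dp_next
        tpow *= t
    if not converged and t > 0.5:
        raise ConvergenceError(
            f"series not converged at order {n_max} for source radius ratio {t:.3f}"
        )
    # geometric factors: V(m) = k * (s_rad * (m . r0_hat) + s_tan * (w . m_tang))
    # with w = e_hat - cos(gamma) r0_hat and m_tang = m - (m . r0_hat) r0_hat
    w = elec_unit - x[:, None] * r0_hat[None, :]
    k = 1e-9 / (4 * np.pi * sigma1 * (R * 1e-3) ** 2) * 1e6  # nA*m -> uV
    out = np.empty((nE, 3))
    eye = np.eye(3)
    for d in range(3):
        m = eye[d]
        m_r = m @ r0_hat
        m_t = m - m_r * r0_hat
        out[:, d] = k * (s_rad * m_r + s_tan * (w @ m_t))
    return out


def compute_leadfield(
    model: SphericalHeadModel,
    electrodes: ElectrodeSet,
    grid: SourceGrid,
    n_max: int = 200,
    tol: float = 1e-8,
    referenced: bool = True,
) -> Leadfield:
    """Compute the three-shell spherical leadfield on a source grid.

    Electrodes must lie on the scalp sphere (co-register first). The series
    is truncated adaptively once the tail bound falls below ``tol`` relative
    to the running sum, up to degree ``n_max``. With ``referenced`` the
    columns are projected to average reference.
    """
    rel = electrodes.positions - model.center
    norms = np.linalg.norm(rel, axis=1)
    if np.any(np.abs(norms - model.r_scalp) > 1e-6 * model.r_scalp):
        raise ValueError("electrodes must lie on the scalp sphere; co-register first")
    elec_unit = rel / norms[:, None]
    taus = _shell_transfer(model, n_max)
    n_v = grid.n_voxels
    gain = np.empty((electrodes.n_channels, 3 * n_v))
    for v in range(n_v):
        gain[:, 3 * v : 3 * v + 3] = _dipole_potentials(
            elec_unit, grid.voxel_positions[v], model, taus, tol
        )
    if referenced:
        gain -= gain.mean(axis=0, keepdims=True)
    return Leadfield(
        gain, electrodes.labels, grid, referenced=referenced, model=model,
        electrode_positions=electrodes.positions.copy(),
    )


def save_leadfield(lf: Leadfield, path) -> None:
    """Write a leadfield archive (HDF5: gain, labels, grid and model metadata)."""
    import h5py

    with h5py.File(path, "w", track_order=True) as f:
        f.create_dataset("gain", data=lf.gain, track_times=False)
        f.create_dataset(
            "labels",
            data=np.array(lf.electrode_order, dtype="S32"),
            track_times=False,
        )
        f.create_dataset("voxel_positions", data=lf.grid.voxel_positions, track_times=False)
        f.attrs["spacing"] = lf.grid.spacing
        f.attrs["inside_mask_radius"] = lf.grid.inside_mask_radius
        f.attrs["referenced"] = bool(lf.referenced)
        if lf.model is not None:
            f.attrs["model_center"] = lf.model.center
            f.attrs["model_radii"] = lf.model.radii
            f.attrs["model_conductivities"] = lf.model.conductivities
        if lf.electrode_positions is not None:
            f.create_dataset(
                "electrode_positions", data=lf.electrode_positions, track_times=False
            )


def load_leadfield(path, electrodes: ElectrodeSet | None = None) -> Leadfield:
    """Load a leadfield archive; optionally validate against an electrode set."""
    import h5py

    with h5py.File(path, "r") as f:
        gain = f["gain"][()]
        labels = tuple(s.decode() for s in f["labels"][()])
        grid = SourceGrid(
            f["voxel_positions"][()],
            float(f.attrs["spacing"]),
            float(f.attrs["inside_mask_radius"]),
        )
        referenced = bool(f.attrs["referenced"])
        positions = f["electrode_positions"][()] if "electrode_positions" in f else None
        model = None
        if "model_radii" in f.attrs:
            model = SphericalHeadModel(
                center=np.asarray(f.attrs["model_center"]),
                radii=tuple(f.attrs["model_radii"]),
                conductivities=tuple(f.attrs["model_conductivities"]),
            )
    if gain.shape[1] != 3 * grid.n_voxels:
        raise CompatibilityError(
            f"gain has {gain.shape[1]} columns but grid has {grid.n_voxels} voxels"
        )
    if electrodes is not None and tuple(electrodes.labels) != labels:
        raise CompatibilityError("leadfield electrode labels do not match electrode set")
    return Leadfield(
        gain, labels, grid, referenced=referenced, model=model,
        electrode_positions=positions,
    )
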