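"""Head geometry: electrode sets, spherical head models and volumetric source grids.

Coordinate convention: right-handed head frame, origin at the sphere center,
+x right, +y anterior, +z superior, all lengths in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ElectrodeSet",
    "SphericalHeadModel",
    "SourceGrid",
    "read_electrodes",
    "fit_sphere_to_electrodes",
    "coregister_electrodes",
    "build_source_grid",
]

#: default fiducial labels, matched case-insensitively
FIDUCIAL_ALIASES = {
    "nasion": ("nz", "nas", "nasion"),
    "lpa": ("lpa", "left", "al"),
    "rpa": ("rpa", "right", "ar"),
}


class FiducialError(ValueError):
    """Missing or degenerate (collinear) anatomical landmarks."""


class DegenerateFitError(ValueError):
    """Sphere fit attempted on rank-deficient (coplanar) positions."""


@dataclass(frozen=True)
class ElectrodeSet:
    """Named scalp electrodes with anatomical landmark (fiducial) positions.

    Parameters
    ----------
    labels
        Unique channel names, one per electrode.
    positions
        ``(n_E, 3)`` coordinates in mm.
    fiducials
        Mapping of landmark name (``nasion``, ``lpa``, ``rpa``) to a 3-vector.
    reference_label
        Optional name of the physical reference channel.
    """

    labels: tuple[str, ...]
    positions: np.ndarray
    fiducials: dict[str, np.ndarray] = field(default_factory=dict)
    reference_label: str | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (n_E, 3) array")
        if len(self.labels) != pos.shape[0]:
            raise ValueError("labels and positions length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        if not np.all(np.isfinite(pos)):
            raise ValueError("electrode positions must be finite")
        fids = {k: np.asarray(v, dtype=float) for k, v in self.fiducials.items()}
        object.__setattr__(self, "fiducials", fids)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def fiducial_matrix(self) -> np.ndarray:
        """Return the (3, 3) array [nasion; lpa; rpa]; raise if absent or collinear."""
        missing = [k for k in ("nasion", "lpa", "rpa") if k not in self.fiducials]
        if missing:
            raise FiducialError(f"missing fiducials: {missing}")
        F = np.stack([self.fiducials[k] for k in ("nasion", "lpa", "rpa")])
        if not np.all(np.isfinite(F)):
            raise FiducialError("non-finite fiducial coordinates")
        v1, v2 = F[1] - F[0], F[2] - F[0]
        cross = np.linalg.norm(np.cross(v1, v2))
        scale = max(np.linalg.norm(v1) * np.linalg.norm(v2), 1e-30)
        if cross / scale < 1e-8:
            raise FiducialError("fiducials are collinear")
        return F


@dataclass(frozen=True)
class SphericalHeadModel:
    """Three concentric conducting shells (brain, skull, scalp).

    Radii are in mm with ``r_brain < r_skull < r_scalp``; conductivities in
    S/m default to 0.33 (brain), 0.01 (skull) and 0.43 (skin).
    """

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radii: tuple[float, float, float] = (82.65, 87.4, 95.0)
    conductivities: tuple[float, float, float] = (0.33, 0.01, 0.43)

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        r = tuple(float(x) for x in self.radii)
        object.__setattr__(self, "radii", r)
        object.__setattr__(
            self, "conductivities", tuple(float(s) for s in self.conductivities)
        )
        if not (0 < r[0] < r[1] < r[2]):
            raise ValueError("radii must satisfy 0 < r_brain < r_skull < r_scalp")
        if any(s <= 0 for s in self.conductivities):
            raise ValueError("conductivities must be positive")

    @property
    def r_brain(self) -> float:
        return self.radii[0]

    @property
    def r_skull(self) -> float:
        return self.radii[1]

    @property
    def r_scalp(self) -> float:
        return self.radii[2]

    def scalp_fiducials(self) -> dict[str, np.ndarray]:
        """Canonical model-space landmarks on the scalp sphere."""
        r = self.r_scalp
        return {
            "nasion": self.center + np.array([0.0, r, 0.0]),
            "lpa": self.center + np.array([-r, 0.0, 0.0]),
            "rpa": self.center + np.array([r, 0.0, 0.0]),
        }


@dataclass(frozen=True)
class SourceGrid:
    """Regular volumetric lattice of candidate dipole locations (mm)."""

    voxel_positions: np.ndarray
    spacing: float
    inside_mask_radius: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.voxel_positions, dtype=float)
        object.__setattr__(self, "voxel_positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("voxel_positions must be (n_V, 3)")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def n_voxels(self) -> int:
        return self.voxel_positions.shape[0]

    def nearest_voxel(self, point) -> int:
        d = np.linalg.norm(self.voxel_positions - np.asarray(point, float), axis=1)
        return int(np.argmin(d))


def read_electrodes(path, fiducial_aliases: dict | None = None) -> ElectrodeSet:
    """Read electrode positions from an SFP/ELC-style plain-text file.

    SFP dialect: one ``label x y z`` row per line. ELC dialect: a
    ``Positions:`` section of ``label : x y z`` rows (a ``Labels:`` section,
    if present, is ignored since labels are inline). Rows whose label matches
    a fiducial alias (default Nz/LPA/RPA families, case-insensitive) become
    fiducials rather than channels.
    """
    aliases = fiducial_aliases or FIDUCIAL_ALIASES
    lookup = {a.lower(): name for name, al in aliases.items() for a in al}
    labels, coords, fids = [], [], {}
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    in_positions = True
    for ln in lines:
        if not ln or ln.startswith("#"):
            continue
        low = ln.lower()
        if low.endswith(":") or low.split()[0] in {"numberpositions=", "units"}:
            in_positions = low.startswith("position")
            continue
        if "=" in ln:
            continue
        if not in_positions:
            continue
        parts = ln.replace(":", " ").split()
        if len(parts) < 4:
            continue
        try:
            xyz = [float(p) for p in parts[-3:]]
        except ValueError:
            continue
        label = " ".join(parts[:-3])
        key = label.lower()
        if key in lookup:
            fids[lookup[key]] = np.array(xyz)
        else:
            labels.append(label)
            coords.append(xyz)
    if not labels:
        raise ValueError(f"no electrode rows found in {path}")
    return ElectrodeSet(tuple(labels), np.array(coords), fids)


def write_electrodes_sfp(electrodes: ElectrodeSet, path) -> None:
    """Write an SFP file (fiducials first, channels after)."""
    names = {"nasion": "Nz", "lpa": "LPA", "rpa": "RPA"}
    with open(path, "w") as fh:
        for key, out in names.items():
            if key in electrodes.fiducials:
                x, y, z = electrodes.fiducials[key]
                fh.write(f"{out}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")
        for lab, p in zip(electrodes.labels, electrodes.positions):
            fh.write(f"{lab}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\n")


def fit_sphere_to_electrodes(
    electrodes: ElectrodeSet,
    skull_ratio: float = 0.92,
    brain_ratio: float = 0.87,
    conductivities: tuple[float, float, float] = (0.33, 0.01, 0.43),
) -> SphericalHeadModel:
    """Least-squares sphere through the electrode positions.

    Solves the linear system for center ``c`` and radius ``r`` from
    ``|p|^2 = 2 p·c + (r^2 - |c|^2)``. Inner shell radii are fixed ratios of
    the fitted scalp radius.
    """
    P = electrodes.positions
    if P.shape[0] < 4:
        raise DegenerateFitError("need at least 4 electrodes to fit a sphere")
    A = np.hstack([2 * P, np.ones((P.shape[0], 1))])
    rhs = np.sum(P**2, axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < 4:
        raise DegenerateFitError("electrode positions are coplanar")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateFitError("sphere fit collapsed to non-positive radius")
    r_scalp = float(np.sqrt(r2))
    return SphericalHeadModel(
        center=center,
        radii=(brain_ratio * r_scalp, skull_ratio * r_scalp, r_scalp),
        conductivities=conductivities,
    )


def _rigid_fit(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (Kabsch): returns (Rot, t) with dst ≈ Rot·src + t."""
    mu_s, mu_d = src.mean(0), dst.mean(0)
    Hm = (src - mu_s).T @ (dst - mu_d)
    U, _, Vt = np.linalg.svd(Hm)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    Rot = Vt.T @ D @ U.T
    t = mu_d - Rot @ mu_s
    return Rot, t


def coregister_electrodes(
    electrodes: ElectrodeSet,
    model: SphericalHeadModel,
    model_fiducials: dict[str, np.ndarray] | None = None,
) -> ElectrodeSet:
    """Rigidly align electrodes to head-model space and project onto the scalp.

    The rotation+translation (no scaling) is the least-squares optimum over
    the three fiducials; each electrode is then projected radially onto the
    scalp sphere (the spherical analogue of orthogonal surface projection).
    """
    fid_src = electrodes.fiducial_matrix()
    fids_dst = model_fiducials or model.scalp_fiducials()
    missing = [k for k in ("nasion", "lpa", "rpa") if k not in fids_dst]
    if missing:
        raise FiducialError(f"model fiducials missing: {missing}")
    fid_dst = np.stack([np.asarray(fids_dst[k], float) for k in ("nasion", "lpa", "rpa")])
    Rot, t = _rigid_fit(fid_src, fid_dst)
    pos = electrodes.positions @ Rot.T + t
    rel = pos - model.center
    norms = np.linalg.norm(rel, axis=1)
    if np.any(norms < 1e-9):
        bad = [electrodes.labels[i] for i in np.where(norms < 1e-9)[0]]
        raise ValueError(f"electrodes at sphere center cannot be projected: {bad}")
    projected = model.center + rel * (model.r_scalp / norms)[:, None]
    new_fids = {k: Rot @ np.asarray(v, float) + t for k, v in electrodes.fiducials.items()}
    return replace(electrodes, positions=projected, fiducials=new_fids)


def build_source_grid(
    model: SphericalHeadModel,
    spacing: float = 6.0,
    mask_ratio: float = 0.95,
) -> SourceGrid:
    """Regular lattice of source voxels strictly inside the brain shell.

    Deterministic ordering: x varies fastest, then y, then z. The lattice is
    centred on the sphere center, so the origin itself is a voxel.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    r_mask = mask_ratio * model.r_brain
    if spacing > 2 * r_mask:
        raise ValueError(
            f"spacing {spacing} mm exceeds the brain diameter ({2 * r_mask:.0f} mm): "
            "empty source grid"
        )
    n_half = int(np.floor(r_mask / spacing))
    if n_half < 0 or r_mask < 0:
        raise ValueError("empty source grid")
    axis = np.arange(-n_half, n_half + 1) * spacing
    Z, Y, X = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()]) + model.center
    inside = np.linalg.norm(pts - model.center, axis=1) <= r_mask + 1e-9
    pts = pts[inside]
    if pts.shape[0] == 0:
        raise ValueError(
            f"spacing {spacing} mm produced an empty grid (mask radius {r_mask:.1f} mm)"
        )
    return SourceGrid(pts, float(spacing), float(r_mask))
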