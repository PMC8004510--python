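import numpy as np
import pytest

import eegstream as es
from eegstream.forward import (
    CompatibilityError,
    _dipole_potentials,
    _shell_transfer,
    compute_leadfield,
)
from eegstream.geometry import ElectrodeSet, SphericalHeadModel, build_source_grid


def closed_form_homogeneous(elec_unit, dip_pos, R, sigma, m):
    """Independent oracle: analytic surface potential of a current dipole in
    a homogeneous conducting sphere (generating-function closed form)."""
    rel = np.asarray(dip_pos, float)
    b = np.linalg.norm(rel)
    t = b / R
    r0 = rel / b
    x = elec_unit @ r0
    d = np.sqrt(1 - 2 * t * x + t * t)
    m_r = m @ r0
    m_t = m - m_r * r0
    w = elec_unit - x[:, None] * r0[None, :]
    s_rad = (2 * t * (x - t) / d**3 + 1 / d - 1) / t
    s_tan = (2 * t / d**3 + (t - x) / ((1 - x**2) * d) + x / (1 - x**2)) / t
    k = 1e-9 / (4 * np.pi * sigma * (R * 1e-3) ** 2) * 1e6
    return k * (s_rad * m_r + s_tan * (w @ m_t))


@pytest.fixture(scope="module")
def montage_unit():
    rng = np.random.default_rng(0)
    v = rng.normal(size=(32, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestShellTransfer:
    def test_equal_conductivities_reduce_to_homogeneous(self):
        model = SphericalHeadModel(conductivities=(0.33, 0.33, 0.33))
        taus = _shell_transfer(model, 200)
        n = np.arange(1, 201)
        np.testing.assert_allclose(taus[1:], (2 * n + 1) / n, atol=1e-12)

    def test_skull_attenuation_reduces_transfer(self):
        taus3 = _shell_transfer(SphericalHeadModel(), 40)
        taus1 = _shell_transfer(SphericalHeadModel(conductivities=(0.33, 0.33, 0.33)), 40)
        assert np.all(taus3[1:] < taus1[1:])


class TestDipolePotentials:
    def test_matches_homogeneous_closed_form(self, montage_unit):
        """Equal-conductivity series vs closed-form oracle, 100 random pairs."""
        model = SphericalHeadModel(conductivities=(0.33, 0.33, 0.33))
        taus = _shell_transfer(model, 200)
        rng = np.random.default_rng(1)
        for _ in range(100):
            b = rng.uniform(5.0, 0.95 * model.r_brain)
            u = rng.normal(size=3)
            pos = b * u / np.linalg.norm(u)
            m = rng.normal(size=3)
            V = _dipole_potentials(montage_unit, pos, model, taus, 1e-10) @ m
            Vc = closed_form_homogeneous(montage_unit, pos, model.r_scalp, 0.33, m)
            assert np.abs(V - Vc).max() < 1e-6 * np.abs(Vc).max()

    def test_zero_moment_gives_zero_potential(self, montage_unit):
        model = SphericalHeadModel()
        taus = _shell_transfer(model, 100)
        V = _dipole_potentials(montage_unit, [0, 0, 40.0], model, taus, 1e-8)
        np.testing.assert_allclose(V @ np.zeros(3), 0.0)

    def test_axial_symmetry(self):
        """Dipole on z along z: potentials invariant under montage rotation about z."""
        model = SphericalHeadModel()
        taus = _shell_transfer(model, 200)
        theta = np.linspace(0.3, 1.2, 8)
        ring = np.column_stack([np.sin(theta), np.zeros(8), np.cos(theta)])
        ring_rot = np.column_stack([np.zeros(8), np.sin(theta), np.cos(theta)])
        V1 = _dipole_potentials(ring, [0, 0, 50.0], model, taus, 1e-10)
        V2 = _dipole_potentials(ring_rot, [0, 0, 50.0], model, taus, 1e-10)
        np.testing.assert_allclose(V1[:, 2], V2[:, 2], atol=1e-8)

    def test_truncation_order_converged(self, montage_unit):
        """Doubling the maximum order changes nothing beyond the tolerance."""
        model = SphericalHeadModel()
        pos = [0.0, 30.0, 60.0]
        m = np.array([1.0, 0.5, -0.3])
        V1 = _dipole_potentials(montage_unit, pos, model, _shell_transfer(model, 150), 1e-8) @ m
        V2 = _dipole_potentials(montage_unit, pos, model, _shell_transfer(model, 300), 1e-8) @ m
        assert np.abs(V1 - V2).max() < 1e-8 * np.abs(V1).max()

    def test_dipole_outside_brain_rejected(self, montage_unit):
        model = SphericalHeadModel()
        taus = _shell_transfer(model, 50)
        with pytest.raises(ValueError):
            _dipole_potentials(montage_unit, [0, 0, 0.99 * model.r_skull], model, taus, 1e-8)


class TestLeadfield:
    def test_average_reference_columns_sum_to_zero(self, leadfield):
        col_sums = leadfield.gain.sum(axis=0)
        assert np.abs(col_sums).max() < 1e-10 * np.abs(leadfield.gain).max()

    def test_linearity(self, leadfield, rng):
        J1 = rng.normal(size=leadfield.gain.shape[1])
        J2 = rng.normal(size=leadfield.gain.shape[1])
        lhs = leadfield.gain @ (2.0 * J1 - 3.0 * J2)
        rhs = 2.0 * leadfield.gain @ J1 - 3.0 * leadfield.gain @ J2
        np.testing.assert_allclose(lhs, rhs, atol=1e-12 * np.abs(lhs).max())

    def test_electrodes_off_sphere_rejected(self, setup32):
        electrodes, model, grid, _ = setup32
        bad = ElectrodeSet(
            electrodes.labels, electrodes.positions * 1.05, electrodes.fiducials
        )
        with pytest.raises(ValueError, match="scalp sphere"):
            compute_leadfield(model, bad, grid)


class TestLeadfieldArchive:
    def test_round_trip_bit_identical(self, leadfield, tmp_path):
        path = tmp_path / "lf.h5"
        es.save_leadfield(leadfield, path)
        back = es.load_leadfield(path)
        assert np.array_equal(back.gain, leadfield.gain)
        assert back.electrode_order == leadfield.electrode_order
        assert back.grid.spacing == leadfield.grid.spacing
        assert back.referenced == leadfield.referenced

    def test_label_mismatch_rejected(self, leadfield, tmp_path, setup32):
        electrodes = setup32[0]
        path = tmp_path / "lf.h5"
        es.save_leadfield(leadfield, path)
        renamed = ElectrodeSet(
            tuple(f"X{i}" for i in range(electrodes.n_channels)),
            electrodes.positions,
            electrodes.fiducials,
        )
        with pytest.raises(CompatibilityError):
            es.load_leadfield(path, renamed)

    def test_externally_written_file_accepted(self, tmp_path):
        """A file assembled by hand (not by save_leadfield) loads fine."""
        import h5py

        model = SphericalHeadModel()
        grid = build_source_grid(model, spacing=40.0)
        gain = np.zeros((4, 3 * grid.n_voxels))
        with h5py.File(tmp_path / "ext.h5", "w") as f:
            f.create_dataset("gain", data=gain)
            f.create_dataset("labels", data=np.array(["A", "B", "C", "D"], dtype="S32"))
            f.create_dataset("voxel_positions", data=grid.voxel_positions)
            f.attrs["spacing"] = grid.spacing
            f.attrs["inside_mask_radius"] = grid.inside_mask_radius
            f.attrs["referenced"] = True
        back = es.load_leadfield(tmp_path / "ext.h5")
        assert back.n_voxels == grid.n_voxels

    def test_wrong_column_count_rejected(self, tmp_path):
        import h5py

        model = SphericalHeadModel()
        grid = build_source_grid(model, spacing=40.0)
        with h5py.File(tmp_path / "bad.h5", "w") as f:
            f.create_dataset("gain", data=np.zeros((4, 3 * grid.n_voxels + 1)))
            f.create_dataset("labels", data=np.array(["A", "B", "C", "D"], dtype="S32"))
            f.create_dataset("voxel_positions", data=grid.voxel_positions)
            f.attrs["spacing"] = grid.spacing
            f.attrs["inside_mask_radius"] = grid.inside_mask_radius
            f.attrs["referenced"] = False
        with pytest.raises(CompatibilityError):
            es.load_leadfield(tmp_path / "bad.h5")
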