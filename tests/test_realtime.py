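import numpy as np
import pytest

import eegstream as es
from eegstream.calibration import SpatialFilterSet
from eegstream.ica import ICADecomposition
from eegstream.realtime import StreamBuffer, process_buffer, extract_latest, localize


def toy_filters(n_e=6, n_a=2, seed=0, n_k_rows=9):
    rng = np.random.default_rng(seed)
    W_A = rng.normal(size=(n_a, n_e))
    R = es.build_reference_matrix(n_e)
    return SpatialFilterSet(
        C=np.eye(n_e),
        R=R,
        W_A=W_A,
        F0=np.eye(n_e),
        H=np.eye(n_e),
        K=rng.normal(size=(n_k_rows, n_e)),
        method="mne",
        alpha=0.05,
        band=(1.0, 40.0),
        labels=tuple(f"E{i}" for i in range(n_e)),
    )


class TestStreamBuffer:
    def test_fifo_order(self):
        buf = StreamBuffer(2, 4)
        for k in range(4):
            buf.push([k, -k])
        assert buf.full
        np.testing.assert_array_equal(buf.window()[0], [0, 1, 2, 3])

    def test_oldest_sample_evicted(self):
        buf = StreamBuffer(1, 4)
        for k in range(5):
            buf.push([k])
        np.testing.assert_array_equal(buf.window()[0], [1, 2, 3, 4])

    def test_wrong_length_rejected(self):
        buf = StreamBuffer(3, 8)
        with pytest.raises(ValueError, match="channels"):
            buf.push([1.0, 2.0])

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            StreamBuffer(2, 3)


class TestProcessBuffer:
    def test_null_space_data_unchanged(self, rng):
        filters = toy_filters()
        cfg = es.RealtimeConfig(sampling_rate=100.0, band=(1.0, 40.0))
        # data orthogonal to the artifact rows (in average reference already)
        X = rng.normal(size=(6, 50))
        X = filters.R @ X
        P = filters.W_A @ filters.R
        X = X - P.T @ np.linalg.solve(P @ P.T, P @ X)
        out = process_buffer(X, filters, cfg, pre_filtered=True)
        xq = filters.C @ filters.R @ X
        assert np.linalg.norm(out - xq) < 1e-6 * np.linalg.norm(xq)

    def test_per_buffer_annihilation(self, rng):
        filters = toy_filters(seed=1)
        cfg = es.RealtimeConfig(sampling_rate=100.0, band=(1.0, 40.0))
        X = rng.normal(size=(6, 50))
        out = process_buffer(X, filters, cfg, pre_filtered=True)
        xq = filters.C @ filters.R @ X
        ratio = np.linalg.norm(filters.W_A @ out) / np.linalg.norm(filters.W_A @ xq)
        assert ratio < 1e-10

    def test_adaptive_filter_matches_calibration_filter_on_same_data(self, rng):
        """Built from identical data, the per-buffer filter and the
        calibration-time filter coincide."""
        n_e = 6
        X = rng.normal(size=(n_e, 200))
        W = rng.normal(size=(4, n_e))
        A = np.linalg.pinv(W)
        ica = ICADecomposition(A, W, W @ X, artifact_indices=(0, 2))
        F0 = es.build_artifact_filter(X, ica)
        filters = toy_filters()
        from dataclasses import replace

        filters = replace(filters, W_A=ica.W_A, F0=F0, C=np.eye(n_e), R=np.eye(n_e))
        cfg = es.RealtimeConfig(sampling_rate=100.0, band=(1.0, 40.0))
        out = process_buffer(X, filters, cfg, pre_filtered=True)
        np.testing.assert_allclose(out, F0 @ X, atol=1e-8 * np.abs(X).max())

    def test_idempotent_on_own_buffer(self, rng):
        filters = toy_filters(seed=2)
        cfg = es.RealtimeConfig(sampling_rate=100.0, band=(1.0, 40.0))
        X = rng.normal(size=(6, 50))
        once = process_buffer(X, filters, cfg, pre_filtered=True)
        # re-apply the filter built on the cleaned buffer
        S_A = filters.W_A @ once
        from eegstream.calibration import regress_out

        F = regress_out(once, S_A, filters.W_A)
        np.testing.assert_allclose(F @ once, once, atol=1e-8 * np.abs(once).max())


class TestLocalize:
    def test_zero_in_zero_out(self):
        assert np.all(localize(np.zeros(6), np.ones((9, 6))) == 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            localize(np.zeros(5), np.ones((9, 6)))

    def test_linearity(self, rng):
        K = rng.normal(size=(12, 6))
        a, b = rng.normal(size=6), rng.normal(size=6)
        np.testing.assert_allclose(
            localize(a + b, K), localize(a, K) + localize(b, K), atol=1e-12
        )

    def test_roi_filter_gives_twelve_outputs(self, study):
        _, _, grid = None, None, None
        res = study
        from eegstream.inverse import downsample_filter_to_rois
        from eegstream.geometry import SourceGrid

        grid = SourceGrid(res.grid_positions, 20.0, 80.0)
        rois = [(res.grid_positions[i], 10.0) for i in (2, 30, 60, 100)]
        K_r, _ = downsample_filter_to_rois(res.filters.K, grid, rois)
        B = localize(res.Y[:, 0], K_r)
        assert B.shape == (12,)


class TestRunStream:
    def make_stream_inputs(self, n=300, n_e=6, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(n_e, n))
        labels = tuple(f"E{i}" for i in range(n_e))
        return es.Recording(data, labels, 100.0)

    def test_output_count_contract(self):
        rec = self.make_stream_inputs()
        filters = toy_filters()
        cfg = es.RealtimeConfig(sampling_rate=100.0, band=(1.0, 40.0), buffer_ms=500.0)
        outs = es.run_stream(es.replay_recording(rec), filters, cfg)
        assert len(outs) == rec.n_samples - cfg.n_buffer + 1
        stamps = [o.timestamp for o in outs]
        assert stamps == list(range(cfg.n_buffer - 1, rec.n_samples))

    def test_replay_determinism(self):
        rec = self.make_stream_inputs(seed=1)
        filters = toy_filters(seed=1)
        cfg = es.RealtimeConfig(sampling_rate=100.0, band=(1.0, 40.0))
        o1 = es.run_stream(es.replay_recording(rec), filters, cfg)
        o2 = es.run_stream(es.replay_recording(rec), filters, cfg)
        np.testing.assert_array_equal(
            np.stack([o.Y for o in o1]), np.stack([o.Y for o in o2])
        )
        np.testing.assert_array_equal(
            np.stack([o.B for o in o1]), np.stack([o.B for o in o2])
        )

    def test_failing_sink_does_not_stop_stream(self):
        rec = self.make_stream_inputs(seed=2)
        filters = toy_filters(seed=2)
        cfg = es.RealtimeConfig(sampling_rate=100.0, band=(1.0, 40.0))

        def bad_sink(out):
            raise RuntimeError("sink exploded")

        outs = es.run_stream(es.replay_recording(rec), filters, cfg, sinks=(bad_sink,))
        assert len(outs) == rec.n_samples - cfg.n_buffer + 1

    def test_stride_mode_emits_every_sample(self):
        rec = self.make_stream_inputs(seed=3)
        filters = toy_filters(seed=3)
        cfg = es.RealtimeConfig(sampling_rate=100.0, band=(1.0, 40.0), refresh_stride=5)
        outs = es.run_stream(es.replay_recording(rec), filters, cfg)
        assert len(outs) == rec.n_samples - cfg.n_buffer + 1


class TestReplay:
    def test_yields_all_samples(self):
        rec = TestRunStream().make_stream_inputs(n=1000)
        samples = list(es.replay_recording(rec))
        assert len(samples) == 1000
        np.testing.assert_array_equal(samples[5], rec.eeg[:, 5])

    def test_truncated_fixture_file_raises(self, tmp_path):
        rec = TestRunStream().make_stream_inputs(n=100)
        es.write_recording_fixture(rec, tmp_path / "r")
        raw = (tmp_path / "r.f32").read_bytes()
        (tmp_path / "r.f32").write_bytes(raw[: len(raw) // 2])
        with pytest.raises(ValueError, match="truncated"):
            list(es.replay_recording(str(tmp_path / "r.json")))


class TestOnlineOfflineAgreement:
    def test_streamed_matches_static_cleaning_on_stationary_data(self, setup32):
        """With stationary artifact-free input the per-buffer adaptive filter
        reproduces the frozen offline cleaning almost exactly."""
        electrodes, _, _, lf = setup32
        cal, _ = es.simulate_recording(es.calibration_spec(lf, 60.0, seed=11), lf)
        filters, _ = es.run_calibration(
            cal, lf, electrodes,
            es.CalibrationConfig(adjacency_mm=60.0, noise_cov="identity", seed=11),
        )
        # same source repertoire as the calibration (seed selects the voxels):
        # the artifact unmixing is only orthogonal to topographies it has seen
        rest, _ = es.simulate_recording(
            es.calibration_spec(lf, 30.0, seed=11, with_artifacts=False), lf
        )
        cfg = es.RealtimeConfig(sampling_rate=100.0, band=filters.band)
        outs = es.run_stream(es.replay_recording(rest), filters, cfg)
        Y = np.stack([o.Y for o in outs], axis=1)
        t0 = outs[0].timestamp
        off = es.offline_clean(rest, filters, phase="forward")[:, t0:]
        warm = 300
        cors = [np.corrcoef(Y[i, warm:], off[i, warm:])[0, 1] for i in range(32)]
        assert min(cors) > 0.95
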