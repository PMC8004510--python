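import numpy as np
import pytest

import eegstream as es
from eegstream.erd import (
    ERDMap,
    band_power,
    compute_erd,
    compute_erd_tf,
    detect_onsets,
    epoch,
    erd_map_to_nifti,
    erd_tf_to_table,
    residual_artifact_correlation,
    spatial_correlation,
)


class TestOnsetDetection:
    def make_emg(self, onset_times, fs=1000.0, dur=80.0, seed=0):
        rng = np.random.default_rng(seed)
        n = int(dur * fs)
        emg = 1.0 * rng.normal(size=n)
        for t in onset_times:
            i = int(t * fs)
            emg[i : i + int(2 * fs)] += 8.0 * rng.normal(size=int(2 * fs))
        return emg

    def test_bursts_detected_within_50ms(self):
        fs = 1000.0
        truth = [6.0, 18.0, 30.0, 42.0, 54.0, 66.0]
        onsets = detect_onsets(self.make_emg(truth), fs)
        assert len(onsets) == len(truth)
        for det, t in zip(onsets, truth):
            assert abs(det / fs - t) <= 0.05

    def test_flat_emg_gives_empty_list(self):
        assert detect_onsets(np.zeros(5000), 1000.0).size == 0

    def test_refractory_merges_close_bursts(self):
        fs = 1000.0
        emg = self.make_emg([10.0, 11.0], dur=20.0)
        onsets = detect_onsets(emg, fs, refractory_s=3.0)
        assert len(onsets) == 1


class TestEpoching:
    def test_twelve_onsets_give_twelve_epochs(self, rng):
        sig = rng.normal(size=(2, 20000))
        onsets = 1000 + 1500 * np.arange(12)
        trials = epoch(sig, onsets, fs=100.0, pre_s=1.0, post_s=2.0)
        assert trials.n_trials == 12
        assert trials.epochs.shape == (12, 2, 300)

    def test_early_onset_dropped(self, rng):
        sig = rng.normal(size=(1, 1000))
        trials = epoch(sig, [50, 500], fs=100.0, pre_s=1.0, post_s=2.0)
        assert trials.n_trials == 1

    def test_empty_onsets_rejected(self, rng):
        with pytest.raises(ValueError):
            epoch(rng.normal(size=(1, 1000)), [], fs=100.0)

    def test_onset_alignment(self):
        sig = np.zeros((1, 2000))
        sig[0, 700] = 1.0
        trials = epoch(sig, [700], fs=100.0, pre_s=1.0, post_s=2.0)
        assert trials.epochs[0, 0, trials.onset_idx] == 1.0


class TestBandPower:
    def test_unit_sinusoid_mean_power_half(self):
        fs = 200.0
        x = np.sin(2 * np.pi * 20 * np.arange(4000) / fs)
        p = band_power(x, (13.0, 30.0), fs)
        assert p[500:3500].mean() == pytest.approx(0.5, rel=0.02)

    def test_quadratic_amplitude_scaling(self):
        fs = 200.0
        x = np.sin(2 * np.pi * 20 * np.arange(4000) / fs)
        p1 = band_power(x, (13.0, 30.0), fs)[500:3500].mean()
        p2 = band_power(0.5 * x, (13.0, 30.0), fs)[500:3500].mean()
        assert p2 / p1 == pytest.approx(0.25, rel=0.02)

    def test_out_of_band_rejected(self):
        fs = 200.0
        inband = np.sin(2 * np.pi * 20 * np.arange(4000) / fs)
        outband = np.sin(2 * np.pi * 50 * np.arange(4000) / fs)
        p_in = band_power(inband, (13.0, 30.0), fs)[500:3500].mean()
        p_out = band_power(outband, (13.0, 30.0), fs)[500:3500].mean()
        assert p_out < 0.01 * p_in


class TestComputeERD:
    def modulated_trials(self, a, n_trials=20, seed=0):
        fs = 100.0
        rng = np.random.default_rng(seed)
        n = int(n_trials * 12 * fs) + 1000
        onsets = (600 + 1200 * np.arange(n_trials)).astype(int)
        from eegstream.synth import _harmonic_comb, make_task_modulation

        carrier = _harmonic_comb(rng, n, fs, (13.0, 30.0))
        env = make_task_modulation(n, fs, onsets, a, 6.0) if a < 1 else np.ones(n)
        sig = (env * carrier)[None, :]
        return epoch(sig, onsets, fs, pre_s=1.5, post_s=2.5)

    def test_no_modulation_gives_zero_erd(self):
        m = compute_erd(self.modulated_trials(1.0), (13.0, 30.0))
        assert abs(m.values[0]) < 2.0

    def test_total_suppression_approaches_minus_100(self):
        m = compute_erd(self.modulated_trials(1e-6), (13.0, 30.0))
        assert m.values[0] == pytest.approx(-100.0, abs=3.0)

    def test_half_amplitude_gives_minus_75(self):
        """Amplitude depth a scales power by a^2: ERD = (a^2-1)*100 = -75 %."""
        m = compute_erd(self.modulated_trials(0.5), (13.0, 30.0))
        assert m.values[0] == pytest.approx(-75.0, abs=5.0)

    def test_amplitude_rescaling_invariance(self):
        trials = self.modulated_trials(0.5, n_trials=4)
        m1 = compute_erd(trials, (13.0, 30.0))
        from dataclasses import replace

        scaled = replace(trials, epochs=trials.epochs * 37.5)
        m2 = compute_erd(scaled, (13.0, 30.0))
        np.testing.assert_allclose(m1.values, m2.values, rtol=1e-12)

    def test_zero_baseline_flagged_nan(self):
        trials = epoch(np.zeros((1, 5000)), [1000, 2500], fs=100.0, pre_s=1.0, post_s=2.0)
        m = compute_erd(trials, (13.0, 30.0))
        assert np.isnan(m.values[0])

    def test_erd_bounded_below(self):
        trials = self.modulated_trials(0.3, n_trials=4)
        m = compute_erd(trials, (13.0, 30.0))
        assert np.all(m.values[np.isfinite(m.values)] >= -100.0)


class TestTimeFrequency:
    def test_baseline_bins_average_to_zero(self):
        trials = TestComputeERD().modulated_trials(0.5, n_trials=8)
        tf = compute_erd_tf(trials, signal_index=0, fmax=40.0)
        base = (tf.times >= -1.0) & (tf.times < 0.0)
        beta = (tf.freqs >= 13) & (tf.freqs <= 30)
        assert abs(tf.values[np.ix_(beta, base)].mean()) < 5.0

    def test_beta_bins_desynchronize_in_task_window(self):
        trials = TestComputeERD().modulated_trials(0.5, n_trials=8)
        tf = compute_erd_tf(trials, signal_index=0, fmax=40.0)
        task = (tf.times >= 0.5) & (tf.times <= 2.0)
        beta = (tf.freqs >= 15) & (tf.freqs <= 28)
        assert tf.values[np.ix_(beta, task)].mean() < -50.0


class TestSpatialCorrelation:
    def test_identical_maps(self):
        m = ERDMap(np.arange(10.0), (13.0, 30.0))
        assert spatial_correlation([m, m]) == pytest.approx(1.0)

    def test_negated_map(self):
        v = np.arange(10.0)
        assert spatial_correlation(
            [ERDMap(v, (13.0, 30.0)), ERDMap(-v, (13.0, 30.0))]
        ) == pytest.approx(-1.0)

    def test_noisy_replicates_match_analytic_attenuation(self):
        """12 maps = pattern + iid noise at known SNR; the mean pairwise
        correlation approaches SNR^2/(SNR^2+1), cross-checked by Monte Carlo."""
        rng = np.random.default_rng(0)
        n_vox, snr = 500, 1.5
        pattern = rng.normal(size=n_vox)

        def mean_pairwise(maps):
            return spatial_correlation([ERDMap(m, (13.0, 30.0)) for m in maps])

        maps = [pattern + rng.normal(size=n_vox) / snr for _ in range(12)]
        observed = mean_pairwise(maps)
        # brute-force Monte-Carlo oracle over independent replications
        mc = np.mean(
            [
                mean_pairwise([pattern + rng.normal(size=n_vox) / snr for _ in range(12)])
                for _ in range(20)
            ]
        )
        expected = snr**2 / (snr**2 + 1)
        assert observed == pytest.approx(expected, abs=0.05)
        assert observed == pytest.approx(mc, abs=0.05)

    def test_undefined_voxels_excluded_pairwise(self):
        a = np.array([1.0, 2.0, 3.0, np.nan])
        b = np.array([1.0, 2.0, 3.0, 100.0])
        c = spatial_correlation([ERDMap(a, (13.0, 30.0)), ERDMap(b, (13.0, 30.0))])
        assert c == pytest.approx(1.0)


class TestResidualArtifactCorrelation:
    def test_identical_signal_gives_one(self, rng):
        x = rng.normal(size=5000)
        out = residual_artifact_correlation(x[None, :], {"vEOG": x})
        assert out["vEOG"][0] == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        out = residual_artifact_correlation(
            rng.normal(size=(3, 10_000)), {"vEOG": rng.normal(size=10_000)}
        )
        assert np.all(out["max"] < 0.05)

    def test_constant_input_flagged_nan(self, rng):
        out = residual_artifact_correlation(
            np.zeros((1, 100)), {"vEOG": rng.normal(size=100)}
        )
        assert np.isnan(out["vEOG"][0])

    def test_band_matched_comparison_recovers_filtered_artifact(self, rng):
        """A causally filtered copy of the aux signal correlates ~1 when the
        aux is passed through the same filter, but poorly against the raw."""
        from scipy import signal as sps

        from eegstream.preprocess import _filter_sos

        pulse = np.zeros(20000)
        for i in range(500, 19000, 1100):
            pulse[i : i + 30] += np.hanning(30)
        filt = sps.sosfilt(_filter_sos((1.0, 50.0), 100.0), pulse)
        raw = residual_artifact_correlation(filt[None], {"vEOG": pulse})["max"][0]
        matched = residual_artifact_correlation(
            filt[None], {"vEOG": pulse}, band=(1.0, 50.0), fs=100.0
        )["max"][0]
        assert matched > 0.99 and matched > raw


class TestExports:
    def test_nifti_round_trip_preserves_voxel_values(self, setup32, tmp_path):
        import nibabel as nib

        _, _, grid, _ = setup32
        vals = np.arange(grid.n_voxels, dtype=float)
        erd_map_to_nifti(ERDMap(vals, (13.0, 30.0)), grid, tmp_path / "erd.nii.gz")
        img = nib.load(tmp_path / "erd.nii.gz")
        vol = np.asarray(img.dataobj)
        pos = grid.voxel_positions
        idx = np.round((pos - pos.min(0)) / grid.spacing).astype(int)
        np.testing.assert_allclose(vol[idx[:, 0], idx[:, 1], idx[:, 2]], vals)
        # off-lattice corners are undefined
        assert np.isnan(vol).any()

    def test_tf_table_shape_and_labels(self):
        trials = TestComputeERD().modulated_trials(0.5, n_trials=3)
        tf = compute_erd_tf(trials, signal_index=0, fmax=40.0)
        table = erd_tf_to_table(tf)
        assert table.shape == tf.values.shape
        assert table.index.name == "frequency_hz"
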