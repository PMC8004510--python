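# eegstream

Real-time source reconstruction for high-density EEG: calibration-derived
spatial filters for artifact attenuation and source localization, applied
per sample to a live (or replayed) sensor stream, with event-related
desynchronization (ERD) analytics and a ground-truth simulator for
validation.

The intended users are EEG methods researchers and BCI/neurofeedback
developers who need source-space signals *during* an experiment rather
than offline.

## The method

All processing is linear algebra prepared once from a resting
**calibration recording** and applied per sample afterwards:

- **Forward model.** Scalp potentials are linear in the source currents,
  `θ(t) = L J(t)`, with `L` the `(n_E × 3n_V)` leadfield of a three-shell
  spherical head model (brain/skull/scalp conductivities 0.33/0.01/0.43
  S/m), computed analytically on a regular volumetric grid.
- **Sensor repair and reference.** Bad channels (4-SD outliers in in-band
  minimum correlation or 200–250 Hz noise variance) are replaced by
  neighbour averages (`C`); `R = I − (1/n_E)𝟙𝟙ᵀ` applies the average
  reference: `X_q = C R X`.
- **Artifact subspace.** FastICA (deflation, tanh contrast) decomposes the
  band-passed calibration data; components whose power envelope tracks the
  vEOG/hEOG/EMG channels, whose spectrum fits 1/f, or whose kurtosis is
  extreme form the artifact unmixing `W_A`. The attenuation filter
  `F₀ = I − X S_Aᵀ (S_A S_Aᵀ)⁻¹ W_A` (with `S_A = W_A X`) annihilates that
  subspace exactly; online, the regression is re-fit on every 500 ms
  buffer, `F(τ)`, to track non-stationary artifacts.
- **Inverse operator.** `K = G⁻¹ Lᵀ (L G⁻¹ Lᵀ + αH)⁺` with eLORETA
  weights `G` by default (zero localization error for noiseless point
  sources), or MNE / sLORETA; `α = 0.05`.
- **Streaming.** Per incoming sample: band-pass (causal, persistent
  state) → push to buffer → `C R` → `F(τ)` → newest cleaned sample
  `Y(t)` → `B(t) = K Y(t)`.
- **Validation.** ERD maps `100·(P − P_b)/P_b` in the beta band (13–30 Hz,
  task window [0, 2] s vs baseline [−1, 0] s around EMG-detected movement
  onsets), across-trial map reliability, and residual EOG/EMG correlation.

## Worked example

```python
import eegstream as es

study = es.run_validation_study(seed=2, n_trials=20)
print(f"ERD at source voxel: {study.erd_at_true_voxel:.1f} %")
print(f"peak voxel {study.peak_voxel} vs planted {study.true_voxel}")
print(f"uncleaned/cleaned vEOG correlation: "
      f"{study.uncleaned_veog_corr:.2f} / {study.cleaned_veog_corr:.3f}")
print(f"online/offline min channel correlation: "
      f"{study.online_offline_corr.min():.3f}")
```

prints (seed 2):

```
ERD at source voxel: -73.4 %
peak voxel 198 vs planted 198
uncleaned/cleaned vEOG correlation: 0.96 / 0.006
online/offline min channel correlation: 0.966
```

The simulated beta source drops to half amplitude during each 6 s movement
window, so the expected ERD is (0.5² − 1)·100 = −75 %; the measured
−73.4 % at the exactly-recovered source voxel reflects the onset ramps and
the small residual background/noise power. Ocular contamination of the
reconstructed signals falls from 0.96 to 0.006 with the adaptive artifact
filter, and the streamed output agrees with offline cleaning channel by
channel.

The `examples/` directory walks through each capability (forward model,
calibration, streaming, ERD mapping, and the CLI pipeline
`eegstream leadfield / simulate / calibrate / stream / erd`). The model,
estimators and simulator are documented in `docs/methods.md`.

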