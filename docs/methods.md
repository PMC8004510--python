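# Methods

`eegstream` reconstructs neural source activity from high-density EEG in
real time, using spatial filters estimated once from a calibration
recording and then applied per sample to a rolling buffer. This note
documents the model, the estimators, the numerical choices, and what the
synthetic validation does and does not demonstrate.

## Forward model

Scalp potentials are linear in the source currents, `theta(t) = L J(t)`,
with `L` the `(n_E, 3 n_V)` leadfield over a regular volumetric grid and
`J` the stacked x/y/z dipole moments per voxel. The head is modelled as
three concentric conducting spheres (brain, skull, scalp) with default
radii 82.65 / 87.4 / 95 mm and conductivities 0.33 / 0.01 / 0.43 S/m.
The leadfield is evaluated analytically: per Legendre degree `n` the
boundary-value problem reduces to a 5x5 linear system whose solution is a
transfer coefficient `tau_n` (equal-conductivity limit `(2n+1)/n`, the
homogeneous sphere); the electrode potential is the dipole multipole
expansion weighted by these coefficients. The series is truncated
adaptively when the tail bound falls below 1e-8 of the running sum, up to
degree 200. Order 200 is needed because the shallowest grid sources sit at
~0.83 of the scalp radius, where the terms decay as `0.83^n`; order 60
would leave ~1e-3 relative error, incompatible with the 1e-6 agreement the
test suite demands against the closed-form homogeneous-sphere oracle.
Units are mm, nA*m and uV; all tests are scale-free.

Electrode co-registration is the closed-form least-squares rigid fit
(rotation + translation, no scaling) over the three fiducials, followed by
radial projection onto the scalp sphere — for a sphere, surface ICP adds
nothing to the landmark fit. A source grid voxel ordering is fixed
(x fastest, then y, then z) so that column `3 v + d` is unambiguous.
When no head model is supplied, a sphere is fitted to the electrode
positions, with inner radii at fixed ratios 0.92 and 0.87 of the scalp
radius.

## Calibration filters

From a resting recording the calibration stage estimates, in order:

1. **Bad channels.** Two per-channel quality parameters: the minimum
   in-band Pearson correlation against all other channels (constant
   channels receive a −1 sentinel), and the 200–250 Hz noise variance
   (skipped with a warning below 500 Hz sampling). A channel is bad when
   its correlation falls below `mean − 4 sd` or its noise variance rises
   above `mean + 4 sd` of the across-channel distribution. The two-sided
   placement preserves the 4-SD robustness while matching the physical
   direction of each parameter.
2. **Repair and reference.** The correction matrix `C` replaces each bad
   channel by the uniform average of its good neighbours (Euclidean
   distance rule, 40 mm default; 60 mm with the sparse 32-channel synthetic
   montage), and `R = I − (1/n_E) 1 1^T` applies the average reference:
   `X_q = C R X`.
3. **ICA.** After zero-phase band-pass (4th-order Butterworth, forward-
   backward; an upper edge at/above Nyquist degrades to high-pass only,
   which is exactly the stated 1–50 Hz band at 100 Hz), FastICA
   (deflation, tanh contrast, max 500 iterations, tol 1e-6, seeded) is run
   at the data's effective rank — average reference and each repaired
   channel remove one rank each. Deflation routinely stalls on the last,
   near-Gaussian components; by default the partial estimate is kept and a
   warning logged, since the artifact-carrying components converge first
   (a strict mode raises instead).
4. **Artifact components.** A component is artifactual when any of three
   features crosses its threshold: maximum absolute correlation of its
   1 s-smoothed power envelope with the vEOG/hEOG/EMG envelopes (> 0.3),
   R² of a log-log linear fit to its Welch spectrum (> 0.8), or excess
   kurtosis (> 10). The thresholds are package defaults, configurable; no
   claim is made that they reproduce any particular prior setting.
5. **Artifact filter.** `F0 = I − X S_A^T (S_A S_A^T)^{-1} W_A` with
   `S_A = W_A X` computed on the filtered calibration data `X_q~`. By
   substitution, `W_A F0 X_q~ = 0` exactly — the annihilation identity the
   tests check to 1e-10. Ill-conditioned regressions (condition > 1e12)
   receive a logged ridge of `1e-8 trace/n_A`.
6. **Noise covariance.** Default: sample covariance of the cleaned
   calibration data, symmetrized, projected `R H R` and trace-normalized
   to `n_E`. Because this estimate contains the neural rhythms themselves,
   the Tikhonov term then selectively penalizes exactly the source
   topographies of interest and biases source-power analyses; the
   `noise_cov="identity"` option (`H = R`, the average-reference
   projector) avoids this and is used for the validation study.
7. **Inverse operator.** `K = G^{-1} L^T (L G^{-1} L^T + alpha H)^+`.
   eLORETA (default) finds block-diagonal 3x3 weights by the fixed-point
   iteration `W_v = (L_v^T M L_v)^{1/2}`, `M` the regularized
   pseudoinverse of the weighted Gram matrix, to relative change 1e-6
   (max 100 iterations); MNE uses `G = I`; sLORETA standardizes the MNE
   filter by the inverse square root of the per-voxel 3x3 resolution
   blocks. The regularizer enters as `alpha * trace(L G^{-1} L^T)/n_E`
   times the trace-normalized `H`, making `alpha` a dimensionless fraction
   of mean signal power (default 0.05). Pseudoinverses zero singular
   values below 1e-10 of the maximum (average reference forces rank
   `n_E − 1`).

## Real-time engine

Samples are filtered causally on arrival (the band-pass run as a streaming
filter with persistent state) and pushed into a rolling buffer of
`round(buffer_ms fs / 1000)` samples (500 ms default). Per buffer the
engine applies `C R`, re-fits the artifact regression
`F(tau) = I − X_q~ S_A^T (S_A S_A^T)^{-1} W_A` (every sample by default; a
stride reuses the last regression), extracts the newest cleaned sample
`Y(t)` and localizes it, `B(t) = K Y(t)`. No output is produced until the
buffer first fills; thereafter exactly one `(Y, B)` pair per input sample.
For region-of-interest streaming, `K` is restricted to three rows per ROI
(the in-radius grid voxel nearest the ROI center; a `mean` mode averages
rows over all in-ROI voxels instead).

A design note on the in-buffer filter: applying a *zero-phase* filter to
each 500 ms window and keeping the last sample does not work — the
backward pass has no future data, so the window's final sample is pure
edge transient (empirically ~40x attenuated and uncorrelated with the
signal). The streaming engine therefore filters causally with persistent
state, which is both real-time-correct and cheaper; a `per-buffer`
zero-phase mode remains available for offline-style experimentation.
Online/offline agreement is consequently assessed against the offline
pipeline run with the same causal filter (`offline_clean(...,
phase="forward")`): that comparison isolates the difference between the
per-buffer adaptive regression and the frozen `F0`, instead of being
bounded at ~0.90 by causal-versus-zero-phase distortion of the
low-frequency noise.

An important property of the adaptive regression, reproduced by the
simulator: `W_A` annihilates only topographies present in the calibration
mixture. A strong source that appears *only* during the streaming session
leaks into `S_A(tau)` and is partially regressed out. Physiologically the
task-modulated rhythms idle at rest and are seen by the calibration ICA,
so the paired simulation places the same source repertoire in both
recordings; a calibration that misses a later-active source degrades it —
a real limitation of calibration-based artifact removal, not an
implementation artifact.

## ERD analysis

Movement onsets come from the EMG channel (rectified, 200 ms moving
average, threshold at the envelope's median + 8 scaled MADs, 3 s
refractory) or from a file. The median/MAD baseline is immune to the
bursts themselves; a mean/SD baseline estimated from the quietest samples
is biased low by the truncation and floods the detector with false
crossings, while movement EMG sits an order of magnitude above the
resting envelope, so the 8-MAD threshold separates with a wide margin. Epochs span the baseline window [−1, 0] s and task window
[0, +2] s around each onset, cut with 0.5 s margins so filter edges stay
clear of the windows. Band power is the squared output of the zero-phase
Butterworth band-pass; for map-mode ERD the window mean itself is the
power estimator (an additional 250 ms moving average is available for
envelope displays and the time-frequency mode, which uses an STFT with
500 ms windows and 80 % overlap). ERD is
`100 (P_task − P_base) / P_base`, per trial and trial-averaged; zero
baseline power yields NaN, never silent zeros. Per-voxel ERD combines the
three Cartesian source components by summing their power. Across-trial
reliability is the mean pairwise Pearson correlation over voxels with
pairwise exclusion of undefined entries. Residual artifact contamination
is the absolute correlation between reconstructed ROI signals and the
EOG/EMG channels, with the auxiliary channel passed through the *same*
causal band-pass as the source stream — correlating a band-passed
reconstruction against a raw auxiliary trace understates the shared
artifact by a large factor (measured 0.39 versus 0.97 for a pure blink
train) purely through waveform mismatch.

## Synthetic data

The simulator emulates the validation study's structure: a resting
calibration session and a task session of alternating 6 s self-paced
movement and 6 s rest. Defaults, chosen once for physiological
plausibility at desk scale:

- **Montage/grid.** 32 electrodes on a Fibonacci lattice over the upper
  scalp; 20 mm source grid (251 voxels). Full test runs stay under a few
  minutes.
- **Neural sources.** A beta (13–30 Hz), an alpha (8–11 Hz) and a theta
  (4–7 Hz) rhythm at well-separated mid-depth voxels, each a random-phase
  harmonic comb at 1 Hz line spacing with a 10 uV RMS sensor footprint.
  The comb makes windowed power nearly deterministic (filtered noise
  fluctuates by ~`1/sqrt(2BT)` per window, which at 20 trials leaves
  several ERD points of seed-to-seed wobble); integer line spacing makes
  every whole-second analysis window integrate whole beat cycles. The
  alpha band stops at 11 Hz because the 4th-order 13–30 Hz filter edge
  still passes appreciable 12 Hz power into beta-band maps.
- **Background activity.** Spatially incoherent beta generators at every
  grid voxel, 2 uV total sensor RMS. Without it every voxel's beta content
  is a scaled copy of the one focal source and the ERD map is flat; the
  ubiquitous unmodulated background is what makes real ERD maps focal.
- **Task modulation.** The beta source's amplitude scales by depth
  `a = 0.5` during move windows (expected ERD `(a² − 1) 100 = −75 %`),
  with 250 ms raised-cosine ramps centred on the onset marker — cortical
  beta suppression is already underway at the EMG-defined movement onset.
- **Artifacts.** Blinks: Poisson train, 18/min, 300 ms biphasic pulses,
  150 uV sensor RMS topography built from leadfield columns of the most
  frontal-superior and most anterior voxels (a declared, stylized stand-in
  for real ocular fields). Muscle: 1 s bursts of 20–50 Hz noise at 8/min
  on an edge-channel topography — inside the analysis band, so band-pass
  alone cannot remove it. Auxiliary vEOG/hEOG/EMG channels carry the
  artifact reference signals plus independent noise; in task mode the EMG
  channel carries movement bursts aligned to the true onsets (the sensor
  muscle-artifact generator is off during the task, where the EMG channel
  is dominated by movement itself).
- **Sensor noise.** 1 uV white noise per channel.
- **Acquisition reference.** Recorded channels are the scalp potentials
  minus a reference-site common mode (the mean of the three most superior
  channels), emulating common-reference acquisition: raw channels then
  show the positive inter-correlations the bad-channel detector expects,
  and the average-reference projector removes the common mode exactly, so
  all products downstream of `C R` are unaffected.
- **Study sizes.** Calibration 180 s (the original design uses 4 min;
  3 min keeps the ICA unmixing accurate — shorter calibrations leave
  enough unmixing error that the adaptive regression visibly nibbles at
  the neural sources), task 20 trials (4 min).

What the simulation does *not* contain: realistic cortical geometry and
orientation fields, non-stationary rhythm dynamics, 1/f broadband
background, electrode drift, line noise, or real ocular/muscle field
patterns. Passing tests therefore demonstrate the correctness of the
algebra, the estimators and the engine under the model's own assumptions,
not clinical-grade performance on human data.

## Known limitations

- The ERD map at 32 channels / 20 mm localizes the modulated source to
  within one grid step; for some seeds the peak lands on an immediate
  neighbour (the ERD ratio normalizes away the eLORETA power peak, whose
  argmax is exact, and instead follows the noise-normalized pattern, which
  carries no exactness guarantee).
- The spherical model ignores skull inhomogeneity and CSF; a four-layer
  model is out of scope.
- Latency is accounted in samples, not wall-clock time; hardware-bound
  timing figures are not reproduced.
- EDF/BrainVision files are read (via MNE-Python) but not written; the
  simulator emits the documented JSON + float32 fixture format.
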