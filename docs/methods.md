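# Methods

## Model

`boldsim` simulates a 4-D functional scan as a baseline template plus a
linear combination of noise sources. It is a descriptive, data-driven model
— each component reproduces a statistical signature of real BOLD data
(temporal autocorrelation, spatial smoothness, slow drift, periodic
physiology, scanner noise floor) rather than the physics that produces it.

Brain-specific temporal noise is a weighted mix of standardized components,

    W · ( w_ARMA · v_ARMA + w_physio · v_physio + w_task · v_task ),

applied to brain voxels only, with drift (weighted separately) and system
noise added to all voxels. Every `v` is standardized — 4-D fields to unit
per-voxel temporal variance, timecourses to unit variance — so the weights
are interpretable as relative contributions, and the weighted mix is
re-standardized before scaling so the brain temporal noise standard
deviation equals `W` exactly regardless of correlations between components.

### Parameters

| parameter | meaning | units | default |
|---|---|---|---|
| `snr` | mean brain intensity / non-brain spatial std at one volume | — | 30 |
| `sfnr` | per-voxel mean / detrended temporal std, brain average | — | 70 |
| `fwhm` | spatial smoothness of the temporal noise fields | mm | 4 |
| `ar_phi`, `ma_omega` | ARMA(1,1) coefficients of brain noise | — | 0.5, 0.2 |
| `drift_period` P | period below which 99% of drift power lies | s | 150 |
| `w_arma`, `w_physio`, `w_task` | temporal mix weights (sum to 1) | — | 0.9, 0.1, 0 |
| `w_drift` | drift std in units of W | — | 0.5 |
| `physio_heart_hz`, `physio_resp_hz` | cardiac / respiratory rates | Hz | 1.17, 0.2 |

SNR, SFNR, FWHM and the ARMA coefficients are estimable from data
(`calc_noise`); the remaining parameters cannot be recovered from a raw
scan — drift is degenerate with slow neural signal, task noise requires
knowing the latent events, and physiological rates alias at typical TRs —
and must be specified. `w_task` defaults to 0 because task-locked noise
requires an event timecourse; when a stimulus is supplied a typical split
is 0.8/0.1/0.1.

### Drift

Drift is a sum of `floor(L/A)` cosine harmonics of the run length with
random phases and geometrically decaying amplitudes `r^(i-1)`, where `r`
solves `0.99 = (1 - r^(2L/P)) / (1 - r^(2L/A))` by bracketed root finding
(Brent, |residual| < 1e-10). The ratio decreases monotonically from 1 to
A/P on (0, 1), so the root exists iff A/P < 0.99 (longer TRs relative to P
leave no valid drop-off and raise an error). The summation limit (L/A) and
the drop-off exponents (2L/P, 2L/A) are used exactly as given even though
they are mutually inconsistent by a factor of two; the amplitude envelope
is therefore slightly conservative, and the spectral guarantee — at least
99% of summed squared amplitudes at periods ≥ P — holds a fortiori
(99.99% at L=300 s, A=1.5 s, P=150 s).

### Spatial fields

The innovation fields of the ARMA process are Gaussian random fields whose
smoothness is parameterized by FWHM. They are synthesized by **circulant
embedding**: white noise is coloured in the Fourier domain by the square
root of the power spectrum of the (periodized, separable) Gaussian
autocorrelation `c(d) = exp(-d² / (4σ²))`, σ = FWHM/√(8 ln 2) in voxels per
axis. Unlike convolution with a sampled Gaussian kernel — which truncates
the kernel's spectrum at the grid Nyquist frequency and inflates the
apparent smoothness by ~10% once σ approaches half a voxel — this
construction gives lag-d autocorrelation exactly `c(d)` at every kernel
width, including sub-voxel widths, and degrades continuously to a white
field as FWHM → 0. This exactness matters because the package's own FWHM
estimator inverts the same relation: generation and estimation agree in
expectation at all widths, so chains of estimate → regenerate do not
accumulate smoothness bias.

### ARMA(1,1) temporal structure

`Y_t = X_t + φ Y_{t-1} + ω X_{t-1}` is run volume-wise with fresh spatial
innovations, a burn-in of 100 discarded volumes to remove the
initial-condition transient, and per-voxel standardization. Stationarity
requires |φ| < 1 (enforced). Each voxel timecourse is an exact ARMA(1,1)
process; the lag-1 autocorrelation satisfies the closed form
`(1 + φω)(φ + ω) / (1 + 2φω + ω²)`.

### System noise and the SNR/SFNR partition

System (thermal) noise is Gaussian added to the template across the whole
field of view. Its spatial component is a **static** pattern whose std is
chosen so the non-brain spatial std of template + noise equals
`mean brain intensity / snr` — the template's own non-brain spatial
variance is subtracted first, so the SNR estimator recovers the target
without fitting. The temporal variance budget `W = mean brain
intensity / sfnr` is carried entirely by the structured brain noise: this
is the simplest partition under which both the SNR and the SFNR round-trip
identities hold simultaneously (any white temporal system component would
have to be taken out of W, and would additionally attenuate the apparent
AR coefficient and FWHM of the brain noise). An optional
`temporal_fraction` adds white temporal system noise for users who want a
non-zero scanner noise floor in non-brain voxels; it defaults to 0, with
the consequence that simulated non-brain voxels are constant over time —
a deliberate idealization.

### Fitting loop

Requesting SNR/SFNR does not guarantee recovering them from a stochastic
realization, so `generate_noise(fit=True)` re-estimates both from the
assembled scan and rescales the two internal magnitudes (spatial system
noise, W) by the damped multiplicative ratio `(estimate/target)^0.8`, up to
20 iterations or until both are within the tolerance (5% default). The
loop rescales a fixed noise realization rather than redrawing it, so it
converges deterministically and the output is bit-reproducible from the
seed whether or not fitting is enabled. Non-convergence is a warning, not
an error, and returns the best iterate.

## Estimators

* **SNR** — brain mean over non-brain std at the middle volume,
  index `floor(T/2)`. Zeroed-out backgrounds (masked, preprocessed data)
  are detected and rejected with guidance, since they are an inappropriate
  baseline for non-brain variability.
* **SFNR** — per brain voxel, temporal mean over the std of the residual
  after removing a second-order polynomial in time; brain average. Voxels
  with zero residual variance (to round-off) are excluded with a warning.
* **FWHM** — per axis, `FWHM = voxel · √(8 ln 2) · σ` with
  `σ² = -1 / (4 ln ρ̂)`, where `ρ̂ = 1 - var(Δ)/(2 var)` is the
  lag-1 spatial correlation from first differences of masked voxels
  (difference-variance estimator). Each voxel's temporal mean is removed
  first so the estimate reflects the smoothness of the temporal
  fluctuations rather than anatomy; volumes are sampled every
  `ceil(T/10)`-th timepoint and axes/volumes averaged. Axes rougher than
  white noise (ρ̂ ≤ 0) are uninformative and skipped.
* **ARMA(1,1)** — exact maximum likelihood (statsmodels ARIMA, order
  (1,0,1), no trend) on 100 randomly sampled (seeded) brain voxels,
  coefficients averaged; failed fits are dropped, not imputed. Nuisance
  removal is demeaning plus regression on the brain global-mean timecourse,
  which removes drift and physiological fluctuations exactly in this model
  (both are spatially uniform) — polynomial detrending was rejected because
  removing a low-order trend from short runs absorbs genuine low-frequency
  autoregressive power and biases φ̂ downward by ~0.06 at T=120.

## Signal path

Event designs are boxcars on a fine grid (`dt`, half-open intervals
[onset, onset + duration)), convolved with the canonical double-gamma HRF
(peak gamma shape 6, undershoot shape 16, undershoot ratio 1/6, peak at
5.0 s; parameters exposed) and downsampled to the volume grid. With
`scale_function` the response is normalized to peak 1, so a
percent-signal-change amplitude — `mean(voxel)/100 × magnitude` — applies
to the peak evoked response; contrast-to-noise scaling
(`magnitude × noise_std`) is also available. Signal addition is strictly
linear and independent of the noise content.

Multivariate community-structure patterns place `n` nodes at uniform
angles on a unit circle (communities contiguous), pull each node toward
its community centroid by the `density` factor (0 = equal adjacent edges,
1 = communities collapsed to points), and map the 2-D coordinates into
voxel space with a seeded random orthonormal transform (QR of a Gaussian
matrix), preserving all pairwise Euclidean distances to machine precision.
Per-voxel calibration scales each voxel's largest-magnitude event response
to the voxel's PSC amplitude, other events in proportion.

## Validation protocol and the synthetic reference scans

The recovery experiment (`run_recovery_experiment`, CLI `validate`)
measures how faithfully the simulate → estimate loop closes: for each of
`n_scans` *synthetic reference scans* (fitted simulations with known
targets, standing in for real acquisitions), it estimates the descriptors,
generates `n_sims` fitted simulations from those estimates — exactly what
a user matching a real scan would do — re-estimates each, and reports the
percentage of simulations within tolerance (5% relative, by default) of
their targets, plus the across-simulation variance per scan.

Defaults are desk scale: 24 x 24 x 16 voxels (3 x 3 x 3.5 mm, TR 1.5 s —
a typical EPI geometry), T = 120 volumes, 5 scans x 4 simulations, with
targets spread over SNR 20–50, SFNR 50–90, φ 0.3–0.6 and FWHM 3–6 mm. The
full experiment runs in about half a minute on one CPU; acquisition-scale
grids are a configuration choice. The bundled template is a uniform
ellipsoid over a Rayleigh background — deliberately non-anatomical. What
passing recovery shows is therefore *self-consistency of the model and its
estimators*, not realism of any particular anatomy: real scans add
motion, non-uniform noise distributions, multiband slice effects and
baseline structure that this generator does not emulate.

With the default protocol and seed 1, the proportions of the 20 fitted
simulations within 5% are: SNR 100%, SFNR 100%, FWHM 100%, AR(1) 0%.

## Known limitations

* **AR(1) recovery at short run lengths.** Exact-ML ARMA(1,1) estimation
  carries a finite-sample bias of roughly −0.03 to −0.05 in φ̂ at T = 120
  (measured on simulated series; the bias shrinks roughly as 1/T). The
  recovery protocol generates simulations from the reference's *estimated*
  coefficients and re-estimates them, so the bias is applied afresh at
  each cycle rather than cancelling: the expected chain error is 6–20% of
  φ for φ in 0.3–0.6, against a 5% band. Recovering AR coefficients within
  a tight relative tolerance therefore requires run lengths of several
  hundred volumes (where the bias is proportionally negligible, as in
  typical resting acquisitions); at the desk-scale default the AR
  proportion is expected near zero, and the report should be read
  accordingly. SNR, SFNR and FWHM are unaffected — their estimators are
  consistent with the generators by construction.
* Noise is spatially uniform within the brain; physiological noise in
  particular is not stronger near vessels and ventricles, and is a single
  global timecourse.
* Motion, T1-relaxation effects, breath-hold global signal changes,
  slice-timing and multiband effects, resting-state network structure and
  inter-regional coupling are not modelled.
* With the default partition, non-brain voxels have no temporal variance
  (see above); set `system_temporal_fraction > 0` in `generate_noise` if a
  scanner noise floor is needed, at the cost of slightly attenuating the
  other temporal descriptors.
* The drift amplitude convention (`w_drift` in units of W) is a package
  choice; drift is weighted separately from the unit-sum mix weights.
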