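"""Generate each fMRI noise component and assemble whole-brain simulations.

Noise model
-----------
A simulated scan is the sum of

* a baseline **template** (3-D mean-intensity map),
* **brain temporal noise**: a weighted mix of standardized ARMA(1,1),
  physiological (cardiac + respiratory sinusoids) and task-locked noise
  fields, re-standardized and scaled to W = mean brain intensity / SFNR,
  applied to brain voxels only,
* **drift**: a phase-randomized sum of cosine basis functions whose
  amplitudes decay so that 99% of the drift power lies at periods of at
  least the configured periodicity P; added to all voxels,
* **system noise**: a static spatial Gaussian pattern whose magnitude is set
  by the spatial SNR (plus an optional white temporal component), added to
  all voxels.

Spatial structure of the brain temporal noise comes from Gaussian random
fields of a specified FWHM.  Smoothing is performed in the Fourier domain so
the field's lag-1 autocorrelation is exactly the Gaussian-kernel value
``exp(-1/(4 sigma^2))``, making generation consistent with the
difference-variance FWHM estimator in :mod:`boldsim.estimation`.

Because the generation is stochastic, requesting SNR/SFNR does not
guarantee recovering them exactly from the output; ``generate_noise`` can
therefore iteratively re-estimate the simulated scan and rescale the noise
magnitudes until both match their targets within a tolerance (5% default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .datamodel import BrainMask, NoiseParameters, Volume4D, VolumeTemplate
from .estimation import calc_snr, calc_sfnr

__all__ = [
    "DriftBasis",
    "TemporalNoiseComponents",
    "solve_drift_dropoff",
    "generate_drift",
    "generate_spatial_field",
    "generate_arma_noise",
    "generate_physiological_noise",
    "generate_task_noise",
    "mix_temporal_noise",
    "generate_system_noise",
    "generate_noise",
]

_FWHM_FACTOR = np.sqrt(8.0 * np.log(2.0))


# ---------------------------------------------------------------------------
# Drift
# ---------------------------------------------------------------------------

@dataclass
class DriftBasis:
    """Cosine drift basis for a run of length L seconds sampled every A seconds.

    Basis function i (i = 1..floor(L/A)) is ``cos(i pi t / L + p_i)`` with
    amplitude ``r**(i-1)``; the first has a half cycle of period 2L, each
    subsequent one is a harmonic.  The drop-off ``r`` solves
    ``0.99 = (1 - r**(2L/P)) / (1 - r**(2L/A))`` so that 99% of the drift
    power sits at periods of at least the periodicity ``P``.
    """

    L: float
    A: float
    P: float = 150.0
    r: float = None  # type: ignore[assignment]
    phases: np.ndarray = None  # type: ignore[assignment]

    @property
    def n_basis(self) -> int:
        return int(np.floor(self.L / self.A))

    def amplitudes(self) -> np.ndarray:
        i = np.arange(1, self.n_basis + 1)
        return self.r ** (i - 1.0)

    def power_fraction_below(self, period: float | None = None) -> float:
        """Fraction of summed squared amplitudes at periods >= ``period`` (default P)."""
        period = self.P if period is None else period
        i = np.arange(1, self.n_basis + 1)
        power = self.amplitudes() ** 2
        return float(power[2.0 * self.L / i >= period].sum() / power.sum())


def solve_drift_dropoff(L: float, A: float, P: float = 150.0) -> float:
    """Solve ``0.99 = (1 - r**(2L/P)) / (1 - r**(2L/A))`` for r in (0, 1).

    The ratio decreases monotonically from 1 (r -> 0) to A/P (r -> 1), so a
    unique root exists iff A/P < 0.99.
    """
    if not (0 < A < P):
        raise ValueError(f"need 0 < A < P, got A={A}, P={P}")
    if A / P >= 0.99:
        raise ValueError(
            f"no drop-off solution: A/P = {A / P:.4g} >= 0.99 "
            "(as r -> 1 the power ratio tends to A/P)"
        )
    ep, ea = 2.0 * L / P, 2.0 * L / A

    def f(r):
        return (1.0 - r**ep) / (1.0 - r**ea) - 0.99

    r = optimize.brentq(f, 1e-12, 1.0 - 1e-12, xtol=1e-14, rtol=8.9e-16)
    if abs(f(r)) > 1e-10:
        raise RuntimeError(f"drop-off root residual {f(r):.3g} exceeds 1e-10")
    return float(r)


def generate_drift(
    L: float,
    A: float,
    P: float = 150.0,
    seed: int | None = None,
    phases: np.ndarray | None = None,
) -> np.ndarray:
    """One unit-std drift timecourse of length floor(L/A).

    Sum over i of ``cos(i pi t / L + p_i) * r**(i-1)`` at volume timestamps
    t = 0, A, 2A, ...; phases uniform on [0, 2pi) unless given explicitly.
    """
    basis = make_drift_basis(L, A, P, seed=seed, phases=phases)
    return evaluate_drift(basis)


def make_drift_basis(
    L: float,
    A: float,
    P: float = 150.0,
    seed: int | None = None,
    phases: np.ndarray | None = None,
) -> DriftBasis:
    r = solve_drift_dropoff(L, A, P)
    n = int(np.floor(L / A))
    if phases is None:
        phases = np.random.default_rng(seed).uniform(0.0, 2.0 * np.pi, size=n)
    else:
        phases = np.asarray(phases, dtype=float)
        if phases.shape != (n,):
            raise ValueError(f"need {n} phases, got shape {phases.shape}")
    return DriftBasis(L=L, A=A, P=P, r=r, phases=phases)


def evaluate_drift(basis: DriftBasis) -> np.ndarray:
    n = basis.n_basis
    t = np.arange(n) * basis.A
    i = np.arange(1, n + 1)
    terms = np.cos(np.outer(i, t) * np.pi / basis.L + basis.phases[:, None])
    drift = (terms * basis.amplitudes()[:, None]).sum(axis=0)
    return _standardize_1d(drift)


# ---------------------------------------------------------------------------
# Spatial fields and ARMA temporal structure
# ---------------------------------------------------------------------------

def generate_spatial_field(
    dims: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    fwhm: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Unit-variance Gaussian random field with spatial FWHM in mm.

    White Gaussian noise is coloured in the Fourier domain by circulant
    embedding of the Gaussian autocorrelation implied by the smoothing
    kernel: the field's autocorrelation at voxel lag d along each axis is
    exactly ``exp(-d^2 / (4 sigma^2))`` with sigma = fwhm / sqrt(8 ln 2) in
    voxels.  (Direct convolution with a sampled Gaussian kernel only
    approximates this once the kernel width approaches the voxel size,
    because the grid truncates the kernel's spectrum at the Nyquist
    frequency.)  The result is re-standardized to mean 0, variance 1.
    """
    if fwhm <= 0:
        raise ValueError(f"fwhm must be positive, got {fwhm}")
    rng = np.random.default_rng(seed) if rng is None else rng
    white = rng.standard_normal(dims)
    sigma_vox = fwhm / _FWHM_FACTOR / np.asarray(voxel_size, dtype=float)
    if np.all(np.exp(-1.0 / (4.0 * sigma_vox**2)) < 1e-12):
        return _standardize(white)  # sub-voxel kernel: indistinguishable from white
    spec = np.fft.rfftn(white)
    spec *= np.sqrt(_gaussian_acf_spectrum(dims, sigma_vox, rfft_last=True))
    field = np.fft.irfftn(spec, s=dims, axes=tuple(range(len(dims))))
    return _standardize(field)


def _gaussian_acf_spectrum(dims, sigma_vox, rfft_last=False) -> np.ndarray:
    """Power spectrum of the periodized, separable Gaussian autocorrelation.

    Along each axis the target autocorrelation c(d) = exp(-d^2/(4 sigma^2))
    is wrapped onto the circle of length n; its DFT is non-negative
    (periodized Gaussians stay positive-definite), giving a valid circulant
    covariance factorization.
    """
    axes_spectra = []
    for ax, (n, s) in enumerate(zip(dims, np.atleast_1d(sigma_vox))):
        d = np.minimum(np.arange(n), n - np.arange(n)).astype(float)
        c = np.exp(-(d**2) / (4.0 * s**2)) + np.exp(
            -((n - d) ** 2) / (4.0 * s**2)
        )  # wrap both directions
        spect = np.fft.rfft(c).real if (rfft_last and ax == len(dims) - 1) else np.fft.fft(c).real
        axes_spectra.append(np.clip(spect, 0.0, None))
    out = axes_spectra[0]
    for spect in axes_spectra[1:]:
        out = np.multiply.outer(out, spect)
    return out


def generate_arma_noise(
    phi: float,
    omega: float,
    dims: tuple[int, int, int],
    T: int,
    fwhm: float,
    voxel_size: tuple[float, float, float],
    seed: int | None = None,
    burn_in: int = 100,
) -> np.ndarray:
    """4-D ARMA(1,1) noise: ``Y_t = X_t + phi Y_{t-1} + omega X_{t-1}``.

    Each innovation X_t is a fresh spatially smooth Gaussian field; the
    recursion runs volume-wise with ``burn_in`` initial volumes discarded,
    and every voxel timecourse is standardized to zero mean, unit variance.
    """
    if abs(phi) >= 1:
        raise ValueError(f"|phi| must be < 1 for stationarity, got {phi}")
    if abs(omega) >= 1:
        raise ValueError(f"|omega| must be < 1, got {omega}")
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    rng = np.random.default_rng(seed)
    out = np.empty(tuple(dims) + (T,))
    x_prev = generate_spatial_field(dims, voxel_size, fwhm, rng=rng)
    y = x_prev.copy()
    if burn_in == 0:
        out[..., 0] = y
    for t in range(1, burn_in + T):
        x = generate_spatial_field(dims, voxel_size, fwhm, rng=rng)
        y = x + phi * y + omega * x_prev
        x_prev = x
        if t >= burn_in:
            out[..., t - burn_in] = y
    return _standardize_voxelwise(out)


# ---------------------------------------------------------------------------
# Physiological and task noise
# ---------------------------------------------------------------------------

def generate_physiological_noise(
    T: int,
    A: float,
    heart_hz: float = 1.17,
    resp_hz: float = 0.2,
    seed: int | None = None,
    phases: tuple[float, float] | None = None,
) -> np.ndarray:
    """Cardiac + respiratory sinusoids with random phase, standardized.

    Sampled at the volume times t = 0, A, 2A, ...; with TR above the Nyquist
    limit of the cardiac frequency the heart component aliases to
    ``|heart_hz - k/A|`` for the nearest integer k.
    """
    if T < 2:
        raise ValueError(f"need T >= 2, got {T}")
    if phases is None:
        rng = np.random.default_rng(seed)
        ph_h, ph_r = rng.uniform(0.0, 2.0 * np.pi, size=2)
    else:
        ph_h, ph_r = phases
    t = np.arange(T) * A
    wave = np.sin(2.0 * np.pi * heart_hz * t + ph_h) + np.sin(
        2.0 * np.pi * resp_hz * t + ph_r
    )
    return _standardize_1d(wave)


def generate_task_noise(
    stim_volume_weights: np.ndarray,
    dist: str = "gaussian",
    sigma: float = 1.0,
    seed: int | None = None,
    rician_nu: float = 0.0,
) -> np.ndarray:
    """Noise drawn only at volumes where the stimulus weight is nonzero.

    ``stim_volume_weights`` is the event indicator resampled to the volume
    grid.  Gaussian draws, or Rician (magnitude of a complex Gaussian with
    location ``rician_nu`` and scale ``sigma``); the draws are standardized
    over the event volumes, zeros elsewhere.
    """
    stim = np.asarray(stim_volume_weights, dtype=float)
    out = np.zeros_like(stim)
    events = stim > 0
    n = int(events.sum())
    if n == 0:
        warnings.warn("generate_task_noise: stimulus has no events; returning zeros",
                      stacklevel=2)
        return out
    rng = np.random.default_rng(seed)
    if dist == "gaussian":
        draws = rng.normal(0.0, sigma, size=n)
    elif dist == "rician":
        re = rng.normal(rician_nu, sigma, size=n)
        im = rng.normal(0.0, sigma, size=n)
        draws = np.hypot(re, im)
    else:
        raise ValueError(f"unknown task noise distribution {dist!r}")
    if n > 1 and draws.std() > 0:
        draws = (draws - draws.mean()) / draws.std()
    out[events] = draws
    return out


# ---------------------------------------------------------------------------
# Mixing and system noise
# ---------------------------------------------------------------------------

@dataclass
class TemporalNoiseComponents:
    """Standardized noise components ready for weighting.

    ``v_arma`` is a 4-D field; ``v_physio``, ``v_task`` and ``v_drift`` may
    be 1-D timecourses (broadcast over space) or 4-D fields.  ``W`` is the
    brain temporal-noise magnitude in intensity units, defined as mean brain
    template intensity / SFNR.
    """

    v_arma: np.ndarray
    v_physio: np.ndarray
    v_task: np.ndarray
    v_drift: np.ndarray
    W: float


def mix_temporal_noise(
    components: TemporalNoiseComponents,
    params: NoiseParameters,
    mask: BrainMask,
    restandardize: bool = True,
) -> np.ndarray:
    """Weighted mix ``W (w_a v_a + w_p v_p + w_t v_t) + w_drift W v_drift``.

    The brain-specific components apply to brain voxels only; drift is added
    to every voxel.  With ``restandardize`` the weighted brain mix is brought
    back to unit per-voxel temporal std before scaling by W, so the brain
    temporal std equals W regardless of component correlations.
    """
    s = params.w_arma + params.w_physio + params.w_task
    if abs(s - 1.0) > 1e-8:
        raise ValueError(f"w_arma + w_physio + w_task must sum to 1, got {s:.6g}")
    W = components.W
    mix = params.w_arma * np.asarray(components.v_arma, dtype=float)
    mix = mix + params.w_physio * _as_time_field(components.v_physio, mix.shape)
    mix = mix + params.w_task * _as_time_field(components.v_task, mix.shape)
    if restandardize:
        mix = _standardize_voxelwise(mix, demean=False)
    out = np.zeros(mix.shape)
    out[mask.data] = W * mix[mask.data]
    out += params.w_drift * W * _as_time_field(components.v_drift, mix.shape)
    return out


def generate_system_noise(
    template: VolumeTemplate,
    mask: BrainMask,
    snr: float,
    sfnr: float,
    T: int,
    seed: int | None = None,
    temporal_fraction: float = 0.0,
) -> np.ndarray:
    """Machine (thermal) noise added to the template over all voxels.

    The spatial component is a Gaussian pattern, constant over time, whose
    std is chosen so that the non-brain spatial std of template + noise
    equals mean brain intensity / snr (the template's own non-brain spatial
    variance is subtracted; if it already exceeds the target a warning is
    raised and no spatial noise is added).  ``temporal_fraction`` optionally
    adds white temporal fluctuation with std
    ``temporal_fraction * mean brain intensity / sfnr`` to every voxel; the
    default 0 leaves the whole temporal variance budget to the structured
    brain noise so that the target SFNR is met by construction.
    """
    if snr <= 0 or sfnr <= 0:
        raise ValueError("snr and sfnr must be positive")
    if temporal_fraction < 0:
        raise ValueError("temporal_fraction must be >= 0")
    rng = np.random.default_rng(seed)
    brain_mean = template.data[mask.data].mean()
    target_var = (brain_mean / snr) ** 2
    background_var = template.data[~mask.data].var()
    excess = target_var - background_var
    if excess < 0:
        warnings.warn(
            "template non-brain spatial variance already exceeds the target "
            f"set by snr={snr:.4g}; adding no spatial system noise",
            stacklevel=2,
        )
        excess = 0.0
    static = rng.normal(0.0, np.sqrt(excess), size=template.data.shape)
    out = np.broadcast_to(static[..., None], template.data.shape + (T,)).copy()
    if temporal_fraction > 0:
        sigma_t = temporal_fraction * brain_mean / sfnr
        out += rng.normal(0.0, sigma_t, size=out.shape)
    return out


# ---------------------------------------------------------------------------
# Whole-scan assembly with iterative fitting
# ---------------------------------------------------------------------------

def generate_noise(
    template: VolumeTemplate,
    mask: BrainMask,
    params: NoiseParameters,
    T: int,
    tr: float = 1.5,
    stim_for_task_noise: np.ndarray | None = None,
    fit: bool = True,
    fit_thresh: float = 0.05,
    max_iterations: int = 20,
    seed: int | None = None,
    system_temporal_fraction: float = 0.0,
) -> Volume4D:
    """Simulate a whole-brain 4-D scan with the requested noise properties.

    Assembles template + mixed brain temporal noise + drift + system noise.
    With ``fit`` enabled the scan is re-estimated (SNR, SFNR) and the
    internal spatial/temporal noise magnitudes are rescaled multiplicatively
    (ratio with damping 0.8) until both estimates are within ``fit_thresh``
    relative error of their targets or ``max_iterations`` is reached, in
    which case the best iterate is returned with a warning.  Fitting rescales
    the same noise realization, so a given seed is reproducible whether or
    not fitting converges.
    """
    if template.data.shape != mask.data.shape:
        raise ValueError("template and mask shapes differ")
    if T < 4:
        raise ValueError(f"need T >= 4 to simulate and estimate, got T={T}")
    if params.w_task > 0 and stim_for_task_noise is None:
        raise ValueError(
            "w_task > 0 requires stim_for_task_noise (an event indicator on "
            "the volume grid); task noise cannot be generated without events"
        )
    rng = np.random.default_rng(seed)
    child = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    dims = template.data.shape
    L = T * tr
    v_arma = generate_arma_noise(
        params.ar_phi, params.ma_omega, dims, T, params.fwhm,
        template.voxel_size, seed=child(),
    )
    v_physio = generate_physiological_noise(
        T, tr, params.physio_heart_hz, params.physio_resp_hz, seed=child()
    )
    if stim_for_task_noise is not None:
        v_task = generate_task_noise(
            stim_for_task_noise, dist=params.task_noise_dist, seed=child()
        )
    else:
        v_task = np.zeros(T)
    v_drift = generate_drift(L, tr, params.drift_period, seed=child())

    brain_mean = template.data[mask.data].mean()
    W0 = brain_mean / params.sfnr
    comps = TemporalNoiseComponents(
        v_arma=v_arma, v_physio=v_physio, v_task=v_task, v_drift=v_drift, W=W0
    )
    system = generate_system_noise(
        template, mask, params.snr, params.sfnr, T,
        seed=child(), temporal_fraction=system_temporal_fraction,
    )

    def assemble(scale_temporal: float, scale_spatial: float) -> np.ndarray:
        comps.W = W0 * scale_temporal
        data = template.data[..., None] + mix_temporal_noise(comps, params, mask)
        data += scale_spatial * system
        return data

    scale_t, scale_s = 1.0, 1.0
    if not fit:
        data = assemble(scale_t, scale_s)
        return Volume4D(data, voxel_size=template.voxel_size, tr=tr)

    best = None
    best_err = np.inf
    damping = 0.8
    for _ in range(max_iterations):
        data = assemble(scale_t, scale_s)
        vol = Volume4D(data, voxel_size=template.voxel_size, tr=tr)
        est_snr = calc_snr(vol, mask)
        est_sfnr = calc_sfnr(vol, mask)
        err_snr = abs(est_snr - params.snr) / params.snr
        err_sfnr = abs(est_sfnr - params.sfnr) / params.sfnr
        err = max(err_snr, err_sfnr)
        if err < best_err:
            best, best_err = vol, err
        if err_snr <= fit_thresh and err_sfnr <= fit_thresh:
            return vol
        # SNR too low => too much spatial noise => shrink; SFNR too low =>
        # too much temporal noise => shrink W.  Damped multiplicative update.
        scale_s *= (est_snr / params.snr) ** damping
        scale_t *= (est_sfnr / params.sfnr) ** damping
    warnings.warn(
        f"noise fitting did not converge in {max_iterations} iterations "
        f"(best max relative error {best_err:.3f}); returning best iterate",
        stacklevel=2,
    )
    return best


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _standardize(field: np.ndarray) -> np.ndarray:
    s = field.std()
    if s == 0:
        raise ValueError("cannot standardize a constant field")
    return (field - field.mean()) / s


def _standardize_1d(x: np.ndarray) -> np.ndarray:
    return _standardize(np.asarray(x, dtype=float))


def _standardize_voxelwise(field: np.ndarray, demean: bool = True) -> np.ndarray:
    """Standardize each voxel timecourse (last axis) to unit variance."""
    std = field.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    if demean:
        field = field - field.mean(axis=-1, keepdims=True)
    return field / std


def _as_time_field(component: np.ndarray, shape: tuple) -> np.ndarray:
    """Broadcast a 1-D timecourse over space, or pass a 4-D field through."""
    component = np.asarray(component, dtype=float)
    if component.ndim == 1:
        if component.shape[0] != shape[-1]:
            raise ValueError(
                f"timecourse length {component.shape[0]} does not match T={shape[-1]}"
            )
        return np.broadcast_to(component, shape)
    if component.shape != shape:
        raise ValueError(f"component shape {component.shape} does not match {shape}")
    return component
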