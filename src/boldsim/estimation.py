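"""Estimate noise descriptors (SNR, SFNR, FWHM, ARMA) from a 4-D volume.

The four estimators mirror common fMRI quality metrics:

* **SNR** — spatial signal-to-noise: mean brain intensity at the middle
  volume divided by the standard deviation of non-brain intensities at that
  same volume.
* **SFNR** — signal-to-fluctuation-noise (temporal SNR): per brain voxel,
  temporal mean divided by the standard deviation of the residual after
  removing a second-order polynomial trend; averaged over brain voxels.
* **FWHM** — spatial smoothness of the temporal noise, estimated per axis
  from the ratio of first-difference variance to total variance
  (difference-variance / AFNI-style estimator), converted via
  FWHM = sigma * sqrt(8 ln 2) and expressed in mm.
* **ARMA(1,1)** — maximum-likelihood fit per voxel on a random sample of
  brain-voxel timecourses, coefficients averaged.

Only these descriptors are estimable from a raw scan; drift amplitude,
physiological weights and task-noise weight are not recoverable from the
data and must be specified by the user when simulating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import BrainMask, Volume4D

__all__ = [
    "NoiseEstimate",
    "calc_snr",
    "calc_sfnr",
    "calc_fwhm",
    "calc_arma",
    "calc_noise",
]

_FWHM_FACTOR = np.sqrt(8.0 * np.log(2.0))  # sigma -> FWHM for a Gaussian


@dataclass
class NoiseEstimate:
    """The estimable subset of noise descriptors, plus provenance."""

    snr: float
    sfnr: float
    fwhm: float
    ar_phi: float
    ma_omega: float
    provenance: str = ""

    def __post_init__(self):
        for name in ("snr", "sfnr", "fwhm", "ar_phi", "ma_omega"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"noise estimate field {name} is not finite")

    def to_dict(self) -> dict:
        return {
            "snr": self.snr,
            "sfnr": self.sfnr,
            "fwhm": self.fwhm,
            "ar_phi": self.ar_phi,
            "ma_omega": self.ma_omega,
        }


def calc_snr(vol: Volume4D, mask: BrainMask) -> float:
    """Spatial SNR at the middle volume (index ``floor(T/2)``)."""
    if mask.n_brain < 1 or mask.n_nonbrain < 2:
        raise ValueError("SNR needs >= 1 brain and >= 2 non-brain voxels")
    mid = vol.n_timepoints // 2
    volume = vol.data[..., mid]
    brain_mean = volume[mask.data].mean()
    nonbrain = volume[~mask.data]
    nonbrain_std = nonbrain.std()
    if nonbrain_std == 0:
        raise ValueError(
            "SNR undefined: zero variance across non-brain voxels. If the "
            "scan was preprocessed and non-brain voxels zeroed out, they are "
            "an inappropriate baseline for non-brain variability; estimate "
            "SNR from the unmasked data or specify snr manually."
        )
    return float(brain_mean / nonbrain_std)


def _detrend_quadratic(timecourses: np.ndarray) -> np.ndarray:
    """Residuals after removing a second-order polynomial in time.

    ``timecourses`` is (n_voxels, T); the fit is solved once for all voxels.
    """
    T = timecourses.shape[1]
    t = np.linspace(-1.0, 1.0, T)  # scaled for conditioning
    X = np.column_stack([np.ones(T), t, t**2])
    beta, *_ = np.linalg.lstsq(X, timecourses.T, rcond=None)
    return timecourses - (X @ beta).T


def _regress_out_global(timecourses: np.ndarray, global_tc: np.ndarray) -> np.ndarray:
    """Residuals after removing intercept + the (centred) global timecourse.

    When the global timecourse is constant, only the mean is removed.
    """
    T = timecourses.shape[1]
    g = global_tc - global_tc.mean()
    if g.std() == 0:
        return timecourses - timecourses.mean(axis=1, keepdims=True)
    X = np.column_stack([np.ones(T), g])
    beta, *_ = np.linalg.lstsq(X, timecourses.T, rcond=None)
    return timecourses - (X @ beta).T


def calc_sfnr(vol: Volume4D, mask: BrainMask) -> float:
    """Signal-to-fluctuation-noise ratio averaged over brain voxels."""
    T = vol.n_timepoints
    if T < 4:
        raise ValueError(f"SFNR needs >= 4 time points for quadratic detrending, got {T}")
    tcs = vol.data[mask.data]  # (n_brain, T)
    resid = _detrend_quadratic(tcs)
    res_std = resid.std(axis=1)
    # residuals of noiseless (polynomial) timecourses are zero up to round-off
    ok = res_std > 1e-10 * np.maximum(1.0, np.abs(tcs).max(axis=1))
    if not ok.all():
        warnings.warn(
            f"calc_sfnr: excluding {int((~ok).sum())} brain voxel(s) with zero "
            "residual variance",
            stacklevel=2,
        )
    if not ok.any():
        raise ValueError("SFNR undefined: every brain voxel has zero residual variance")
    voxel_sfnr = tcs[ok].mean(axis=1) / res_std[ok]
    return float(voxel_sfnr.mean())


def _fwhm_one_axis(volume: np.ndarray, mask: np.ndarray, axis: int) -> float:
    """Difference-variance smoothness along one axis, in voxel widths.

    Returns NaN when the axis is uninformative (no valid difference pairs or
    non-positive lag-1 correlation, i.e. rougher than white noise).
    """
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = slice(None, -1)
    sl_hi[axis] = slice(1, None)
    pair_ok = mask[tuple(sl_lo)] & mask[tuple(sl_hi)]
    if pair_ok.sum() < 2:
        return np.nan
    diffs = volume[tuple(sl_hi)][pair_ok] - volume[tuple(sl_lo)][pair_ok]
    var_diff = diffs.var()
    var_tot = volume[mask].var()
    if var_tot == 0:
        raise ValueError("FWHM undefined: constant volume")
    rho = 1.0 - var_diff / (2.0 * var_tot)
    if rho <= 0:
        return np.nan
    sigma2 = -1.0 / (4.0 * np.log(rho))  # Gaussian ACF: rho(1) = exp(-1/(4 sigma^2))
    return float(_FWHM_FACTOR * np.sqrt(sigma2))


def calc_fwhm(
    vol: Volume4D,
    mask: BrainMask,
    n_timepoints_sampled: int | None = None,
) -> float:
    """Spatial FWHM (mm) of the temporal noise, averaged over axes and volumes.

    Each voxel's temporal mean is removed first so the estimate reflects the
    smoothness of the temporal fluctuations, not of the anatomy/template.
    Volumes are sampled on a regular grid: by default every ``ceil(T/10)``-th
    volume; ``n_timepoints_sampled`` overrides the number sampled.
    """
    if any(d < 3 for d in vol.spatial_shape):
        raise ValueError("FWHM estimation needs all spatial dims >= 3")
    T = vol.n_timepoints
    if n_timepoints_sampled is None:
        step = int(np.ceil(T / 10))
    else:
        if n_timepoints_sampled < 1:
            raise ValueError("n_timepoints_sampled must be >= 1")
        step = max(1, T // n_timepoints_sampled)
    sample = np.arange(0, T, step)

    demeaned = vol.data - vol.data.mean(axis=3, keepdims=True)
    per_volume = []
    for t in sample:
        volume = demeaned[..., t]
        vals = [
            _fwhm_one_axis(volume, mask.data, ax) * vol.voxel_size[ax]
            for ax in range(3)
        ]
        vals = [v for v in vals if np.isfinite(v)]
        if vals:
            per_volume.append(np.mean(vals))
    if not per_volume:
        raise ValueError(
            "FWHM undefined: no informative axis in any sampled volume "
            "(volume degenerate or rougher than white noise everywhere)"
        )
    return float(np.mean(per_volume))


def calc_arma(
    vol: Volume4D,
    mask: BrainMask,
    n_voxels: int = 100,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Average ARMA(1,1) coefficients over a random sample of brain voxels.

    Each sampled timecourse is demeaned and cleaned of the brain global-mean
    timecourse (which carries scanner drift and physiological fluctuations,
    both spatially uniform nuisance terms that would otherwise bias the AR
    coefficient), standardized, then fit by maximum likelihood (statsmodels
    ARIMA, order (1, 0, 1), no trend).  Polynomial detrending is
    deliberately avoided here: removing a low-order trend from short runs
    absorbs genuine low-frequency autoregressive power and biases the AR
    coefficient downward.  Non-convergent or degenerate fits are skipped
    with a warning.
    """
    from statsmodels.tsa.arima.model import ARIMA

    T = vol.n_timepoints
    if T < 20:
        raise ValueError(f"ARMA estimation needs >= 20 time points, got {T}")
    rng = np.random.default_rng(seed)
    idx = np.flatnonzero(mask.data.ravel())
    if idx.size > n_voxels:
        idx = rng.choice(idx, size=n_voxels, replace=False)
    tcs = vol.data.reshape(-1, T)[idx]
    resid = _regress_out_global(tcs, vol.data[mask.data].mean(axis=0))

    phis, omegas = [], []
    n_failed = 0
    for row in resid:
        s = row.std()
        if s == 0:
            n_failed += 1
            continue
        y = row / s
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = ARIMA(y, order=(1, 0, 1), trend="n").fit()
            phi, omega = float(fit.arparams[0]), float(fit.maparams[0])
        except Exception:
            n_failed += 1
            continue
        if not (np.isfinite(phi) and np.isfinite(omega) and abs(phi) < 1 and abs(omega) < 1):
            n_failed += 1
            continue
        phis.append(phi)
        omegas.append(omega)
    if n_failed:
        warnings.warn(
            f"calc_arma: {n_failed}/{len(resid)} voxel fits failed or did not "
            "converge and were skipped",
            stacklevel=2,
        )
    if not phis:
        raise ValueError("ARMA estimation failed for every sampled voxel")
    return float(np.mean(phis)), float(np.mean(omegas))


def calc_noise(
    vol: Volume4D,
    mask: BrainMask,
    seed: int | None = 0,
    n_arma_voxels: int = 100,
    provenance: str = "",
) -> NoiseEstimate:
    """Aggregate all estimable descriptors into one :class:`NoiseEstimate`.

    Component errors propagate with the failing descriptor named.
    """
    results = {}
    for name, fn in (
        ("snr", lambda: calc_snr(vol, mask)),
        ("sfnr", lambda: calc_sfnr(vol, mask)),
        ("fwhm", lambda: calc_fwhm(vol, mask)),
        ("arma", lambda: calc_arma(vol, mask, n_voxels=n_arma_voxels, seed=seed)),
    ):
        try:
            results[name] = fn()
        except ValueError as exc:
            raise ValueError(f"noise estimation failed for {name}: {exc}") from exc
    phi, omega = results["arma"]
    return NoiseEstimate(
        snr=results["snr"],
        sfnr=results["sfnr"],
        fwhm=results["fwhm"],
        ar_phi=phi,
        ma_omega=omega,
        provenance=provenance,
    )
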