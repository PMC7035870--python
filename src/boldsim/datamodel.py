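"""Core containers for 4-D functional volumes, baseline templates, brain masks
and noise-parameter sets.

The simulation pipeline works on a single internal axis convention:
volume data are stored ``(x, y, z, t)``, voxel coordinates are 0-based
indices, and spatial units are millimetres via ``voxel_size``.  All file I/O
(:mod:`boldsim.io`) maps external orientations onto this convention.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Volume4D",
    "VolumeTemplate",
    "BrainMask",
    "NoiseParameters",
    "compute_template",
    "compute_mask",
    "synthetic_template",
]


@dataclass
class Volume4D:
    """A 4-D functional volume: intensities over space and time.

    Parameters
    ----------
    data
        Array of shape ``(x, y, z, t)``, arbitrary intensity units.
    voxel_size
        Spatial extent of one voxel per axis, mm.
    tr
        Volume acquisition time (repetition time), seconds.
    affine
        Optional 4x4 voxel-to-world transform; identity by default.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tr: float = 1.0
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(
                f"Volume4D requires 4-D (x, y, z, t) data, got {self.data.ndim}-D"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume4D intensities must all be finite")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class VolumeTemplate:
    """3-D baseline intensity map (temporal mean of a scan).

    Magnitude MR images are non-negative; the template inherits that.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeTemplate requires 3-D data, got {self.data.ndim}-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("template intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("template intensities must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)


@dataclass
class BrainMask:
    """Binary partition of a template into brain and non-brain voxels."""

    data: np.ndarray
    n_brain: int = field(init=False)
    n_nonbrain: int = field(init=False)

    def __post_init__(self):
        arr = np.asarray(self.data)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mask must be strictly binary")
        self.data = arr.astype(bool)
        self.n_brain = int(self.data.sum())
        self.n_nonbrain = int(self.data.size - self.n_brain)
        if self.n_brain == 0 or self.n_nonbrain == 0:
            raise ValueError(
                "unusable mask: need 0 < n_brain < total voxels "
                f"(n_brain={self.n_brain}, total={self.data.size})"
            )


@dataclass
class NoiseParameters:
    """Full descriptor set driving noise generation.

    ``snr`` (spatial signal-to-noise), ``sfnr`` (signal-to-fluctuation-noise,
    a.k.a. temporal SNR), ``fwhm`` (spatial smoothness of the temporal noise,
    mm) and the ARMA(1,1) coefficients ``ar_phi``/``ma_omega`` are estimable
    from data; the temporal mixing weights and drift/physiological settings
    cannot be recovered from a raw scan and must be specified by the user.

    ``w_arma``, ``w_physio`` and ``w_task`` weight the standardized brain
    temporal-noise components and must sum to 1.  ``w_drift`` expresses the
    scanner-drift standard deviation in units of the brain temporal-noise
    magnitude W and may exceed 1.
    """

    snr: float = 30.0
    sfnr: float = 70.0
    fwhm: float = 4.0
    ar_phi: float = 0.5
    ma_omega: float = 0.2
    drift_period: float = 150.0
    w_arma: float = 0.9
    w_physio: float = 0.1
    w_task: float = 0.0
    w_drift: float = 0.5
    physio_heart_hz: float = 1.17
    physio_resp_hz: float = 0.2
    task_noise_dist: str = "gaussian"

    _WEIGHT_TOL = 1e-8

    def __post_init__(self):
        for name in ("snr", "sfnr", "fwhm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("ar_phi", "ma_omega"):
            if not -1.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1), got {getattr(self, name)}")
        if self.drift_period <= 0:
            raise ValueError("drift_period must be positive")
        for name in ("w_arma", "w_physio", "w_task"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.w_drift < 0:
            raise ValueError("w_drift must be non-negative")
        s = self.w_arma + self.w_physio + self.w_task
        if abs(s - 1.0) > self._WEIGHT_TOL:
            raise ValueError(
                f"w_arma + w_physio + w_task must sum to 1, got {s:.6g}"
            )
        if self.task_noise_dist not in ("gaussian", "rician"):
            raise ValueError(
                f"task_noise_dist must be 'gaussian' or 'rician', got {self.task_noise_dist!r}"
            )

    def replace(self, **changes) -> "NoiseParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compute_template(vol: Volume4D) -> VolumeTemplate:
    """Baseline template: element-wise temporal mean of a 4-D volume."""
    if vol.n_timepoints < 2:
        raise ValueError(
            f"template requires >= 2 time points, got {vol.n_timepoints}"
        )
    mean = vol.data.mean(axis=3)
    # magnitude images are non-negative; guard tiny numerical undershoot
    return VolumeTemplate(np.clip(mean, 0.0, None), voxel_size=vol.voxel_size)


def compute_mask(template: VolumeTemplate, threshold_fraction: float = 0.5) -> BrainMask:
    """Threshold the template into brain / non-brain voxels.

    A voxel is brain iff its intensity is at least ``threshold_fraction``
    times the mean intensity of the nonzero voxels.  The relative rule makes
    the mask invariant to global intensity rescaling.
    """
    if not 0.0 < threshold_fraction:
        raise ValueError("threshold_fraction must be positive")
    data = template.data
    nonzero = data[data > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero template: no brain found")
    thresh = threshold_fraction * nonzero.mean()
    mask = data >= thresh
    return BrainMask(mask)


def synthetic_template(
    dims: tuple[int, int, int] = (24, 24, 16),
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.5),
    brain_intensity: float = 800.0,
    background_scale: float = 20.0,
    seed: int | None = 0,
) -> VolumeTemplate:
    """Synthetic (non-anatomical) default template: an ellipsoid 'brain'.

    An ellipsoid of uniform intensity ``brain_intensity`` with semi-axes 0.4
    of each dimension, centred in the box, over a Rician-like background
    (magnitude of a centred complex Gaussian, i.e. Rayleigh with scale
    ``background_scale``) mimicking the low but nonzero intensities outside
    the head in magnitude MR images.  ``ellipsoid_mask`` ground truth is
    recoverable via :func:`synthetic_brain_mask`.
    """
    rng = np.random.default_rng(seed)
    data = _rayleigh_background(dims, background_scale, rng)
    data[synthetic_brain_mask(dims)] = brain_intensity
    return VolumeTemplate(data, voxel_size=voxel_size)


def synthetic_brain_mask(dims: tuple[int, int, int]) -> np.ndarray:
    """Ground-truth ellipsoid membership for :func:`synthetic_template`."""
    grids = np.meshgrid(*(np.arange(d) for d in dims), indexing="ij")
    centre = [(d - 1) / 2.0 for d in dims]
    semi = [0.4 * d for d in dims]
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, centre, semi))
    return r2 <= 1.0


def _rayleigh_background(dims, scale, rng):
    if scale <= 0:
        return np.zeros(dims)
    re = rng.normal(0.0, scale, size=dims)
    im = rng.normal(0.0, scale, size=dims)
    return np.hypot(re, im)
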