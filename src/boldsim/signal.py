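"""Task signal: event timecourses, HRF convolution, calibration, embedding.

The signal path is strictly additive and linear: build a high-resolution
event indicator, convolve it with the canonical double-gamma hemodynamic
response function, scale the evoked amplitude to a requested percent signal
change (PSC) or contrast-to-noise ratio (CNR), and add the resulting
pattern-weighted responses to a noise volume.

For multivariate designs, :func:`embed_graph_pattern` places stimuli on a
2-D ring grouped into communities and maps the ring into voxel space with a
random orthonormal transformation, preserving all pairwise Euclidean
distances, so that community structure (controlled by a ``density``
parameter) can be embedded as distributed voxel patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

from .datamodel import Volume4D

__all__ = [
    "StimTimecourse",
    "PatternSpec",
    "generate_stimfunction",
    "double_gamma_hrf",
    "convolve_hrf",
    "compute_signal_scale",
    "embed_graph_pattern",
    "apply_signal",
]


@dataclass
class StimTimecourse:
    """High-resolution event indicator for one condition.

    ``values[k]`` is the summed event weight on ``[k*dt, (k+1)*dt)``; events
    occupy half-open intervals ``[onset, onset + duration)``.
    """

    values: np.ndarray
    dt: float
    onsets: tuple = ()
    durations: tuple = ()
    total_time: float = 0.0


@dataclass
class PatternSpec:
    """Per-event voxel patterns for a region of interest.

    ``pattern`` has one row per event/condition and one column per ROI
    voxel; entries are dimensionless pattern weights.  ``magnitude`` is the
    evoked-response size in the units of ``metric`` (percent signal change
    by default); ``density`` records the community clustering used by the
    graph embedding, if any.
    """

    roi_voxel_ids: np.ndarray
    pattern: np.ndarray
    magnitude: float | None = None
    metric: str = "percent_signal_change"
    density: float | None = None
    node_positions_2d: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.roi_voxel_ids = np.atleast_2d(np.asarray(self.roi_voxel_ids, dtype=int))
        self.pattern = np.atleast_2d(np.asarray(self.pattern, dtype=float))
        if self.pattern.shape[1] != self.roi_voxel_ids.shape[0]:
            raise ValueError(
                f"pattern has {self.pattern.shape[1]} voxel columns but "
                f"{self.roi_voxel_ids.shape[0]} ROI voxels were given"
            )
        if self.density is not None and not 0.0 <= self.density <= 1.0:
            raise ValueError(f"density must lie in [0, 1], got {self.density}")


def generate_stimfunction(
    onsets,
    durations,
    total_time: float,
    dt: float = 0.1,
    weights=None,
) -> StimTimecourse:
    """Boxcar event weight vector at resolution ``dt`` seconds per sample.

    ``durations`` may be a scalar (shared) or per-event sequence; overlapping
    events sum.  Length of the result is ``round(total_time / dt)``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.broadcast_to(np.asarray(durations, dtype=float), onsets.shape)
    if weights is None:
        weights = np.ones_like(onsets)
    else:
        weights = np.broadcast_to(np.asarray(weights, dtype=float), onsets.shape)
    if np.any(onsets < 0) or np.any(durations < 0):
        raise ValueError("onsets and durations must be non-negative")
    if onsets.size and np.any(onsets + durations > total_time + 1e-9):
        raise ValueError("event extends past total_time")
    n = int(round(total_time / dt))
    values = np.zeros(n)
    for onset, dur, w in zip(onsets, durations, weights):
        lo = int(round(onset / dt))
        hi = int(round((onset + dur) / dt))
        values[lo:hi] += w
    return StimTimecourse(values=values, dt=dt, onsets=tuple(onsets),
                          durations=tuple(durations), total_time=total_time)


def double_gamma_hrf(
    dt: float = 0.1,
    duration: float = 32.0,
    peak_shape: float = 6.0,
    undershoot_shape: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    scale: float = 1.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds.

    Difference of two gamma densities: a peak (shape 6, scale 1, maximum
    near 5 s) minus a scaled undershoot (shape 16, ratio 1/6).
    """
    t = np.arange(0.0, duration, dt)
    h = gamma_dist.pdf(t / scale, peak_shape) - undershoot_ratio * gamma_dist.pdf(
        t / scale, undershoot_shape
    )
    return h


def convolve_hrf(
    stim: StimTimecourse,
    tr: float,
    scale_function: bool = True,
    **hrf_kwargs,
) -> np.ndarray:
    """Convolve an event timecourse with the double-gamma HRF and downsample
    to the volume grid.

    ``stim.dt`` must divide ``tr``.  With ``scale_function`` the output is
    normalized so its peak response is exactly 1 — the convention that makes
    a percent-signal-change amplitude apply to the peak evoked response;
    otherwise the raw convolution (scaled by ``dt``) is returned.
    """
    step = tr / stim.dt
    if abs(step - round(step)) > 1e-9:
        raise ValueError(f"stim dt {stim.dt} must divide tr {tr}")
    step = int(round(step))
    kernel = double_gamma_hrf(dt=stim.dt, **hrf_kwargs)
    response = np.convolve(stim.values, kernel)[: stim.values.size]
    if scale_function:
        peak = np.abs(response).max()
        response = response / peak if peak > 0 else response
    else:
        response = response * stim.dt
    return response[::step]


def compute_signal_scale(
    voxel_noise_timecourse: np.ndarray,
    magnitude: float,
    metric: str = "percent_signal_change",
    noise_std: float | None = None,
) -> float:
    """Evoked-response amplitude in intensity units for one voxel.

    percent_signal_change: mean(voxel) / 100 * magnitude.
    cnr: magnitude * noise_std.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if metric == "percent_signal_change":
        return float(np.mean(voxel_noise_timecourse) / 100.0 * magnitude)
    if metric == "cnr":
        if noise_std is None:
            raise ValueError("cnr metric requires noise_std")
        return float(magnitude * noise_std)
    raise ValueError(f"unknown signal metric {metric!r}")


def embed_graph_pattern(
    n_nodes: int,
    communities: int,
    density: float,
    n_voxels: int,
    seed: int | None = None,
    magnitude: float | None = None,
    metric: str = "percent_signal_change",
) -> PatternSpec:
    """Voxel patterns encoding a ring of nodes grouped into communities.

    Nodes sit at uniform angles on a unit circle with communities occupying
    contiguous arcs; each node is then pulled linearly toward its community
    centroid by the factor ``density`` (0 = untouched ring with all adjacent
    edges equal; 1 = every community collapsed to a point).  A seeded random
    orthonormal map carries the 2-D coordinates into ``n_voxels``-dimensional
    voxel space, preserving every pairwise Euclidean distance.
    """
    if n_voxels < 2:
        raise ValueError("need n_voxels >= 2")
    if n_nodes % communities != 0:
        raise ValueError(
            f"n_nodes ({n_nodes}) must be divisible by communities ({communities})"
        )
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must lie in [0, 1], got {density}")
    angles = 2.0 * np.pi * np.arange(n_nodes) / n_nodes
    pos = np.column_stack([np.cos(angles), np.sin(angles)])
    per = n_nodes // communities
    for c in range(communities):
        block = slice(c * per, (c + 1) * per)
        centroid = pos[block].mean(axis=0)
        pos[block] = (1.0 - density) * pos[block] + density * centroid

    rng = np.random.default_rng(seed)
    gauss = rng.standard_normal((n_voxels, 2))
    q, _ = np.linalg.qr(gauss)  # (n_voxels, 2), orthonormal columns
    pattern = pos @ q.T  # (n_nodes, n_voxels)
    roi = np.arange(n_voxels)
    return PatternSpec(
        roi_voxel_ids=np.column_stack([roi, np.zeros_like(roi), np.zeros_like(roi)]),
        pattern=pattern,
        magnitude=magnitude,
        metric=metric,
        density=density,
        node_positions_2d=pos,
    )


def apply_signal(
    noise_vol: Volume4D,
    pattern: PatternSpec,
    responses: np.ndarray,
) -> Volume4D:
    """Add pattern-weighted evoked responses to a noise volume.

    ``responses`` is (n_events, T) on the volume grid (a single shared
    response may be passed as 1-D).  When ``pattern.magnitude`` is set, each
    ROI voxel's pattern column is calibrated so its largest absolute entry
    evokes the amplitude given by :func:`compute_signal_scale` for that
    voxel's noise timecourse, with the other events scaled proportionally;
    otherwise pattern entries are treated as intensity units directly.
    The output is noise + signal, addition only.
    """
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    n_events = pattern.pattern.shape[0]
    if responses.shape[0] == 1 and n_events > 1:
        responses = np.broadcast_to(responses, (n_events, responses.shape[1]))
    if responses.shape[0] != n_events:
        raise ValueError(
            f"{n_events} pattern rows but {responses.shape[0]} response timecourses"
        )
    if responses.shape[1] != noise_vol.n_timepoints:
        raise ValueError("responses are not aligned to the volume time grid")
    ids = pattern.roi_voxel_ids
    if np.any(ids < 0) or np.any(ids >= np.array(noise_vol.spatial_shape)):
        raise ValueError("ROI voxel ids fall outside the volume bounds")

    weights = pattern.pattern
    if pattern.magnitude is not None:
        weights = weights.copy()
        for j, (x, y, z) in enumerate(ids):
            tc = noise_vol.data[x, y, z, :]
            peak = np.abs(weights[:, j]).max()
            if peak == 0:
                continue
            amp = compute_signal_scale(
                tc, pattern.magnitude, metric=pattern.metric,
                noise_std=float(np.std(tc)),
            )
            weights[:, j] *= amp / peak

    signal = np.zeros(noise_vol.data.shape)
    # signal[v, t] = sum_e weights[e, v] * responses[e, t]
    roi_signal = weights.T @ responses  # (n_roi_voxels, T)
    for j, (x, y, z) in enumerate(ids):
        signal[x, y, z, :] += roi_signal[j]
    return Volume4D(
        noise_vol.data + signal,
        voxel_size=noise_vol.voxel_size,
        tr=noise_vol.tr,
        affine=noise_vol.affine,
    )
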