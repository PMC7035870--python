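"""NIfTI reading/writing, noise-descriptor JSON and simulation config files."""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .datamodel import NoiseParameters, Volume4D
from .estimation import NoiseEstimate

__all__ = [
    "read_volume",
    "write_volume",
    "write_noise_descriptors",
    "read_noise_descriptors",
    "SimulationConfig",
    "load_config",
]


def read_volume(path, tr: float | None = None) -> Volume4D:
    """Load a 4-D NIfTI-1/2 file (optionally gzipped) as a :class:`Volume4D`.

    TR is taken from header pixdim[4]; if the header carries TR = 0 a
    ``tr`` override is required.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"could not read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(
            f"{path}: expected a 4-D functional volume, got {data.ndim}-D data"
        )
    zooms = img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if header_tr <= 0:
        if tr is None:
            warnings.warn(
                f"{path}: header pixdim[4] (TR) is {header_tr}; pass tr= explicitly",
                stacklevel=2,
            )
            raise ValueError(f"{path}: TR missing from header; a --tr value is required")
        header_tr = tr
    elif tr is not None:
        header_tr = tr
    return Volume4D(data, voxel_size=voxel_size, tr=header_tr, affine=img.affine)


def write_volume(vol: Volume4D, path) -> Path:
    """Write a :class:`Volume4D` as NIfTI-1 with TR in pixdim[4]."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(vol.data, affine=vol.affine)
    img.header.set_zooms(vol.voxel_size + (vol.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def write_noise_descriptors(estimate: NoiseEstimate | NoiseParameters, path) -> Path:
    """Flat key-value JSON, keys matching the NoiseParameters field names."""
    path = Path(path)
    path.write_text(json.dumps(estimate.to_dict(), indent=2) + "\n")
    return path


def read_noise_descriptors(path) -> dict:
    return json.loads(Path(path).read_text())


_NOISE_FIELDS = {f.name for f in dataclasses.fields(NoiseParameters)}


@dataclass
class SimulationConfig:
    """Everything needed to run one simulation.

    ``template`` is either the string ``"synthetic"`` (bundled ellipsoid
    default) or a path to a 4-D NIfTI scan whose temporal mean will be used.
    Noise parameters default to :class:`NoiseParameters` defaults; unknown
    config keys are rejected.
    """

    noise: NoiseParameters = field(default_factory=NoiseParameters)
    n_timepoints: int = 120
    tr: float = 1.5
    template: str = "synthetic"
    dims: tuple[int, int, int] = (24, 24, 16)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.5)
    mask_threshold: float = 0.5
    seed: int = 0
    fit: bool = True
    fit_thresh: float = 0.05
    max_iterations: int = 20
    onsets_file: str | None = None
    roi_file: str | None = None
    signal_magnitude: float | None = None
    signal_metric: str = "percent_signal_change"
    output_volume: str = "simulation.nii.gz"
    output_params: str = "simulation_params.json"


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)} - {"noise"}


def load_config(path) -> SimulationConfig:
    """Parse a YAML (or JSON: valid YAML) config file into a SimulationConfig."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    noise_kwargs = {}
    cfg_kwargs = {}
    for key, value in raw.items():
        if key in _NOISE_FIELDS:
            noise_kwargs[key] = value
        elif key in _CONFIG_FIELDS:
            if key in ("dims", "voxel_size"):
                value = tuple(value)
            cfg_kwargs[key] = value
        else:
            raise ValueError(f"unknown config key {key!r} in {path}")
    return SimulationConfig(noise=NoiseParameters(**noise_kwargs), **cfg_kwargs)


def read_onsets(path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column text file of (onset_s, duration_s); header line optional."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except (ValueError, IndexError):
            if rows:
                raise ValueError(f"malformed onset line in {path}: {line!r}")
            continue  # tolerate a single header line
    if not rows:
        raise ValueError(f"no onset rows found in {path}")
    arr = np.asarray(rows)
    return arr[:, 0], arr[:, 1]
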