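"""File formats and pipeline configuration.

Volumes travel as NIfTI with a JSON sidecar carrying acquisition metadata
(frame times, modality, echo time); cohort tables are CSV; configuration
is a strict JSON document (unknown keys rejected) hashed into every
output for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np

from .deconv import PerfusionMaps, ScalingConstants
from .errors import FormatError, ParameterError
from .lesion import Thresholds
from .signal import DSC_MRI, MODALITIES, PerfusionSeries

SIDE_CAR_REQUIRED = ("frame_times", "modality")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run depends on, serializable to JSON."""

    thresholds: Thresholds = field(default_factory=Thresholds)
    constants: ScalingConstants = field(default_factory=ScalingConstants)
    threshold_frac: float = 0.10
    circulant: bool = True
    fwhm_mm: Optional[float] = None  # None -> modality default
    motion_correction: bool = True
    core_requires_hypoperfusion: bool = True
    aif_top_k: int = 5
    fit_aif_gamma: bool = False
    seed: int = 0
    output_dir: Optional[str] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in d and not isinstance(d["thresholds"], Thresholds):
            t = dict(d["thresholds"])
            extra = set(t) - {f.name for f in dataclasses.fields(Thresholds)}
            if extra:
                raise FormatError(f"unknown threshold keys: {sorted(extra)}")
            d["thresholds"] = Thresholds(**t)
        if "constants" in d and not isinstance(d["constants"], ScalingConstants):
            c = dict(d["constants"])
            extra = set(c) - {f.name for f in dataclasses.fields(ScalingConstants)}
            if extra:
                raise FormatError(f"unknown constants keys: {sorted(extra)}")
            d["constants"] = ScalingConstants(**c)
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        try:
            return cls.from_dict(json.loads(text))
        except json.JSONDecodeError as exc:
            raise FormatError(f"config is not valid JSON: {exc}") from exc

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _affine(voxel_size) -> np.ndarray:
    return np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])


def read_series(path, sidecar_path) -> PerfusionSeries:
    """Load a 4D NIfTI plus its JSON sidecar into a PerfusionSeries."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"expected a 4D series; {path} is {data.ndim}D")
    try:
        sidecar = json.loads(Path(sidecar_path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar is not valid JSON: {exc}") from exc
    for key in SIDE_CAR_REQUIRED:
        if key not in sidecar:
            raise FormatError(f"sidecar missing required field '{key}'")
    modality = sidecar["modality"]
    if modality not in MODALITIES:
        raise FormatError(f"sidecar modality must be one of {MODALITIES}; got {modality!r}")
    if modality == DSC_MRI and "echo_time" not in sidecar:
        raise FormatError("sidecar missing required field 'echo_time' for DSC-MRI")
    frame_times = np.asarray(sidecar["frame_times"], dtype=float)
    if frame_times.size != data.shape[3]:
        raise FormatError(
            f"sidecar frame_times has {frame_times.size} entries but the series "
            f"has {data.shape[3]} frames"
        )
    voxel_size = sidecar.get("voxel_size")
    if voxel_size is None:
        voxel_size = [float(z) for z in img.header.get_zooms()[:3]]
    try:
        return PerfusionSeries(
            data=data,
            voxel_size=tuple(voxel_size),
            frame_times=frame_times,
            modality=modality,
            echo_time=sidecar.get("echo_time"),
        )
    except ParameterError as exc:
        raise FormatError(str(exc)) from exc


def write_series(series: PerfusionSeries, path, sidecar_path) -> None:
    nib.save(
        nib.Nifti1Image(series.data.astype(np.float32), _affine(series.voxel_size)),
        str(path),
    )
    sidecar = {
        "frame_times": series.frame_times.tolist(),
        "modality": series.modality,
        "voxel_size": list(series.voxel_size),
    }
    if series.echo_time is not None:
        sidecar["echo_time"] = series.echo_time
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def read_volume(path) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    """Load a 3D NIfTI volume; returns (data, voxel_size_mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D volume; {path} is {data.ndim}D")
    return data, tuple(float(z) for z in img.header.get_zooms()[:3])


def write_volume(data: np.ndarray, voxel_size, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size)), str(path))


def write_maps(maps: PerfusionMaps, voxel_size, outdir) -> None:
    """One NIfTI per perfusion parameter, sharing the input grid."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, vol in [
        ("rcbf", maps.rcbf), ("rcbv", maps.rcbv),
        ("mtt", maps.mtt), ("tmax", maps.tmax),
        ("brain_mask", maps.brain_mask.astype(np.uint8)),
    ]:
        write_volume(vol, voxel_size, outdir / f"{name}.nii.gz")
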