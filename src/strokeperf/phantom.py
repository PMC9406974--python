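"""Synthetic 4D perfusion phantoms with known ground truth.

A phantom is a head-sized grid holding an ellipsoidal "brain" whose voxel
time-curves follow gamma-variate-AIF (convolved with) exponential-residue
kinetics. A core lesion (low CBF, low ADC) and a surrounding penumbra
(delayed tracer arrival) are planted at known locations, together with a
small arterial voxel plug carrying the pure AIF, so that every downstream
stage — masking, AIF detection, deconvolution, segmentation, triage — can
be validated against exact ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .deconv import PerfusionMaps, ScalingConstants
from .errors import DimensionError, GeometryError, ParameterError
from .kinetics import GammaVariateParams, gamma_variate_curve
from .signal import CTP, DSC_MRI, MODALITIES, PerfusionSeries

__all__ = [
    "GammaVariateParams",
    "gamma_variate_curve",
    "Ellipsoid",
    "PhantomSpec",
    "PhantomDataset",
    "synthesize_tissue_curve",
    "make_phantom",
    "make_adc_phantom",
    "default_phantom_spec",
    "write_phantom",
]

#: ADC threshold separating core from viable tissue, mm^2/s.
ADC_CORE_LIMIT = 620e-6

#: CT number assigned to the synthetic skull shell (HU).
_SKULL_HU = 1100.0


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid given by a center voxel and semi-axes in mm."""

    center: Tuple[float, float, float]
    semi_axes_mm: Tuple[float, float, float]

    def __post_init__(self):
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ParameterError(f"semi-axes must be positive; got {self.semi_axes_mm}")

    def mask(self, grid_shape, voxel_size, scale: float = 1.0) -> np.ndarray:
        """Rasterize (voxel centers inside the ellipsoid)."""
        axes = [np.arange(n) for n in grid_shape]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        q = np.zeros(grid_shape)
        for coord, c, v, a in zip(
            (xx, yy, zz), self.center, voxel_size, self.semi_axes_mm
        ):
            q = q + ((coord - c) * v / (a * scale)) ** 2
        return q <= 1.0

    def check_inside(self, grid_shape, voxel_size, name: str, margin: float = 0.0):
        for c, a, v, n in zip(self.center, self.semi_axes_mm, voxel_size, grid_shape):
            if c - (a + margin) / v < 0 or c + (a + margin) / v > n - 1:
                raise GeometryError(
                    f"{name} ellipsoid extends outside the grid "
                    f"(center {self.center}, semi-axes {self.semi_axes_mm} mm)"
                )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic perfusion dataset.

    All ground-truth tissue parameters are per region: normal tissue gets
    (``tissue_cbf_normal``, ``tissue_mtt_normal``, delay 0); the penumbra
    ellipsoid adds an arrival delay; the core ellipsoid (a subset of the
    penumbra) additionally drops CBF to ``cbf_core`` and ADC to
    ``adc_core``.
    """

    grid_shape: Tuple[int, int, int] = (64, 64, 16)
    voxel_size: Tuple[float, float, float] = (3.0, 3.0, 5.0)
    n_frames: int = 40
    dt: float = 1.5
    aif: GammaVariateParams = GammaVariateParams(amplitude=10.0, t0=8.0, alpha=3.0, beta=1.5)
    tissue_cbf_normal: float = 60.0  # mL/100 g/min
    tissue_mtt_normal: float = 4.0  # s
    core_region: Ellipsoid = Ellipsoid((32.0, 26.0, 8.0), (15.0, 15.0, 12.0))
    cbf_core: float = 15.0
    penumbra_region: Ellipsoid = Ellipsoid((32.0, 28.0, 8.0), (27.0, 27.0, 20.0))
    delay_penumbra: float = 9.0  # s
    adc_normal: float = 800e-6  # mm^2/s
    adc_core: float = 450e-6
    noise_sd: float = 0.0  # signal units
    adc_noise_sd: float = 0.0
    modality: str = CTP
    seed: int = 0
    brain_region: Optional[Ellipsoid] = None
    aif_center: Optional[Tuple[int, int, int]] = None
    baseline_signal: Optional[float] = None
    echo_time: float = 0.03  # s, DSC-MRI only
    constants: ScalingConstants = field(default_factory=ScalingConstants)

    def __post_init__(self):
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if self.noise_sd < 0 or self.adc_noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.modality not in MODALITIES:
            raise ParameterError(f"modality must be one of {MODALITIES}")
        if self.cbf_core >= self.tissue_cbf_normal:
            raise ParameterError("cbf_core must be below tissue_cbf_normal")
        if not (self.adc_core < ADC_CORE_LIMIT <= self.adc_normal):
            raise ParameterError(
                f"require adc_core < {ADC_CORE_LIMIT} <= adc_normal; "
                f"got {self.adc_core}, {self.adc_normal}"
            )

    # -- derived geometry -------------------------------------------------
    @property
    def brain(self) -> Ellipsoid:
        if self.brain_region is not None:
            return self.brain_region
        center = tuple((n - 1) / 2.0 for n in self.grid_shape)
        semi = tuple(0.42 * (n - 1) * v for n, v in zip(self.grid_shape, self.voxel_size))
        return Ellipsoid(center, semi)

    @property
    def aif_voxel(self) -> Tuple[int, int, int]:
        if self.aif_center is not None:
            return tuple(int(c) for c in self.aif_center)
        bc = self.brain.center
        return (int(round(bc[0])), int(round(bc[1] - 0.5 * self.brain.semi_axes_mm[1] / self.voxel_size[1])), int(round(bc[2])))

    @property
    def baseline(self) -> float:
        if self.baseline_signal is not None:
            return self.baseline_signal
        return 40.0 if self.modality == CTP else 100.0

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown phantom spec keys: {sorted(unknown)}")
        for key in ("core_region", "penumbra_region", "brain_region"):
            if d.get(key) is not None and not isinstance(d[key], Ellipsoid):
                e = d[key]
                d[key] = Ellipsoid(tuple(e["center"]), tuple(e["semi_axes_mm"]))
        if d.get("aif") is not None and not isinstance(d["aif"], GammaVariateParams):
            d["aif"] = GammaVariateParams(**d["aif"])
        if d.get("constants") is not None and not isinstance(d["constants"], ScalingConstants):
            d["constants"] = ScalingConstants(**d["constants"])
        for key in ("grid_shape", "voxel_size", "aif_center"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PhantomDataset:
    """A generated phantom: the 4D series plus all ground truth."""

    series: PerfusionSeries
    truth_maps: PerfusionMaps
    truth_core_mask: np.ndarray
    truth_penumbra_mask: np.ndarray
    truth_adc: Optional[np.ndarray]
    brain_mask: np.ndarray
    aif_voxels: list
    manifest: PhantomSpec

    def __post_init__(self):
        shape = self.series.grid_shape
        for vol in (self.truth_core_mask, self.truth_penumbra_mask, self.brain_mask):
            if vol.shape != shape:
                raise DimensionError("phantom truth volume shape mismatch")
        if np.any(self.truth_core_mask & ~self.truth_penumbra_mask):
            raise GeometryError("truth core must be a subset of truth penumbra")


def _residue_vector(mtt: float, dt: float, n: int) -> np.ndarray:
    """Discrete exponential residue preserving peak (=1) and area (=mtt).

    Plain sampling of exp(-t/MTT) on a coarse grid biases either the peak
    (flow) or the area (flow*MTT) by O(dt/MTT). This vector keeps sample 0
    at the true peak and rescales the tail so the rectangle-rule area is
    exactly MTT, which makes CBF, CBV and MTT simultaneously recoverable
    from the discrete system.
    """
    x = dt / mtt
    r = np.exp(-np.arange(n) * x)
    r[1:] *= (1.0 / x - 1.0) * (np.exp(x) - 1.0)
    return r


def synthesize_tissue_curve(
    aif_curve: np.ndarray,
    cbf: float,
    mtt: float,
    delay: float,
    dt: float,
    constants: ScalingConstants = ScalingConstants(),
) -> np.ndarray:
    """Forward-model a tissue concentration curve ct(t).

    Discrete convolution (rectangle rule, step ``dt``) of the delayed AIF
    with the flow-scaled exponential residue. The flow scale inverts the
    map equations, so the generating CBF/CBV/MTT are exactly what the map
    stage recovers from noiseless data.
    """
    aif_curve = np.asarray(aif_curve, dtype=float)
    if aif_curve.ndim != 1:
        raise DimensionError("aif_curve must be 1D")
    if cbf < 0:
        raise ParameterError("cbf must be >= 0")
    if mtt <= 0:
        raise ParameterError("mtt must be > 0")
    if delay < 0:
        raise ParameterError("delay must be >= 0")
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    n = aif_curve.size
    if cbf == 0:
        return np.zeros(n)
    shift = int(round(delay / dt))
    ca = np.zeros(n)
    ca[shift:] = aif_curve[: n - shift] if shift > 0 else aif_curve
    # g inverts rCBF = 6000 * (k_av/rho) * hematocrit_factor * max(residue)
    g = cbf * constants.rho / (6000.0 * constants.k_av * constants.hematocrit_factor)
    r = g * _residue_vector(mtt, dt, n)
    return dt * np.convolve(ca, r)[:n]


def make_adc_phantom(spec: PhantomSpec) -> np.ndarray:
    """ADC volume (mm^2/s): ``adc_core`` in the core, ``adc_normal`` in the
    rest of the brain, 0 outside; optional seeded Gaussian noise."""
    brain = spec.brain.mask(spec.grid_shape, spec.voxel_size)
    core = spec.core_region.mask(spec.grid_shape, spec.voxel_size) & brain
    adc = np.where(brain, spec.adc_normal, 0.0)
    adc[core] = spec.adc_core
    if spec.adc_noise_sd > 0:
        rng = np.random.default_rng([spec.seed, 1])
        adc = adc + rng.normal(0.0, spec.adc_noise_sd, adc.shape) * brain
    return adc


def make_phantom(spec: PhantomSpec) -> PhantomDataset:
    """Generate the full phantom dataset from a spec. Seeded, deterministic."""
    spec.brain.check_inside(spec.grid_shape, spec.voxel_size, "brain")
    spec.core_region.check_inside(spec.grid_shape, spec.voxel_size, "core")
    spec.penumbra_region.check_inside(spec.grid_shape, spec.voxel_size, "penumbra")

    brain = spec.brain.mask(spec.grid_shape, spec.voxel_size)
    core = spec.core_region.mask(spec.grid_shape, spec.voxel_size) & brain
    penumbra = spec.penumbra_region.mask(spec.grid_shape, spec.voxel_size) & brain
    if np.any(core & ~penumbra):
        raise GeometryError("core_region must be contained in penumbra_region")

    times = spec.frame_times
    ca = gamma_variate_curve(spec.aif, times)
    realized_delay = round(spec.delay_penumbra / spec.dt) * spec.dt

    classes = [
        (brain & ~penumbra, spec.tissue_cbf_normal, 0.0),
        (penumbra & ~core, spec.tissue_cbf_normal, spec.delay_penumbra),
        (core, spec.cbf_core, spec.delay_penumbra),
    ]
    conc = np.zeros(spec.grid_shape + (spec.n_frames,))
    for mask, cbf, delay in classes:
        if mask.any():
            conc[mask] = synthesize_tissue_curve(
                ca, cbf, spec.tissue_mtt_normal, delay, spec.dt, spec.constants
            )

    # 5-voxel arterial plug (in-plane cross) carrying the pure AIF
    ax, ay, az = spec.aif_voxel
    plug = [(ax, ay, az), (ax + 1, ay, az), (ax - 1, ay, az), (ax, ay + 1, az), (ax, ay - 1, az)]
    plug = [(x, y, z) for x, y, z in plug if brain[x, y, z]]
    if not plug:
        raise GeometryError("arterial plug lies outside the brain region")
    for v in plug:
        conc[v] = ca

    if spec.modality == CTP:
        signal = np.where(brain[..., None], spec.baseline + conc, 0.0)
        shell = spec.brain.mask(spec.grid_shape, spec.voxel_size, scale=1.12) & ~spec.brain.mask(
            spec.grid_shape, spec.voxel_size, scale=1.04
        )
        signal[shell] = _SKULL_HU
    else:
        signal = np.where(
            brain[..., None],
            spec.baseline * np.exp(-spec.echo_time * conc),
            0.0,
        )

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        signal = signal + rng.normal(0.0, spec.noise_sd, signal.shape)

    series = PerfusionSeries(
        data=signal,
        voxel_size=spec.voxel_size,
        frame_times=times,
        modality=spec.modality,
        echo_time=spec.echo_time if spec.modality == DSC_MRI else None,
    )

    rcbf = np.where(brain, spec.tissue_cbf_normal, 0.0)
    rcbf[core] = spec.cbf_core
    mtt = np.where(brain, spec.tissue_mtt_normal, 0.0)
    rcbv = rcbf * mtt / 60.0
    tmax = np.where(penumbra, realized_delay, 0.0)
    truth_maps = PerfusionMaps(rcbf=rcbf, rcbv=rcbv, mtt=mtt, tmax=tmax, brain_mask=brain)

    return PhantomDataset(
        series=series,
        truth_maps=truth_maps,
        truth_core_mask=core,
        truth_penumbra_mask=penumbra,
        truth_adc=make_adc_phantom(spec),
        brain_mask=brain,
        aif_voxels=plug,
        manifest=spec,
    )


def default_phantom_spec(**overrides) -> PhantomSpec:
    """Spec with testing-friendly defaults; keyword overrides applied on top."""
    return dataclasses.replace(PhantomSpec(), **overrides)


def truth_volumes_ml(dataset: PhantomDataset) -> dict:
    vv = float(np.prod(dataset.series.voxel_size)) / 1000.0
    return {
        "core_ml": float(dataset.truth_core_mask.sum() * vv),
        "penumbra_incl_core_ml": float(dataset.truth_penumbra_mask.sum() * vv),
        "penumbra_excl_core_ml": float(
            (dataset.truth_penumbra_mask & ~dataset.truth_core_mask).sum() * vv
        ),
    }


def write_phantom(dataset: PhantomDataset, outdir) -> None:
    """Write the series, truth volumes (NIfTI) and a JSON manifest."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vs = dataset.series.voxel_size
    affine = np.diag([vs[0], vs[1], vs[2], 1.0])

    def save(arr, name):
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), outdir / name)

    save(dataset.series.data, "series.nii.gz")
    save(dataset.truth_maps.rcbf, "truth_rcbf.nii.gz")
    save(dataset.truth_maps.rcbv, "truth_rcbv.nii.gz")
    save(dataset.truth_maps.mtt, "truth_mtt.nii.gz")
    save(dataset.truth_maps.tmax, "truth_tmax.nii.gz")
    save(dataset.truth_core_mask.astype(np.uint8), "truth_core.nii.gz")
    save(dataset.truth_penumbra_mask.astype(np.uint8), "truth_penumbra.nii.gz")
    save(dataset.brain_mask.astype(np.uint8), "brain_mask.nii.gz")
    if dataset.truth_adc is not None:
        save(dataset.truth_adc, "truth_adc.nii.gz")

    sidecar = {
        "frame_times": dataset.series.frame_times.tolist(),
        "modality": dataset.series.modality,
        "voxel_size": list(vs),
    }
    if dataset.series.echo_time is not None:
        sidecar["echo_time"] = dataset.series.echo_time
    (outdir / "series.json").write_text(json.dumps(sidecar, indent=2))

    manifest = {
        "spec": dataset.manifest.to_dict(),
        "aif_voxels": [list(v) for v in dataset.aif_voxels],
        "truth_volumes_ml": truth_volumes_ml(dataset),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
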