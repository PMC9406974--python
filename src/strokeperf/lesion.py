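"""Ischemic core / penumbra segmentation, mismatch profiles and triage.

Default thresholds: core is rCBF below 30% of the normally-perfused
reference (CTP) or ADC below 620e-6 mm^2/s (MRI); penumbra is Tmax above
6 s excluding core. Thrombectomy eligibility follows the DEFUSE3 profile:
core volume < 70 mL, mismatch ratio > 1.8 and mismatch volume > 15 mL.
All inequalities are strict, exactly as stated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import FrozenSet, Tuple

import numpy as np
from skimage.measure import label

from .deconv import PerfusionMaps
from .errors import ParameterError, SegmentationError, UnitError

#: DEFUSE3 eligibility cutoffs.
DEFUSE3_ICV_MAX_ML = 70.0
DEFUSE3_RATIO_MIN = 1.8
DEFUSE3_MISMATCH_MIN_ML = 15.0


@dataclass(frozen=True)
class Thresholds:
    """Lesion-definition thresholds; every field is user-definable."""

    rcbf_frac: float = 0.30
    adc_max: float = 620e-6  # mm^2/s
    tmax_min: float = 6.0  # s
    min_cluster_ml: float = 1.0
    #: Tmax (s) below which tissue counts as normally perfused when
    #: building the rCBF reference.
    reference_tmax_max: float = 4.0

    def __post_init__(self):
        if min(self.rcbf_frac, self.adc_max, self.tmax_min, self.min_cluster_ml) <= 0:
            raise ParameterError("all thresholds must be positive")
        if self.rcbf_frac >= 1:
            raise ParameterError("rcbf_frac must be < 1")


@dataclass(frozen=True)
class VolumetricResult:
    """Per-case lesion volumes and mismatch profile."""

    icv: float  # mL
    pv: float  # mL
    mismatch_volume: float = field(default=None)  # type: ignore[assignment]
    mismatch_ratio: float = field(default=None)  # type: ignore[assignment]
    modality: str = "CTP"

    def __post_init__(self):
        if self.icv < 0 or self.pv < 0:
            raise ParameterError("volumes must be >= 0")
        if self.mismatch_volume is None:
            object.__setattr__(self, "mismatch_volume", self.pv - self.icv)
        if self.mismatch_ratio is None:
            if self.icv > 0:
                ratio = self.pv / self.icv
            elif self.pv > 0:
                ratio = math.inf
            else:
                ratio = 0.0
            object.__setattr__(self, "mismatch_ratio", ratio)


@dataclass(frozen=True)
class TriageDecision:
    """Outcome of the DEFUSE3 eligibility check."""

    eligible: bool
    failed_criteria: FrozenSet[str]

    def __post_init__(self):
        if self.eligible != (len(self.failed_criteria) == 0):
            raise ParameterError("eligible must match empty failed_criteria")


def _remove_small_clusters(mask: np.ndarray, voxel_size, min_ml: float) -> np.ndarray:
    """Drop 26-connected components smaller than ``min_ml`` millilitres."""
    if not mask.any() or min_ml <= 0:
        return mask
    voxel_ml = float(np.prod(voxel_size)) / 1000.0
    min_vox = min_ml / voxel_ml
    labels = label(mask, connectivity=3)
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_vox)
    keep = keep[keep != 0]
    return np.isin(labels, keep)


def segment_core_ctp(
    maps: PerfusionMaps,
    thresholds: Thresholds = Thresholds(),
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0),
    require_hypoperfusion: bool = True,
) -> np.ndarray:
    """CTP core: rCBF below ``rcbf_frac`` of the normal-tissue reference.

    The reference is the median rCBF over brain voxels with
    Tmax <= ``reference_tmax_max`` (falling back to the whole-brain median
    when no such tissue exists). By default core is additionally restricted
    to hypoperfused tissue (Tmax > ``tmax_min``).
    """
    brain = maps.brain_mask
    if not brain.any():
        raise SegmentationError("brain mask is empty")
    normal = brain & (maps.tmax <= thresholds.reference_tmax_max)
    ref_pool = maps.rcbf[normal] if normal.any() else maps.rcbf[brain]
    if ref_pool.size == 0:
        raise SegmentationError("reference tissue set is empty")
    reference = float(np.median(ref_pool))
    if reference <= 0:
        raise SegmentationError("reference CBF is non-positive")
    core = brain & (maps.rcbf < thresholds.rcbf_frac * reference)
    if require_hypoperfusion:
        core &= maps.tmax > thresholds.tmax_min
    return _remove_small_clusters(core, voxel_size, thresholds.min_cluster_ml)


def segment_core_adc(
    adc: np.ndarray,
    brain_mask: np.ndarray,
    thresholds: Thresholds = Thresholds(),
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """MRI core: brain voxels with ADC strictly below ``adc_max`` (mm^2/s)."""
    adc = np.asarray(adc, dtype=float)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if adc.shape != brain_mask.shape:
        raise ParameterError("adc and brain_mask shapes differ")
    if brain_mask.any():
        med = float(np.median(adc[brain_mask]))
        if med > 0.1:
            raise UnitError(
                f"median brain ADC {med:g} looks mis-scaled; expected mm^2/s "
                "(order 1e-3 or below)"
            )
    core = brain_mask & (adc < thresholds.adc_max)
    return _remove_small_clusters(core, voxel_size, thresholds.min_cluster_ml)


def segment_penumbra(
    maps: PerfusionMaps,
    core: np.ndarray,
    thresholds: Thresholds = Thresholds(),
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Penumbra: hypoperfused tissue (Tmax strictly above ``tmax_min``)
    minus the core."""
    hypo = maps.brain_mask & (maps.tmax > thresholds.tmax_min)
    hypo = _remove_small_clusters(hypo, voxel_size, thresholds.min_cluster_ml)
    return hypo & ~np.asarray(core, dtype=bool)


def mask_volume(mask: np.ndarray, voxel_size) -> float:
    """Volume of a binary mask in millilitres."""
    if any(v <= 0 for v in voxel_size):
        raise ParameterError("voxel_size must be positive")
    return float(np.count_nonzero(mask) * np.prod(voxel_size) / 1000.0)


def mismatch_profile(icv: float, pv: float, modality: str = "CTP") -> VolumetricResult:
    """Mismatch volume (pv - icv) and ratio (pv / icv) from the two volumes."""
    if icv < 0 or pv < 0:
        raise ParameterError("volumes must be >= 0")
    return VolumetricResult(icv=icv, pv=pv, modality=modality)


def triage_defuse3(result: VolumetricResult) -> TriageDecision:
    """Apply the DEFUSE3 imaging eligibility profile."""
    failed = set()
    if not result.icv < DEFUSE3_ICV_MAX_ML:
        failed.add("icv")
    if not result.mismatch_ratio > DEFUSE3_RATIO_MIN:
        failed.add("ratio")
    if not result.mismatch_volume > DEFUSE3_MISMATCH_MIN_ML:
        failed.add("volume")
    return TriageDecision(eligible=not failed, failed_criteria=frozenset(failed))
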