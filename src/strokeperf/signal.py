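"""Preprocessing of 4D perfusion series and signal-to-concentration conversion.

Covers the standard preparation chain: rigid (translation-only) motion
correction, spatial smoothing, brain masking, and conversion of the raw
signal to contrast-agent concentration — subtraction of the pre-bolus
baseline for CT, log-ratio for spin-echo MR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.measure import label
from skimage.registration import phase_cross_correlation

from .errors import (
    BolusDetectionError,
    DimensionError,
    MaskingError,
    ParameterError,
)

log = logging.getLogger(__name__)

CTP = "CTP"
DSC_MRI = "DSC-MRI"
MODALITIES = (CTP, DSC_MRI)

#: FWHM -> Gaussian sigma conversion factor, 2*sqrt(2*ln 2)
_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Default smoothing kernels (mm) per modality.
DEFAULT_FWHM_MM = {CTP: 4.0, DSC_MRI: 0.0}

# Intensity windows for the time-mean volume used in brain masking.
_CTP_BRAIN_WINDOW_HU = (10.0, 300.0)
_MR_BRAIN_REL_THRESHOLD = 0.2


@dataclass
class PerfusionSeries:
    """A 4D perfusion acquisition with spatial and temporal metadata.

    Parameters
    ----------
    data
        Signal array with axes ``(x, y, z, t)``. Hounsfield units for CTP,
        arbitrary signal units for DSC-MRI.
    voxel_size
        Voxel edge lengths in mm, one per spatial axis.
    frame_times
        Acquisition time of each frame in seconds, strictly increasing.
    modality
        ``"CTP"`` or ``"DSC-MRI"``.
    echo_time
        Echo time TE in seconds; required for DSC-MRI.
    """

    data: np.ndarray
    voxel_size: Tuple[float, float, float]
    frame_times: np.ndarray
    modality: str = CTP
    echo_time: Optional[float] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.data.ndim != 4:
            raise DimensionError(
                f"series data must be 4D (x, y, z, t); got {self.data.ndim}D"
            )
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ParameterError(f"voxel_size must be 3 positive mm values; got {self.voxel_size}")
        if self.frame_times.ndim != 1 or self.frame_times.size != self.data.shape[3]:
            raise DimensionError(
                f"frame_times length {self.frame_times.size} does not match "
                f"frame count {self.data.shape[3]}"
            )
        if self.frame_times.size > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ParameterError("frame_times must be strictly increasing")
        if self.modality not in MODALITIES:
            raise ParameterError(f"modality must be one of {MODALITIES}; got {self.modality!r}")
        if self.modality == DSC_MRI and (self.echo_time is None or self.echo_time <= 0):
            raise ParameterError("DSC-MRI series requires echo_time > 0 (seconds)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def dt(self) -> float:
        """Smallest frame spacing in seconds."""
        if self.n_frames < 2:
            raise ParameterError("dt undefined for a single-frame series")
        return float(np.min(np.diff(self.frame_times)))


@dataclass
class ConcentrationSeries:
    """Voxelwise contrast-agent concentration over time.

    ``data`` is zero outside ``brain_mask``; ``baseline_window`` is the
    half-open frame range ``[start, stop)`` preceding bolus arrival.
    """

    data: np.ndarray
    baseline_window: Tuple[int, int]
    brain_mask: np.ndarray
    frame_times: np.ndarray
    voxel_size: Tuple[float, float, float]
    n_clipped: int = 0
    n_nonpositive: int = field(default=0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.data.ndim != 4:
            raise DimensionError("concentration data must be 4D")
        if self.brain_mask.shape != self.data.shape[:3]:
            raise DimensionError("brain_mask shape does not match concentration grid")
        b0, b1 = self.baseline_window
        if not (0 <= b0 < b1 <= self.data.shape[3]):
            raise ParameterError(f"invalid baseline_window {self.baseline_window}")

    @property
    def dt(self) -> float:
        return float(np.min(np.diff(self.frame_times)))


def compute_brain_mask(series: PerfusionSeries) -> np.ndarray:
    """Segment the brain on the time-mean volume.

    Modality-specific intensity windowing (soft-tissue HU window for CTP,
    relative threshold for MR) followed by largest-connected-component
    selection and hole filling. Deterministic.
    """
    if series.n_frames < 1:
        raise ParameterError("series has no frames")
    tmean = series.data.mean(axis=3)
    if series.modality == CTP:
        lo, hi = _CTP_BRAIN_WINDOW_HU
        raw = (tmean >= lo) & (tmean <= hi)
    else:
        peak = float(tmean.max())
        raw = tmean >= _MR_BRAIN_REL_THRESHOLD * peak if peak > 0 else np.zeros_like(tmean, bool)
    if not raw.any():
        raise MaskingError("brain masking produced an empty mask")
    labels = label(raw, connectivity=3)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        raise MaskingError("brain masking produced an empty mask")
    return mask


def motion_correct(series: PerfusionSeries) -> PerfusionSeries:
    """Rigidly align every frame to frame 0 by translation.

    The shift is estimated by cross-correlation with subvoxel refinement
    and applied with linear interpolation. Frame times are untouched.
    Constant (information-free) frames are passed through with a warning.
    """
    if series.n_frames < 2:
        raise ParameterError("motion correction requires at least 2 frames")
    ref = series.data[..., 0]
    if np.ptp(ref) == 0:
        warnings.warn("reference frame is constant; motion correction skipped")
        return series
    out = np.empty_like(series.data)
    out[..., 0] = ref
    for t in range(1, series.n_frames):
        frame = series.data[..., t]
        if np.ptp(frame) == 0:
            warnings.warn(f"frame {t} is constant; left unaligned")
            out[..., t] = frame
            continue
        shift, _, _ = phase_cross_correlation(ref, frame, upsample_factor=10)
        if np.max(np.abs(shift)) < 1e-9:
            out[..., t] = frame
        else:
            out[..., t] = ndimage.shift(frame, shift, order=1, mode="nearest")
    return replace(series, data=out)


def smooth(series: PerfusionSeries, fwhm_mm: float) -> PerfusionSeries:
    """Per-frame Gaussian spatial smoothing with the kernel given in mm FWHM."""
    if fwhm_mm < 0:
        raise ParameterError(f"fwhm_mm must be >= 0; got {fwhm_mm}")
    if fwhm_mm == 0:
        return series
    sigma_vox = [fwhm_mm / _FWHM_TO_SIGMA / v for v in series.voxel_size]
    out = ndimage.gaussian_filter(series.data, sigma=sigma_vox + [0.0])
    return replace(series, data=out)


def detect_baseline_window(
    series: PerfusionSeries, brain_mask: np.ndarray, min_frames: int = 3
) -> Tuple[int, int]:
    """Locate the pre-bolus baseline as ``[0, arrival)``.

    Arrival is the first frame where the mean brain signal departs from the
    early-frame mean by more than 3 standard deviations of the early frames
    (with a small floor so noiseless data still triggers). At least
    ``min_frames`` frames are always kept.
    """
    if series.n_frames < min_frames + 1:
        raise BolusDetectionError(
            f"need more than {min_frames} frames to detect bolus arrival"
        )
    m = series.data[brain_mask].mean(axis=0)
    b_mean = m[:min_frames].mean()
    b_sd = m[:min_frames].std()
    span = float(np.ptp(m))
    sd_eff = max(b_sd, 1e-6 * max(span, 1.0))
    exceeds = np.abs(m - b_mean) > 3.0 * sd_eff
    exceeds[:min_frames] = False
    idx = np.flatnonzero(exceeds)
    if idx.size == 0:
        raise BolusDetectionError("no bolus arrival detected in mean brain signal")
    return (0, int(idx[0]))


def to_concentration(
    series: PerfusionSeries,
    brain_mask: np.ndarray,
    baseline_window: Optional[Tuple[int, int]] = None,
) -> ConcentrationSeries:
    """Convert signal to contrast concentration inside the brain mask.

    CTP: ``c = s - mean(baseline)``. DSC-MRI: ``c = -ln(s / s0) / TE``.
    Negative and non-finite concentrations are clipped to 0 (counts kept on
    the result for auditing); voxels outside the mask are 0.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ParameterError("brain_mask is empty")
    if baseline_window is None:
        baseline_window = detect_baseline_window(series, brain_mask)
    b0, b1 = baseline_window
    s = series.data
    s0 = s[..., b0:b1].mean(axis=3)

    n_nonpositive = 0
    if series.modality == CTP:
        conc = s - s0[..., None]
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = s / s0[..., None]
            n_nonpositive = int(np.count_nonzero((s <= 0) & brain_mask[..., None]))
            conc = -np.log(ratio) / series.echo_time
        if n_nonpositive:
            log.warning("%d non-positive MR signal samples inside mask clipped", n_nonpositive)
    conc[~np.isfinite(conc)] = 0.0
    n_clipped = int(np.count_nonzero((conc < 0) & brain_mask[..., None]))
    np.clip(conc, 0.0, None, out=conc)
    conc[~brain_mask] = 0.0
    return ConcentrationSeries(
        data=conc,
        baseline_window=(b0, b1),
        brain_mask=brain_mask,
        frame_times=series.frame_times,
        voxel_size=series.voxel_size,
        n_clipped=n_clipped,
        n_nonpositive=n_nonpositive,
    )
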