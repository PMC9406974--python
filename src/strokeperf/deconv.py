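"""Deconvolution of tissue curves by the AIF and perfusion-map computation.

The tissue curve is modelled as ``ct(t) = (ca * k)(t)`` where ``k`` is the
flow-scaled residue function. Deconvolution inverts the discrete
convolution with a truncated-SVD pseudo-inverse, either on the standard
lower-triangular Toeplitz system or (default) on a zero-padded
block-circulant system, which is insensitive to tracer-arrival delay.

Map scaling follows the conventional tracer-kinetic relations::

    rCBV = 100 * (k_av / rho) * (1 - h_sv) / (1 - h_lv) * integral(ct) / integral(ca)
    rCBF = 100 * 60 * (k_av / rho) * (1 - h_sv) / (1 - h_lv) * max(k)
    MTT  = 60 * rCBV / rCBF
    Tmax = argmax(k) * dt

The hematocrit ratio corrects for the different plasma fractions seen by
the large-vessel AIF and the capillary bed and is applied to both CBV and
CBF so that the central-volume identity holds in consistent units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.linalg import circulant, toeplitz

from .aif import AIF
from .errors import DeconvolutionError, DimensionError, MapError, ParameterError
from .signal import ConcentrationSeries


@dataclass(frozen=True)
class ScalingConstants:
    """Dimensional constants of the perfusion-map equations.

    ``k_av`` (dimensionless calibration), ``rho`` (brain density, g/mL),
    ``h_sv`` / ``h_lv`` (small- and large-vessel hematocrit fractions).
    """

    k_av: float = 1.0
    rho: float = 1.04
    h_sv: float = 0.25
    h_lv: float = 0.45

    def __post_init__(self):
        if not (0 <= self.h_sv < 1) or not (0 <= self.h_lv < 1):
            raise ParameterError("hematocrit fractions must be in [0, 1)")
        if self.rho <= 0:
            raise ParameterError("rho must be > 0")
        if self.k_av <= 0:
            raise ParameterError("k_av must be > 0")

    @property
    def hematocrit_factor(self) -> float:
        """(1 - h_sv) / (1 - h_lv)."""
        return (1.0 - self.h_sv) / (1.0 - self.h_lv)


@dataclass
class ResidueMap:
    """Voxelwise flow-scaled residue curves (units 1/s) on a uniform grid.

    ``data`` has shape ``(x, y, z, L)`` where ``L`` equals the frame count
    in standard mode and twice that in circulant mode; ``n_frames`` is the
    number of physically meaningful samples.
    """

    data: np.ndarray
    dt: float
    n_frames: int
    brain_mask: np.ndarray

    def __post_init__(self):
        if self.data.ndim != 4:
            raise DimensionError("residue data must be 4D")
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")


@dataclass
class PerfusionMaps:
    """The four perfusion parameter volumes plus the brain mask."""

    rcbf: np.ndarray  # mL/100 g/min
    rcbv: np.ndarray  # mL/100 g
    mtt: np.ndarray  # s
    tmax: np.ndarray  # s
    brain_mask: np.ndarray

    def __post_init__(self):
        shapes = {m.shape for m in (self.rcbf, self.rcbv, self.mtt, self.tmax)}
        if len(shapes) != 1 or self.brain_mask.shape not in shapes:
            raise DimensionError("perfusion map volumes must share one shape")


def _check_uniform(times: np.ndarray, rtol: float = 1e-6) -> float:
    diffs = np.diff(times)
    dt = float(diffs.min())
    if not np.allclose(diffs, dt, rtol=rtol, atol=rtol * dt):
        raise ParameterError(
            "AIF is not on a uniform time grid; resample before building the matrix"
        )
    return dt


def build_convolution_matrix(aif: AIF, dt: float, circulant_mode: bool = True) -> np.ndarray:
    """Discrete convolution operator of the AIF with step ``dt``.

    Standard mode returns the N x N lower-triangular Toeplitz matrix with
    first column ``dt * ca``; circulant mode returns the 2N x 2N circulant
    matrix of the zero-padded AIF (delay-insensitive form).
    """
    _check_uniform(aif.times)
    ca = aif.concentration
    n = ca.size
    if circulant_mode:
        first_col = np.concatenate([dt * ca, np.zeros(n)])
        return circulant(first_col)
    return toeplitz(dt * ca, np.zeros(n))


def _truncated_pinv(a: np.ndarray, threshold_frac: float) -> np.ndarray:
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    s_inv = np.where(s >= threshold_frac * s[0], 1.0 / np.where(s > 0, s, 1.0), 0.0)
    return (vt.T * s_inv) @ u.T


def _resample_uniform(times: np.ndarray, values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Linear resampling to a uniform grid at the minimum frame spacing."""
    dt = float(np.min(np.diff(times)))
    n = int(np.floor((times[-1] - times[0]) / dt)) + 1
    grid = times[0] + dt * np.arange(n)
    flat = values.reshape(-1, times.size)
    out = np.empty((flat.shape[0], n))
    for i, row in enumerate(flat):
        out[i] = np.interp(grid, times, row)
    return grid, out.reshape(values.shape[:-1] + (n,))


def deconvolve(
    conc: ConcentrationSeries,
    aif: AIF,
    threshold_frac: float = 0.10,
    circulant_mode: bool = True,
) -> ResidueMap:
    """Recover the flow-scaled residue in every brain voxel.

    Truncated-SVD inversion keeping singular values at or above
    ``threshold_frac`` of the largest. In circulant mode both the AIF
    matrix and the tissue curves are zero-padded to length 2N.
    """
    if not (0 < threshold_frac <= 1):
        raise ParameterError(f"threshold_frac must be in (0, 1]; got {threshold_frac}")
    times = conc.frame_times
    diffs = np.diff(times)
    if np.allclose(diffs, diffs.min(), rtol=1e-6):
        grid = times
        ct = conc.data
        ca = aif.concentration
    else:
        grid, ct = _resample_uniform(times, conc.data)
        _, ca = _resample_uniform(aif.times, aif.concentration)
    dt = float(np.min(np.diff(grid)))
    if np.sum(ca) * dt <= 0:
        raise DeconvolutionError("AIF integral is zero; cannot deconvolve")
    n = ca.size
    aif_u = AIF(times=grid, concentration=ca, source_voxels=aif.source_voxels)
    a = build_convolution_matrix(aif_u, dt, circulant_mode=circulant_mode)
    a_inv = _truncated_pinv(a, threshold_frac)

    curves = ct[conc.brain_mask]  # (n_vox, N)
    if circulant_mode:
        curves = np.concatenate([curves, np.zeros_like(curves)], axis=1)
    residue_curves = curves @ a_inv.T
    out = np.zeros(conc.brain_mask.shape + (a.shape[0],))
    out[conc.brain_mask] = residue_curves
    return ResidueMap(data=out, dt=dt, n_frames=n, brain_mask=conc.brain_mask)


def compute_maps(
    residue: ResidueMap,
    conc: ConcentrationSeries,
    aif: AIF,
    constants: ScalingConstants = ScalingConstants(),
) -> PerfusionMaps:
    """Scale the deconvolution output into the four perfusion maps.

    Integrals use the rectangle rule with the uniform step ``dt``. The
    residue max/argmax is taken over the first ``n_frames`` samples (the
    circulant tail only carries wrap-around energy). MTT is set to 0 where
    CBF is 0; Tmax is an integer multiple of ``dt`` by construction.
    """
    mask = residue.brain_mask
    r = residue.data[..., : residue.n_frames]
    if not np.all(np.isfinite(r[mask])):
        bad = np.argwhere(mask & ~np.isfinite(r).all(axis=-1))
        raise MapError(f"non-finite residue inside brain mask at voxels {bad[:10].tolist()}")
    dt = residue.dt
    scale = 100.0 * (constants.k_av / constants.rho) * constants.hematocrit_factor

    int_ct = conc.data.sum(axis=-1) * conc.dt
    int_ca = float(np.sum(aif.concentration) * aif.dt)
    if int_ca <= 0:
        raise DeconvolutionError("AIF integral is zero")

    rcbv = np.where(mask, scale * int_ct / int_ca, 0.0)
    rcbf = np.where(mask, 60.0 * scale * np.clip(r.max(axis=-1), 0.0, None), 0.0)
    np.clip(rcbv, 0.0, None, out=rcbv)
    with np.errstate(divide="ignore", invalid="ignore"):
        mtt = np.where(rcbf > 0, 60.0 * rcbv / rcbf, 0.0)
    tmax = np.where(mask, r.argmax(axis=-1) * dt, 0.0)
    return PerfusionMaps(rcbf=rcbf, rcbv=rcbv, mtt=mtt, tmax=tmax, brain_mask=mask)
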