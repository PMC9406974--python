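"""Automatic arterial input function determination.

An arterial voxel shows an early, tall, narrow bolus passage. Each brain
voxel is scored by equally weighted z-scores of peak height, earliness
(low first moment) and narrowness (low FWHM); the top-scoring voxels are
averaged into the AIF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .errors import AIFDetectionError, FitError, ParameterError
from .kinetics import GammaVariateParams, gamma_variate_curve
from .signal import ConcentrationSeries


@dataclass
class AIF:
    """Arterial concentration-time curve and its provenance."""

    times: np.ndarray
    concentration: np.ndarray
    source_voxels: List[Tuple[int, int, int]]
    fit: Optional[GammaVariateParams] = None
    fit_rmse: Optional[float] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.times.shape != self.concentration.shape:
            raise ParameterError("AIF times and concentration lengths differ")
        if np.any(self.concentration < 0):
            raise ParameterError("AIF concentration must be non-negative")
        if self.concentration.max(initial=0.0) <= 0:
            raise ParameterError("AIF peak must be positive")

    @property
    def dt(self) -> float:
        return float(np.min(np.diff(self.times)))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _curve_features(curves: np.ndarray, times: np.ndarray):
    """Peak, first moment (s) and FWHM (s) of each row of ``curves``."""
    peak = curves.max(axis=1)
    area = curves.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        first_moment = (curves * times[None, :]).sum(axis=1) / area
    dt = float(np.min(np.diff(times)))
    fwhm = (curves > 0.5 * peak[:, None]).sum(axis=1) * dt
    return peak, first_moment, fwhm


def detect_aif(conc: ConcentrationSeries, top_k: int = 5) -> AIF:
    """Select the ``top_k`` most arterial-looking voxels and average them.

    Deterministic: ties in the composite score are broken by lexicographic
    voxel coordinate.
    """
    if top_k < 1:
        raise ParameterError("top_k must be >= 1")
    if conc.data.shape[3] < 8:
        raise ParameterError("AIF detection requires at least 8 frames")
    coords = np.argwhere(conc.brain_mask)
    if coords.size == 0:
        raise AIFDetectionError("brain mask is empty")
    curves = conc.data[conc.brain_mask]  # (n_vox, T)
    times = conc.frame_times

    peak, first_moment, fwhm = _curve_features(curves, times)
    finite = (peak > 0) & np.isfinite(first_moment) & np.isfinite(fwhm)
    if int(finite.sum()) < top_k:
        raise AIFDetectionError(
            f"only {int(finite.sum())} voxels with finite AIF scores; need {top_k}"
        )
    cand_idx = np.flatnonzero(finite)
    score = (
        _zscore(peak[cand_idx])
        + _zscore(-first_moment[cand_idx])
        + _zscore(-fwhm[cand_idx])
    )
    cand_coords = coords[cand_idx]
    # sort by descending score, then lexicographic (x, y, z)
    order = np.lexsort(
        (cand_coords[:, 2], cand_coords[:, 1], cand_coords[:, 0], -score)
    )
    chosen = order[:top_k]
    ca = curves[cand_idx[chosen]].mean(axis=0)
    sources = [tuple(int(c) for c in cand_coords[i]) for i in chosen]
    return AIF(times=times, concentration=np.clip(ca, 0.0, None), source_voxels=sources)


def _gamma_model(t, amplitude, t0, alpha, beta):
    dt = t - t0
    out = np.zeros_like(t)
    pos = dt > 0
    out[pos] = amplitude * dt[pos] ** alpha * np.exp(-dt[pos] / beta)
    return out


def fit_gamma_variate(
    curve: np.ndarray, times: np.ndarray, peak_window_factor: float = 1.5
) -> Tuple[GammaVariateParams, float]:
    """Least-squares gamma-variate fit to the first bolus passage.

    Only samples up to ``peak_window_factor`` times the time-to-peak are
    used, which suppresses recirculation. Returns the fitted parameters and
    the RMSE of the fit over the window.
    """
    curve = np.asarray(curve, dtype=float)
    times = np.asarray(times, dtype=float)
    peak = curve.max(initial=0.0)
    if peak <= 0:
        raise FitError("curve has no positive peak; cannot fit gamma-variate")
    i_peak = int(np.argmax(curve))
    t_peak = times[i_peak]
    window = times <= peak_window_factor * t_peak
    if int(window.sum()) < 5:
        window = np.ones_like(times, dtype=bool)
    t_fit, c_fit = times[window], curve[window]

    above = np.flatnonzero(curve > 0.05 * peak)
    t0_guess = times[above[0] - 1] if above.size and above[0] > 0 else times[0] - 1e-3
    alpha0, beta0 = 3.0, max((t_peak - t0_guess) / 3.0, 1e-2)
    amp0 = peak / max(
        (t_peak - t0_guess) ** alpha0 * np.exp(-(t_peak - t0_guess) / beta0), 1e-12
    )
    try:
        popt, _ = curve_fit(
            _gamma_model,
            t_fit,
            c_fit,
            p0=[amp0, t0_guess, alpha0, beta0],
            bounds=([1e-12, -np.inf, 1e-6, 1e-6], [np.inf, t_peak, 50.0, 1e3]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"gamma-variate fit did not converge: {exc}") from exc
    params = GammaVariateParams(
        amplitude=float(popt[0]), t0=float(popt[1]),
        alpha=float(popt[2]), beta=float(popt[3]),
    )
    rmse = float(np.sqrt(np.mean((gamma_variate_curve(params, t_fit) - c_fit) ** 2)))
    return params, rmse
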