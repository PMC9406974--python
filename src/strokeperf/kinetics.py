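"""Gamma-variate bolus model shared by the phantom generator and AIF fitting."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError


@dataclass(frozen=True)
class GammaVariateParams:
    """Parameters of the gamma-variate bolus curve.

    ``c(t) = amplitude * (t - t0)**alpha * exp(-(t - t0) / beta)`` for
    ``t > t0`` and 0 before arrival. ``t0`` is the bolus-arrival time (s),
    ``alpha`` the shape and ``beta`` the scale (s); the curve peaks at
    ``t0 + alpha * beta``.
    """

    amplitude: float
    t0: float
    alpha: float
    beta: float

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ParameterError(f"amplitude must be > 0; got {self.amplitude}")
        if self.alpha <= 0 or self.beta <= 0:
            raise ParameterError(
                f"alpha and beta must be > 0; got alpha={self.alpha}, beta={self.beta}"
            )

    @property
    def time_to_peak(self) -> float:
        """Mode of the curve: ``t0 + alpha * beta``."""
        return self.t0 + self.alpha * self.beta


def gamma_variate_curve(params: GammaVariateParams, times: np.ndarray) -> np.ndarray:
    """Evaluate the gamma-variate bolus curve on a strictly increasing time grid."""
    times = np.asarray(times, dtype=float)
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ParameterError("times must be strictly increasing")
    dt = times - params.t0
    out = np.zeros_like(times)
    rising = dt > 0
    out[rising] = (
        params.amplitude
        * dt[rising] ** params.alpha
        * np.exp(-dt[rising] / params.beta)
    )
    return out
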