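"""FRAP trace normalization and recovery-parameter estimation.

Double normalization: the bleach-ROI signal is first corrected for
acquisition photobleaching with a similarly sized unbleached reference area,

    F_c(t) = F(t) · mean_pre(R) / R(t),

then anchored so the pre-bleach mean equals 1 and the lowest post-bleach
corrected value equals 0,

    V(t) = (F_c(t) − min_post(F_c)) / (mean_pre(F_c) − min_post(F_c)).

The anchoring is exact by construction. The post-bleach minimum is taken on
corrected values so reference noise cannot shift the anchor. A shared
multiplicative decay exp(−λt) on both ROIs cancels in the correction step.

The optional fit estimates a mobile fraction M and half-time from
V(t) = M·(1 − exp(−t·ln2/t_half)) on post-bleach frames, with M bounded to
[0, 1.5].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .datatypes import FrapTrace, warn

__all__ = ["NormalizedTrace", "normalize_frap", "fit_recovery"]


@dataclass
class NormalizedTrace:
    """Dimensionless trace: pre-bleach mean = 1, post-bleach minimum = 0."""

    times: np.ndarray
    values: np.ndarray
    n_pre: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    @property
    def post_times(self) -> np.ndarray:
        """Time since bleach (0 at the first post-bleach frame)."""
        return self.times[self.n_pre :] - self.times[self.n_pre]

    @property
    def post_values(self) -> np.ndarray:
        return self.values[self.n_pre :]


def normalize_frap(trace: FrapTrace) -> NormalizedTrace:
    """Reference-corrected, doubly normalized FRAP trace."""
    n_pre = trace.n_pre
    ref = trace.reference_intensity
    corrected = trace.bleach_intensity * ref[:n_pre].mean() / ref
    pre_mean = corrected[:n_pre].mean()
    post_min = corrected[n_pre:].min()
    denom = pre_mean - post_min
    if denom <= 0:
        raise ValueError(
            "normalize_frap: pre-bleach mean does not exceed the post-bleach "
            "minimum (no bleach detected)"
        )
    values = (corrected - post_min) / denom
    return NormalizedTrace(times=trace.times, values=values, n_pre=n_pre)


def _model(t: np.ndarray, mobile: float, half_time: float) -> np.ndarray:
    return mobile * (1.0 - np.exp(-t * np.log(2.0) / half_time))


def fit_recovery(trace: NormalizedTrace) -> tuple[float | None, float | None]:
    """Least-squares (mobile_fraction, half_time) on post-bleach frames.

    Returns (None, None) with a diagnostic warning if the fit fails.
    """
    t = trace.post_times
    v = trace.post_values
    if np.allclose(v, 0.0):
        return 0.0, None
    m0 = float(np.clip(v[-1], 1e-3, 1.5))
    # first time the curve passes half its final level
    above = np.flatnonzero(v >= m0 / 2)
    t0 = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(max(t[-1] / 5, 1e-3))
    try:
        popt, _ = curve_fit(
            _model,
            t,
            v,
            p0=(m0, t0),
            bounds=((0.0, 1e-9), (1.5, np.inf)),
            maxfev=10_000,
        )
    except (RuntimeError, ValueError) as exc:
        warn(f"fit_recovery: fit did not converge ({exc})")
        return None, None
    return float(popt[0]), float(popt[1])
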