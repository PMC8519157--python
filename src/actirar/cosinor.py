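"""One-component cosinor: MESOR, amplitude, and acrophase of the 24-h rhythm.

The cosinor model is the linearised fit

    y(t) = M + beta_c * cos(2*pi*t/P) + beta_s * sin(2*pi*t/P) + e,

equivalently ``y(t) = M + A*cos(2*pi*(t - phi)/P)`` with amplitude
``A = sqrt(beta_c^2 + beta_s^2)`` (half the peak-to-trough excursion, the
standard convention) and acrophase ``phi`` the clock time of the fitted peak.
The period P is fixed at 24 h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .utils import hours_to_clock

__all__ = ["CosinorFit", "fit_cosinor", "acrophase_to_clock"]

# amplitudes below this are treated as a flat fit: the acrophase is undefined
_AMPLITUDE_TOL = 1e-9


@dataclass
class CosinorFit:
    mesor: float
    amplitude: float
    acrophase_hours: float  # NaN when the amplitude is numerically zero
    beta_cos: float
    beta_sin: float
    residual_sd: float
    n_points: int
    period_hours: float = 24.0

    @property
    def acrophase_clock(self) -> str:
        return acrophase_to_clock(self.acrophase_hours)

    def predict(self, t_hours) -> np.ndarray:
        w = 2.0 * math.pi / self.period_hours
        t = np.asarray(t_hours, dtype=float)
        return self.mesor + self.beta_cos * np.cos(w * t) + self.beta_sin * np.sin(w * t)


def fit_cosinor(t_hours, values, period_hours: float = 24.0) -> CosinorFit:
    """Ordinary least squares cosinor fit of ``values`` on clock time.

    Requires at least four distinct time points spanning more than half the
    period, so the phase is identifiable. Times may repeat (e.g. pooled bins
    from several days).
    """
    t = np.asarray(t_hours, dtype=float).ravel()
    y = np.asarray(values, dtype=float).ravel()
    if t.shape != y.shape:
        raise ValueError("t_hours and values must have equal length")
    keep = np.isfinite(t) & np.isfinite(y)
    t, y = t[keep], y[keep]
    distinct = np.unique(np.mod(t, period_hours))
    if distinct.size < 4:
        raise ValueError(f"need >= 4 distinct time points, got {distinct.size}")
    if distinct.max() - distinct.min() <= period_hours / 2.0:
        raise ValueError("time points must span more than half the period")

    w = 2.0 * math.pi / period_hours
    design = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    mesor, beta_c, beta_s = map(float, coef)
    amplitude = math.hypot(beta_c, beta_s)
    if amplitude < _AMPLITUDE_TOL:
        acrophase = math.nan
    else:
        # peak of M + A*cos(w*t - psi) at t = psi/w, mapped into [0, P)
        acrophase = (math.atan2(beta_s, beta_c) / w) % period_hours
    resid = y - design @ coef
    dof = max(len(y) - 3, 1)
    residual_sd = float(np.sqrt(resid @ resid / dof))
    return CosinorFit(
        mesor=mesor,
        amplitude=amplitude,
        acrophase_hours=acrophase,
        beta_cos=beta_c,
        beta_sin=beta_s,
        residual_sd=residual_sd,
        n_points=len(y),
        period_hours=period_hours,
    )


def acrophase_to_clock(acrophase_hours: float) -> str:
    """Acrophase in decimal hours as a ``HH:MM`` clock string ('' if undefined)."""
    return hours_to_clock(acrophase_hours)
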