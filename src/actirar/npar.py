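"""Nonparametric rest/activity rhythm statistics: IS, IV, and RA (M10/L5).

All three are computed on binned log activity by default, consistent with the
rest of the pipeline operating on ``ln(AC + 1)``; raw-count mode is a caller
choice (pass raw-binned values).

* IS (interdaily stability): ratio of the variance of the average 24-h
  profile to the total variance — 1 for a perfectly repeated daily pattern,
  0 when days differ only by level shifts.
* IV (intradaily variability): normalised mean squared successive difference —
  near 0 for a smooth sinusoidal day, ~2 for white noise, up to 4 for a
  strictly alternating sequence.
* RA (relative amplitude): (M10 − L5)/(M10 + L5) with M10/L5 the mean level in
  the most-active 10-h and least-active 5-h windows (circular in clock time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocessing import DailyProfileMatrix

__all__ = [
    "NparMetrics",
    "interdaily_stability",
    "intradaily_variability",
    "relative_amplitude",
    "npar_metrics",
]


@dataclass
class NparMetrics:
    IS: float
    IV: float
    RA: float
    M10: float
    L5: float
    M10_onset_hours: float
    L5_onset_hours: float


def _complete_columns(values: np.ndarray) -> np.ndarray:
    """Listwise bin handling: drop bins with any missing day."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    keep = ~np.any(np.isnan(values), axis=0)
    return values[:, keep]


def interdaily_stability(matrix) -> float:
    """IS = [N * sum_h (xbar_h − xbar)^2] / [p * sum_i (x_i − xbar)^2].

    ``matrix`` is a DailyProfileMatrix (valid days only) or a days x bins
    array. Bins missing on any day are dropped listwise first. Undefined (NaN,
    with a warning) when the total variance is zero.
    """
    if isinstance(matrix, DailyProfileMatrix):
        values = matrix.values[matrix.day_valid]
    else:
        values = np.atleast_2d(np.asarray(matrix, dtype=float))
    values = _complete_columns(values)
    n_days, p = values.shape
    if n_days < 2:
        raise ValueError("interdaily stability requires >= 2 valid days")
    N = values.size
    grand = values.mean()
    total = np.sum((values - grand) ** 2)
    if total == 0.0:
        warnings.warn("zero total variance: IS undefined", stacklevel=2)
        return np.nan
    hourly = values.mean(axis=0)
    stat = (N * np.sum((hourly - grand) ** 2)) / (p * total)
    # clip pure floating error at the boundaries
    return float(min(max(stat, 0.0), 1.0)) if -1e-12 < stat < 1 + 1e-12 else float(stat)


def intradaily_variability(values, per_day: bool = True) -> float:
    """Normalised mean squared successive difference of binned activity.

    For a single contiguous sequence x_1..x_N this is the classical

        IV = [N * sum_{i>=2} (x_i − x_{i−1})^2] / [(N−1) * sum_i (x_i − xbar)^2].

    With ``per_day=True`` (default) successive differences are taken within
    days only and pooled, so an artificial midnight jump between consecutive
    days does not count as fragmentation; ``per_day=False`` concatenates days.
    Missing values break a run in either mode: differences never span a gap.
    The grand mean and variance always pool all observed values.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        rows = [values]
    elif per_day:
        rows = list(values)
    else:
        rows = [values.ravel()]

    all_obs = np.concatenate([r[np.isfinite(r)] for r in rows]) if rows else np.array([])
    N = all_obs.size
    if N < 3:
        raise ValueError("intradaily variability requires >= 3 observed values")
    grand = all_obs.mean()
    total = np.sum((all_obs - grand) ** 2)
    if total == 0.0:
        warnings.warn("zero variance: IV undefined", stacklevel=2)
        return np.nan

    ssd = 0.0
    n_pairs = 0
    for row in rows:
        finite = np.isfinite(row)
        # contiguous runs of observed values
        boundaries = np.flatnonzero(np.diff(finite.astype(int)))
        starts = np.r_[0, boundaries + 1]
        ends = np.r_[boundaries, len(row) - 1]
        for s, e in zip(starts, ends):
            if finite[s] and e > s:
                d = np.diff(row[s : e + 1])
                ssd += float(d @ d)
                n_pairs += len(d)
    if n_pairs == 0:
        warnings.warn("no successive pairs: IV undefined", stacklevel=2)
        return np.nan
    # MSSD (pairs denominator) over population variance; for one full
    # sequence this reduces to N*ssd / ((N-1)*total)
    return float((ssd / n_pairs) / (total / N))


def relative_amplitude(mean_profile, bin_minutes: int = 30):
    """RA with M10/L5 from circularly wrapped 10-h and 5-h window means.

    Returns ``(RA, M10, L5, M10_onset_hours, L5_onset_hours)``; onsets are the
    clock time at which each best window starts, ties broken by the earliest
    onset. RA is undefined (NaN) when M10 + L5 == 0.
    """
    profile = np.asarray(mean_profile, dtype=float).ravel()
    if not np.all(np.isfinite(profile)):
        raise ValueError("mean profile must be finite for M10/L5")
    n = profile.size
    bins_per_hour = 60 // bin_minutes
    k10 = 10 * bins_per_hour
    k5 = 5 * bins_per_hour
    if n < k10:
        raise ValueError("profile shorter than the 10-h window")

    wrapped = np.r_[profile, profile]
    csum = np.r_[0.0, np.cumsum(wrapped)]

    def window_means(k):
        return (csum[k : k + n] - csum[:n]) / k

    m10_means = window_means(k10)
    l5_means = window_means(k5)
    i10 = int(np.argmax(m10_means))  # argmax/argmin return the first (earliest) tie
    i5 = int(np.argmin(l5_means))
    M10 = float(m10_means[i10])
    L5 = float(l5_means[i5])
    denom = M10 + L5
    RA = float((M10 - L5) / denom) if denom != 0.0 else np.nan
    hours_per_bin = bin_minutes / 60.0
    return RA, M10, L5, i10 * hours_per_bin, i5 * hours_per_bin


def npar_metrics(matrix: DailyProfileMatrix, per_day_iv: bool = True) -> NparMetrics:
    """All nonparametric metrics for one subject's valid-day profile matrix."""
    valid = matrix.values[matrix.day_valid]
    IS = interdaily_stability(matrix)
    IV = intradaily_variability(valid, per_day=per_day_iv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_profile = np.nanmean(valid, axis=0)
    RA, M10, L5, m10_on, l5_on = relative_amplitude(mean_profile, matrix.bin_minutes)
    return NparMetrics(IS=IS, IV=IV, RA=RA, M10=M10, L5=L5,
                       M10_onset_hours=m10_on, L5_onset_hours=l5_on)
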