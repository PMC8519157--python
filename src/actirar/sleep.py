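"""Epoch-level sleep/wake scoring and nightly sleep parameters.

The scorer is a weighted-moving-window threshold algorithm of the family used
by actigraphy vendors: an epoch is scored wake when a weighted sum of activity
counts in a symmetric window around it exceeds a threshold. The exact
proprietary weights used by commercial software are not public, so the
defaults here (±2 min window, central weight 1.0, neighbours 0.2, threshold 40
— a "medium" sensitivity) are a documented stand-in, not a claim of
equivalence with any vendor implementation.

Sleep parameters are computed within an externally supplied rest (in-bed)
interval per night: sleep onset latency (SOL), total sleep time (TST), wake
after sleep onset (WASO), sleep efficiency (SE), and average wake bout length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import EpochSeries

__all__ = [
    "RestInterval",
    "SleepParameters",
    "default_weights",
    "score_sleep_wake",
    "sleep_parameters",
    "average_sleep_parameters",
]


@dataclass
class RestInterval:
    """One night's in-bed interval, adjudicated upstream (diary/markers/light)."""

    subject_id: str
    night: int
    lights_out: np.datetime64
    out_of_bed: np.datetime64

    def __post_init__(self):
        self.lights_out = np.datetime64(pd.Timestamp(self.lights_out), "s")
        self.out_of_bed = np.datetime64(pd.Timestamp(self.out_of_bed), "s")
        if self.out_of_bed <= self.lights_out:
            raise ValueError("out_of_bed must be after lights_out")
        if (self.out_of_bed - self.lights_out) > np.timedelta64(24 * 3600, "s"):
            raise ValueError("rest interval longer than 24 h")


@dataclass
class SleepParameters:
    TST: float  # min asleep between onset and out-of-bed
    WASO: float  # min awake between onset and out-of-bed
    SE: float  # % of the in-bed interval spent asleep
    SOL: float  # min from lights-out to sleep onset
    avg_wake_bout: float  # mean length (min) of wake bouts after onset; NaN if none
    onset_found: bool = True


def default_weights(epoch_seconds: int = 30) -> np.ndarray:
    """Symmetric scoring weights spanning ±2 minutes around the central epoch."""
    half = max(int(round(120 / epoch_seconds)), 1)
    w = np.full(2 * half + 1, 0.2)
    w[half] = 1.0
    return w


def score_sleep_wake(
    series: EpochSeries,
    threshold: float = 40.0,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Score each epoch sleep (False) or wake (True).

    Wake when the weighted sum of raw counts in the window exceeds
    ``threshold``. Edge epochs use truncated windows. Deterministic.
    """
    if series.is_log:
        raise ValueError("sleep scoring operates on raw activity counts")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if weights is None:
        weights = default_weights(series.epoch_seconds)
    weights = np.asarray(weights, dtype=float)
    if weights.size % 2 == 0:
        raise ValueError("weights must have odd length (symmetric window)")
    counts = np.asarray(series.values, dtype=float)
    # 'same' convolution with the reversed kernel = sliding weighted sum,
    # implicitly zero-padded, i.e. truncated windows at the edges
    score = np.convolve(counts, weights[::-1], mode="same")
    return score > threshold


def _runs(mask: np.ndarray):
    """(start, length) of maximal True runs."""
    idx = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
    return [(s, e - s) for s, e in zip(idx[::2], idx[1::2])]


def sleep_parameters(
    wake: np.ndarray,
    timestamps: np.ndarray,
    interval: RestInterval,
    onset_minutes: float = 10.0,
    epoch_seconds: int = 30,
) -> SleepParameters:
    """Nightly sleep parameters from scored epochs within a rest interval.

    Sleep onset is the start of the first run of at least ``onset_minutes`` of
    consecutive sleep epochs after lights-out. If no such run exists, SOL is
    the whole interval, TST and WASO are 0, and the result is flagged.
    """
    timestamps = np.asarray(timestamps, dtype="datetime64[s]")
    wake = np.asarray(wake, dtype=bool)
    inside = (timestamps >= interval.lights_out) & (timestamps < interval.out_of_bed)
    w = wake[inside]
    if w.size == 0:
        raise ValueError("no scored epochs inside the rest interval")
    epoch_min = epoch_seconds / 60.0
    interval_min = w.size * epoch_min

    need = max(int(math.ceil(onset_minutes / epoch_min)), 1)
    onset_idx = None
    for start, length in _runs(~w):
        if length >= need:
            onset_idx = start
            break
    if onset_idx is None:
        return SleepParameters(
            TST=0.0,
            WASO=0.0,
            SE=100.0 * float(np.sum(~w)) * epoch_min / interval_min,
            SOL=interval_min,
            avg_wake_bout=np.nan,
            onset_found=False,
        )

    sol = onset_idx * epoch_min
    after = w[onset_idx:]
    tst = float(np.sum(~after)) * epoch_min
    waso = float(np.sum(after)) * epoch_min
    se = 100.0 * float(np.sum(~w)) * epoch_min / interval_min
    wake_bouts = [length for _, length in _runs(after)]
    avg_bout = float(np.mean(wake_bouts)) * epoch_min if wake_bouts else np.nan
    return SleepParameters(
        TST=tst, WASO=waso, SE=se, SOL=sol, avg_wake_bout=avg_bout, onset_found=True
    )


def average_sleep_parameters(nights: list[SleepParameters]) -> SleepParameters:
    """Per-subject average over valid nights (NaN-skipping for wake bouts)."""
    if not nights:
        raise ValueError("no nights to average")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg_bout = float(np.nanmean([n.avg_wake_bout for n in nights]))
    return SleepParameters(
        TST=float(np.mean([n.TST for n in nights])),
        WASO=float(np.mean([n.WASO for n in nights])),
        SE=float(np.mean([n.SE for n in nights])),
        SOL=float(np.mean([n.SOL for n in nights])),
        avg_wake_bout=avg_bout,
        onset_found=all(n.onset_found for n in nights),
    )
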