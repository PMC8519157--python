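"""Epoch-level preprocessing: log transform, daily binning, valid-day filtering.

A subject's raw record is a multi-day sequence of 30-second accelerometer
activity counts (AC). The analysis scale throughout the package is
``ln(AC + 1)``: the natural-log transform symmetrises the heavily right-skewed
count distribution. Log epochs are averaged within nonoverlapping clock-time
bins (48 bins of 30 min, or 24 of 60 min, per calendar day) to give a
days x bins matrix, from which each subject's mean and across-day SD
rest/activity profiles are computed over valid days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

SECONDS_PER_DAY = 86_400
MINUTES_PER_DAY = 1_440


@dataclass
class EpochSeries:
    """One subject's ordered, regularly spaced activity epochs.

    ``values`` holds raw counts (non-negative integers) or, after
    :func:`log_transform`, natural-log counts (``is_log=True``). ``off_wrist``
    flags epochs to exclude from binning.
    """

    subject_id: str
    timestamps: np.ndarray  # datetime64[s], strictly increasing, constant spacing
    values: np.ndarray
    off_wrist: np.ndarray = None
    epoch_seconds: int = 30
    is_log: bool = False

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.values = np.asarray(self.values)
        if self.off_wrist is None:
            self.off_wrist = np.zeros(self.values.shape, dtype=bool)
        self.off_wrist = np.asarray(self.off_wrist, dtype=bool)
        if self.timestamps.shape != self.values.shape:
            raise ValueError("timestamps and values must have equal length")
        if len(self.timestamps) > 1:
            steps = np.diff(self.timestamps.astype(np.int64))
            if np.any(steps <= 0):
                raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class DailyProfileMatrix:
    """Days x bins matrix of mean log activity per clock-time bin.

    Rows are consecutive calendar days (midnight-aligned local time), columns
    half-open bins [start, start + bin_minutes). Cells with no wearable epochs
    are NaN. ``day_valid`` marks days passing the wear-fraction rule and
    ``excluded_from_rar`` is set when fewer than ``min_valid_days`` survive.
    """

    subject_id: str
    bin_minutes: int
    values: np.ndarray  # (n_days, n_bins)
    dates: np.ndarray  # datetime64[D] per row
    day_valid: np.ndarray = None
    excluded_from_rar: bool = False

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.day_valid is None:
            self.day_valid = np.ones(self.values.shape[0], dtype=bool)
        self.day_valid = np.asarray(self.day_valid, dtype=bool)
        if MINUTES_PER_DAY % self.bin_minutes:
            raise ValueError(f"bin_minutes={self.bin_minutes} must divide 1440")
        if self.values.shape[1] != self.n_bins:
            raise ValueError(
                f"expected {self.n_bins} bins for {self.bin_minutes}-minute "
                f"binning, got {self.values.shape[1]}"
            )

    @property
    def n_bins(self) -> int:
        return MINUTES_PER_DAY // self.bin_minutes

    @property
    def n_valid_days(self) -> int:
        return int(self.day_valid.sum())

    @property
    def bin_midpoints_hours(self) -> np.ndarray:
        """Clock hour at the centre of each bin (0.25, 0.75, ... for 30 min)."""
        w = self.bin_minutes / 60.0
        return (np.arange(self.n_bins) + 0.5) * w


@dataclass
class SubjectRAR:
    """A subject's mean and across-day SD rest/activity profiles.

    These two curves are the functional outcomes of the group analysis: the
    mean profile captures the average 24-hour activity pattern, the SD profile
    the day-to-day variability of activity at each clock time.
    """

    subject_id: str
    bin_minutes: int
    mean_profile: np.ndarray
    sd_profile: np.ndarray
    n_valid_days: int

    @property
    def n_bins(self) -> int:
        return MINUTES_PER_DAY // self.bin_minutes

    @property
    def bin_midpoints_hours(self) -> np.ndarray:
        w = self.bin_minutes / 60.0
        return (np.arange(self.n_bins) + 0.5) * w


def log_transform(series: EpochSeries) -> EpochSeries:
    """Return a copy of ``series`` with values replaced by ``ln(AC + 1)``."""
    if series.is_log:
        raise ValueError(f"{series.subject_id}: series is already log-transformed")
    values = np.asarray(series.values, dtype=float)
    negative = np.flatnonzero(values < 0)
    if negative.size:
        i = int(negative[0])
        raise ValueError(
            f"{series.subject_id}: negative activity count {series.values[i]} "
            f"at epoch {i} ({series.timestamps[i]})"
        )
    return replace(series, values=np.log1p(values), is_log=True)


def bin_profiles(series: EpochSeries, bin_minutes: int = 30) -> DailyProfileMatrix:
    """Average log epochs into per-day clock-time bins.

    Off-wrist epochs are excluded; a cell with no remaining epochs is NaN.
    Days are calendar days (midnight to midnight, local clock).
    """
    if not series.is_log:
        raise ValueError("bin_profiles expects a log-transformed series")
    if MINUTES_PER_DAY % bin_minutes:
        raise ValueError(f"bin_minutes={bin_minutes} must divide 1440")
    if len(series) > 1:
        steps = np.diff(series.timestamps.astype(np.int64))
        if np.unique(steps).size != 1:
            raise ValueError(
                f"{series.subject_id}: irregular epoch spacing "
                f"(steps {np.unique(steps)} s)"
            )
        if steps[0] != series.epoch_seconds:
            raise ValueError(
                f"{series.subject_id}: epoch spacing {steps[0]} s does not match "
                f"declared epoch_seconds={series.epoch_seconds}"
            )

    secs = series.timestamps.astype(np.int64)
    day = secs // SECONDS_PER_DAY
    day_index = (day - day[0]).astype(np.intp)
    n_days = int(day_index[-1]) + 1
    n_bins = MINUTES_PER_DAY // bin_minutes
    bin_index = ((secs % SECONDS_PER_DAY) // (bin_minutes * 60)).astype(np.intp)

    keep = ~series.off_wrist
    sums = np.zeros((n_days, n_bins))
    counts = np.zeros((n_days, n_bins))
    np.add.at(sums, (day_index[keep], bin_index[keep]), series.values[keep])
    np.add.at(counts, (day_index[keep], bin_index[keep]), 1.0)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.where(counts > 0, counts, 1.0), np.nan)

    dates = (day[0] + np.arange(n_days)).astype("datetime64[D]")
    return DailyProfileMatrix(
        subject_id=series.subject_id,
        bin_minutes=bin_minutes,
        values=values,
        dates=dates,
    )


def filter_valid_days(
    matrix: DailyProfileMatrix,
    max_missing_fraction: float = 0.5,
    min_valid_days: int = 3,
) -> DailyProfileMatrix:
    """Flag days with too much missing wear time and subjects with too few days.

    A day is invalid when more than ``max_missing_fraction`` of its bins are
    missing. Subjects retaining fewer than ``min_valid_days`` valid days are
    flagged ``excluded_from_rar`` (a flag, not an exception — exclusion is a
    cohort-level decision applied downstream).
    """
    missing_fraction = np.mean(np.isnan(matrix.values), axis=1)
    day_valid = missing_fraction <= max_missing_fraction
    excluded = int(day_valid.sum()) < min_valid_days
    return DailyProfileMatrix(
        subject_id=matrix.subject_id,
        bin_minutes=matrix.bin_minutes,
        values=matrix.values,
        dates=matrix.dates,
        day_valid=day_valid,
        excluded_from_rar=excluded,
    )


def subject_rar(matrix: DailyProfileMatrix) -> SubjectRAR:
    """Mean and sample SD (n−1 denominator) of each bin over valid days.

    Missing cells are skipped; a bin with fewer than two contributing days gets
    a NaN SD with a warning.
    """
    valid = matrix.values[matrix.day_valid]
    if valid.shape[0] == 0:
        raise ValueError(f"{matrix.subject_id}: no valid days")
    n_per_bin = np.sum(~np.isnan(valid), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean_profile = np.nanmean(valid, axis=0)
        sd_profile = np.nanstd(valid, axis=0, ddof=1)
    sd_profile = np.where(n_per_bin >= 2, sd_profile, np.nan)
    mean_profile = np.where(n_per_bin >= 1, mean_profile, np.nan)
    if np.any(n_per_bin < 2):
        warnings.warn(
            f"{matrix.subject_id}: {int(np.sum(n_per_bin < 2))} bins with <2 "
            "contributing days; SD undefined there",
            stacklevel=2,
        )
    return SubjectRAR(
        subject_id=matrix.subject_id,
        bin_minutes=matrix.bin_minutes,
        mean_profile=mean_profile,
        sd_profile=sd_profile,
        n_valid_days=matrix.n_valid_days,
    )
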