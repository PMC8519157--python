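"""Synthetic two-group actigraphy cohorts with known circadian ground truth.

The generator emulates a screening cohort of cognitively unimpaired older
adults split into an amyloid-positive and an amyloid-negative group (26 vs 33
subjects, 2–6 valid days of 30-second wrist-actigraphy epochs each). Activity
is produced by exponentiating a Gaussian latent log-process:

    x_idt = mu(t - J_id) + b_i + delta(t) * 1[group_i = pos] + eps_idt
    AC    = max(0, round(exp(x) - 1))

where ``mu`` is a cosinor-plus-harmonics baseline on the log scale, ``b_i`` a
subject-level intercept, ``J_id`` a day-specific phase jitter applied to the
baseline curve (the group effect ``delta`` stays anchored to clock time so the
group contrast at clock time t is exactly ``delta(t)``), and ``eps`` Gaussian
epoch noise whose SD is multiplied inside configurable clock-time windows for
the positive group. Working on the latent log scale keeps the ground-truth
mean and SD structure closed-form, so every downstream stage can be checked
against it; the generator is a stand-in for device data, not a model of any
particular accelerometer's noise process.

Defaults place a negative mean effect centred near 01:15 and positive effects
near 06:30 and 15:00, each 0.5 log units high, with across-day variability
raised in the late-evening and early-morning windows and lowered between
02:30 and 03:30 — the pattern of time-localised group differences the package
is designed to detect.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import EpochSeries, SECONDS_PER_DAY
from .utils import in_circular_window

__all__ = ["Bump", "SDWindow", "CovariateModel", "SimConfig", "CohortDataset",
           "generate_cohort", "latent_mean", "group_effect"]

_MAX_LATENT_MEAN = 20.0  # exp() overflow guard on the log-count scale


@dataclass(frozen=True)
class Bump:
    """Gaussian-shaped group mean effect localised in clock time.

    ``width_hours`` is the Gaussian SD; ``sign`` +1 raises, −1 lowers the
    positive group's log activity around ``center_hours``.
    """

    center_hours: float
    width_hours: float = 1.5
    height_log_units: float = 0.5
    sign: int = 1


@dataclass(frozen=True)
class SDWindow:
    """Multiplier on the positive group's epoch-noise SD in [start, end).

    ``start_hours > end_hours`` wraps past midnight.
    """

    start_hours: float
    end_hours: float
    sd_multiplier: float


@dataclass(frozen=True)
class CovariateModel:
    """Group-specific covariate distributions (age in years, education years)."""

    age_mean_pos: float = 72.4
    age_mean_neg: float = 70.4
    age_sd: float = 4.6
    female_prob_pos: float = 0.65
    female_prob_neg: float = 0.55
    education_mean_pos: float = 16.0
    education_mean_neg: float = 17.0
    education_sd: float = 2.4


_DEFAULT_BUMPS = (
    Bump(center_hours=1.25, width_hours=1.5, height_log_units=0.5, sign=-1),
    Bump(center_hours=6.5, width_hours=1.5, height_log_units=0.5, sign=+1),
    Bump(center_hours=15.0, width_hours=1.5, height_log_units=0.5, sign=+1),
)
_DEFAULT_SD_WINDOWS = (
    SDWindow(21.5, 1.0, 1.5),
    SDWindow(4.5, 8.5, 1.5),
    SDWindow(2.5, 3.5, 0.6),
)


@dataclass
class SimConfig:
    """Full description of one simulated cohort; defaults are the study design."""

    n_group_pos: int = 26
    n_group_neg: int = 33
    day_range: tuple[int, int] = (2, 6)
    # P(days = day_range[0] .. day_range[1]); mean ~5.7 days mimicking a
    # mostly-complete week of wear
    day_weights: tuple[float, ...] = (0.02, 0.02, 0.04, 0.12, 0.80)
    epoch_seconds: int = 30
    baseline_mesor: float = 3.2
    baseline_amplitude: float = 2.3
    baseline_acrophase: float = 14.7
    harmonics: tuple[tuple[float, float, float], ...] = ((2, 0.35, 14.7),)
    mean_effect_bumps: tuple[Bump, ...] = _DEFAULT_BUMPS
    sd_effect_windows: tuple[SDWindow, ...] = _DEFAULT_SD_WINDOWS
    subject_intercept_sd: float = 0.3
    day_phase_jitter_sd: float = 0.5
    noise_sd: float = 0.6
    covariates: CovariateModel = field(default_factory=CovariateModel)
    rng_seed: int = 42
    start_date: str = "2020-01-06"

    def validate(self) -> None:
        if self.n_group_pos < 1 or self.n_group_neg < 1:
            raise ValueError("both groups need at least one subject")
        lo, hi = self.day_range
        if not (2 <= lo <= hi <= 6):
            raise ValueError("day_range must lie within [2, 6]")
        if len(self.day_weights) != hi - lo + 1:
            raise ValueError("day_weights must match the day_range span")
        if SECONDS_PER_DAY % self.epoch_seconds:
            raise ValueError("epoch_seconds must divide 86400")
        for sd in (self.subject_intercept_sd, self.day_phase_jitter_sd, self.noise_sd):
            if sd < 0:
                raise ValueError("all SDs must be >= 0")
        for b in self.mean_effect_bumps:
            if b.width_hours <= 0:
                raise ValueError("bump widths must be > 0")
            if not 0 <= b.center_hours < 24:
                raise ValueError("bump centers must lie in [0, 24)")
        for w in self.sd_effect_windows:
            if w.sd_multiplier < 0:
                raise ValueError("sd multipliers must be >= 0")
        peak = (
            self.baseline_mesor
            + abs(self.baseline_amplitude)
            + sum(abs(a) for _, a, _ in self.harmonics)
            + sum(b.height_log_units for b in self.mean_effect_bumps)
        )
        if peak > _MAX_LATENT_MEAN:
            raise ValueError(
                f"latent mean can reach {peak:.1f} log-counts (> {_MAX_LATENT_MEAN}): "
                "exp() would overflow realistic count ranges"
            )


@dataclass
class CohortDataset:
    """Simulated epoch data plus covariates and closed-form ground truth.

    Ground-truth functions are evaluated at the 30-min bin midpoints:
    ``mu_neg`` the negative group's latent mean log profile, ``delta`` the
    positive-minus-negative mean contrast, ``sigma_neg``/``sigma_pos`` the
    epoch-level noise SD profiles per group.
    """

    subjects: list[EpochSeries]
    covariates: pd.DataFrame
    grid_hours: np.ndarray
    mu_neg: np.ndarray
    delta: np.ndarray
    sigma_neg: np.ndarray
    sigma_pos: np.ndarray
    config: SimConfig


def latent_mean(config: SimConfig, t_hours) -> np.ndarray:
    """Baseline (negative-group) latent log-activity curve mu(t)."""
    t = np.asarray(t_hours, dtype=float)
    w = 2.0 * np.pi / 24.0
    mu = config.baseline_mesor + config.baseline_amplitude * np.cos(
        w * (t - config.baseline_acrophase)
    )
    for order, amp, phase in config.harmonics:
        mu = mu + amp * np.cos(w * order * (t - phase))
    return mu


def group_effect(config: SimConfig, t_hours) -> np.ndarray:
    """Positive-minus-negative mean contrast delta(t) on the log scale."""
    t = np.asarray(t_hours, dtype=float)
    delta = np.zeros_like(t)
    for b in config.mean_effect_bumps:
        d = np.mod(t - b.center_hours, 24.0)
        d = np.minimum(d, 24.0 - d)
        delta = delta + b.sign * b.height_log_units * np.exp(
            -0.5 * (d / b.width_hours) ** 2
        )
    return delta


def _noise_sd_profile(config: SimConfig, t_hours, positive: bool) -> np.ndarray:
    sd = np.full(np.shape(t_hours), config.noise_sd, dtype=float)
    if positive:
        for w in config.sd_effect_windows:
            inside = in_circular_window(t_hours, w.start_hours, w.end_hours)
            sd[inside] *= w.sd_multiplier
    return sd


def generate_cohort(config: SimConfig | None = None) -> CohortDataset:
    """Draw one cohort. Deterministic given ``config.rng_seed``."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    cov = config.covariates

    groups = ["pos"] * config.n_group_pos + ["neg"] * config.n_group_neg
    n = len(groups)
    subject_ids = [f"sub-{i + 1:03d}" for i in range(n)]
    is_pos = np.array([g == "pos" for g in groups])

    age = np.where(
        is_pos,
        rng.normal(cov.age_mean_pos, cov.age_sd, n),
        rng.normal(cov.age_mean_neg, cov.age_sd, n),
    ).clip(65, 85).round(1)
    female = rng.random(n) < np.where(is_pos, cov.female_prob_pos, cov.female_prob_neg)
    education = np.where(
        is_pos,
        rng.normal(cov.education_mean_pos, cov.education_sd, n),
        rng.normal(cov.education_mean_neg, cov.education_sd, n),
    ).clip(10, 20).round(0).astype(int)

    lo, hi = config.day_range
    weights = np.asarray(config.day_weights, dtype=float)
    weights = weights / weights.sum()
    n_days = rng.choice(np.arange(lo, hi + 1), size=n, p=weights)

    epochs_per_day = SECONDS_PER_DAY // config.epoch_seconds
    t_epoch = (np.arange(epochs_per_day) + 0.5) * config.epoch_seconds / 3600.0
    delta_epoch = group_effect(config, t_epoch)
    start = np.datetime64(config.start_date, "s")

    subjects: list[EpochSeries] = []
    for i, sid in enumerate(subject_ids):
        d = int(n_days[i])
        b_i = rng.normal(0.0, config.subject_intercept_sd)
        jitter = rng.normal(0.0, config.day_phase_jitter_sd, size=d)
        sd_t = _noise_sd_profile(config, t_epoch, positive=bool(is_pos[i]))
        latent = (
            latent_mean(config, t_epoch[None, :] - jitter[:, None])
            + b_i
            + (delta_epoch[None, :] if is_pos[i] else 0.0)
            + rng.standard_normal((d, epochs_per_day)) * sd_t[None, :]
        )
        counts = np.maximum(0.0, np.rint(np.exp(latent) - 1.0)).astype(np.int64)
        timestamps = start + (
            np.arange(d * epochs_per_day, dtype=np.int64) * config.epoch_seconds
        ).astype("timedelta64[s]")
        subjects.append(
            EpochSeries(
                subject_id=sid,
                timestamps=timestamps,
                values=counts.ravel(),
                epoch_seconds=config.epoch_seconds,
            )
        )

    covariates = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age": age,
            "sex": np.where(female, "F", "M"),
            "education_years": education,
            "abeta": groups,
        }
    )
    grid = (np.arange(48) + 0.5) * 0.5
    return CohortDataset(
        subjects=subjects,
        covariates=covariates,
        grid_hours=grid,
        mu_neg=latent_mean(config, grid),
        delta=group_effect(config, grid),
        sigma_neg=_noise_sd_profile(config, grid, positive=False),
        sigma_pos=_noise_sd_profile(config, grid, positive=True),
        config=config,
    )


def config_to_dict(config: SimConfig) -> dict:
    """Plain-dict form of a SimConfig (for YAML/JSON round trips)."""
    d = asdict(config)
    d["mean_effect_bumps"] = [asdict(b) for b in config.mean_effect_bumps]
    d["sd_effect_windows"] = [asdict(w) for w in config.sd_effect_windows]
    d["harmonics"] = [list(h) for h in config.harmonics]
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "covariates" in d and isinstance(d["covariates"], dict):
        d["covariates"] = CovariateModel(**d["covariates"])
    if "mean_effect_bumps" in d:
        d["mean_effect_bumps"] = tuple(
            b if isinstance(b, Bump) else Bump(**b) for b in d["mean_effect_bumps"]
        )
    if "sd_effect_windows" in d:
        d["sd_effect_windows"] = tuple(
            w if isinstance(w, SDWindow) else SDWindow(**w)
            for w in d["sd_effect_windows"]
        )
    if "harmonics" in d:
        d["harmonics"] = tuple(tuple(h) for h in d["harmonics"])
    if "day_range" in d:
        d["day_range"] = tuple(d["day_range"])
    if "day_weights" in d:
        d["day_weights"] = tuple(d["day_weights"])
    return SimConfig(**d)
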