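"""End-to-end orchestration and scalar group comparisons.

``run_pipeline`` drives the full analysis: simulate (or read) an epoch-level
cohort, preprocess into daily profile matrices and subject mean/SD profiles,
compute cosinor, nonparametric and (optionally) sleep metrics, compare them
between groups with two-sample t-tests, Fisher exact tests and
covariate-adjusted linear models, and run the function-on-scalar regression
of the mean and SD profiles at 30-minute resolution plus a 60-minute
sensitivity pass. All outputs are plain CSV/JSON in a run directory, with a
manifest recording seeds and configuration so a rerun with the same seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from . import __version__
from .cosinor import fit_cosinor
from .fosr import (
    FunctionalDesign,
    build_design,
    fit_fosr,
    global_f_test,
    pointwise_band,
    significant_windows,
    simultaneous_band,
)
from .io import (
    read_covariates_csv,
    read_epoch_csv,
    read_rest_intervals_csv,
    write_cohort,
    write_subject_rars,
)
from .npar import npar_metrics
from .preprocessing import (
    DailyProfileMatrix,
    EpochSeries,
    bin_profiles,
    filter_valid_days,
    log_transform,
    subject_rar,
)
from .simulate import SimConfig, generate_cohort
from .sleep import (
    RestInterval,
    average_sleep_parameters,
    score_sleep_wake,
    sleep_parameters,
)

__all__ = [
    "ComparisonResult",
    "PipelineConfig",
    "PipelineError",
    "compare_continuous",
    "compare_continuous_from_stats",
    "compare_categorical",
    "adjusted_regression",
    "build_metrics_table",
    "comparison_table",
    "nominal_rest_intervals",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """Stage-tagged failure of an end-to-end run."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {err}")
        self.stage = stage


# ------------------------------------------------------------ scalar comparisons


@dataclass
class ComparisonResult:
    outcome: str
    mean_pos: float = np.nan
    sd_pos: float = np.nan
    mean_neg: float = np.nan
    sd_neg: float = np.nan
    statistic: float = np.nan
    p_value: float = np.nan
    B: float = np.nan  # adjusted coefficient, positive vs negative group
    B_se: float = np.nan
    B_p: float = np.nan


def compare_continuous(pos, neg, equal_var: bool = True, outcome: str = "") -> ComparisonResult:
    """Two-sample t-test (pooled-variance by default; Welch optional)."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    pos, neg = pos[np.isfinite(pos)], neg[np.isfinite(neg)]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 observations per group")
    if np.var(pos) + np.var(neg) == 0:
        if pos.mean() == neg.mean():
            return ComparisonResult(
                outcome=outcome, mean_pos=pos.mean(), sd_pos=0.0,
                mean_neg=neg.mean(), sd_neg=0.0, statistic=0.0, p_value=1.0,
            )
        raise ValueError("degenerate zero-variance groups with unequal means")
    t, p = stats.ttest_ind(pos, neg, equal_var=equal_var)
    return ComparisonResult(
        outcome=outcome,
        mean_pos=float(pos.mean()), sd_pos=float(pos.std(ddof=1)),
        mean_neg=float(neg.mean()), sd_neg=float(neg.std(ddof=1)),
        statistic=float(t), p_value=float(p),
    )


def compare_continuous_from_stats(
    n_pos, mean_pos, sd_pos, n_neg, mean_neg, sd_neg,
    equal_var: bool = True, outcome: str = "",
) -> ComparisonResult:
    """t-test from printed summary statistics (group n, mean, SD)."""
    t, p = stats.ttest_ind_from_stats(
        mean_pos, sd_pos, n_pos, mean_neg, sd_neg, n_neg, equal_var=equal_var
    )
    return ComparisonResult(
        outcome=outcome, mean_pos=mean_pos, sd_pos=sd_pos,
        mean_neg=mean_neg, sd_neg=sd_neg, statistic=float(t), p_value=float(p),
    )


def compare_categorical(table, outcome: str = "") -> ComparisonResult:
    """Two-sided Fisher exact test on a 2x2 contingency table."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if not np.issubdtype(table.dtype, np.integer):
        if not np.allclose(table, np.round(table)):
            raise ValueError("contingency cells must be integers")
        table = np.round(table).astype(int)
    if (table < 0).any():
        raise ValueError("contingency cells must be non-negative")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return ComparisonResult(outcome=outcome, statistic=float(odds), p_value=float(p))


def adjusted_regression(df: pd.DataFrame, outcome: str) -> ComparisonResult:
    """OLS of ``outcome`` on group status adjusting for age, sex, education.

    Reports the coefficient B for the positive group (vs negative reference)
    with its standard error and two-sided t-based p-value.
    """
    data = df.dropna(subset=[outcome, "age", "sex", "education_years", "abeta"])
    if len(data) <= 5:
        raise ValueError("need n > 5 for the adjusted model")
    X = pd.DataFrame(
        {
            "abeta_pos": (data["abeta"] == "pos").astype(float),
            "age": data["age"].astype(float),
            "sex_female": (data["sex"] == "F").astype(float),
            "education_years": data["education_years"].astype(float),
        }
    )
    X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X.to_numpy()[:, 1:], rowvar=False)
        raise ValueError(f"collinear predictors (correlations:\n{np.round(corr, 3)})")
    model = sm.OLS(data[outcome].astype(float), X).fit()
    return ComparisonResult(
        outcome=outcome,
        B=float(model.params["abeta_pos"]),
        B_se=float(model.bse["abeta_pos"]),
        B_p=float(model.pvalues["abeta_pos"]),
    )


# ------------------------------------------------------------ metrics assembly


def preprocess_subject(
    series: EpochSeries,
    bin_minutes: int = 30,
    max_missing_fraction: float = 0.5,
    min_valid_days: int = 3,
) -> DailyProfileMatrix:
    """log-transform, bin, and flag valid days for one subject."""
    return filter_valid_days(
        bin_profiles(log_transform(series), bin_minutes=bin_minutes),
        max_missing_fraction=max_missing_fraction,
        min_valid_days=min_valid_days,
    )


def build_metrics_table(
    matrices: list[DailyProfileMatrix],
    covariates: pd.DataFrame,
    sleep_by_subject: dict | None = None,
) -> pd.DataFrame:
    """One row per subject: covariates + cosinor + nonparametric (+ sleep).

    Subjects flagged ``excluded_from_rar`` keep their covariate and sleep
    columns but have NaN rhythm metrics, mirroring exclusion from the
    24-h rhythm analyses only.
    """
    rows = []
    for m in matrices:
        row = {"subject_id": m.subject_id, "n_valid_days": m.n_valid_days,
               "excluded_from_rar": m.excluded_from_rar}
        if not m.excluded_from_rar:
            valid = m.values[m.day_valid]
            t = np.tile(m.bin_midpoints_hours, valid.shape[0])
            y = valid.ravel()
            cos_fit = fit_cosinor(t, y)
            npm = npar_metrics(m)
            row.update(
                mesor=cos_fit.mesor, amplitude=cos_fit.amplitude,
                acrophase_hours=cos_fit.acrophase_hours,
                acrophase_clock=cos_fit.acrophase_clock,
                IS=npm.IS, IV=npm.IV, RA=npm.RA, M10=npm.M10, L5=npm.L5,
            )
        if sleep_by_subject and m.subject_id in sleep_by_subject:
            sp = sleep_by_subject[m.subject_id]
            row.update(TST=sp.TST, WASO=sp.WASO, SE=sp.SE, SOL=sp.SOL,
                       avg_wake_bout=sp.avg_wake_bout)
        rows.append(row)
    table = pd.DataFrame(rows)
    return covariates.merge(table, on="subject_id", how="right")


def comparison_table(metrics: pd.DataFrame, outcomes: list[str]) -> pd.DataFrame:
    """Group means +/- SD, unadjusted t-test, and adjusted B (SE) p per outcome."""
    rows = []
    for outcome in outcomes:
        if outcome not in metrics.columns:
            continue
        sub = metrics.dropna(subset=[outcome])
        pos = sub.loc[sub["abeta"] == "pos", outcome].to_numpy(float)
        neg = sub.loc[sub["abeta"] == "neg", outcome].to_numpy(float)
        unadj = compare_continuous(pos, neg, outcome=outcome)
        adj = adjusted_regression(sub, outcome)
        rows.append(
            {
                "outcome": outcome,
                "n_pos": len(pos), "n_neg": len(neg),
                "mean_all": float(np.concatenate([pos, neg]).mean()),
                "sd_all": float(np.concatenate([pos, neg]).std(ddof=1)),
                "mean_pos": unadj.mean_pos, "sd_pos": unadj.sd_pos,
                "mean_neg": unadj.mean_neg, "sd_neg": unadj.sd_neg,
                "t": unadj.statistic, "p_unadjusted": unadj.p_value,
                "B": adj.B, "B_se": adj.B_se, "p_adjusted": adj.B_p,
            }
        )
    return pd.DataFrame(rows)


def nominal_rest_intervals(
    subjects: list[EpochSeries], lights_out_hour: float = 23.0, rise_hour: float = 7.0
) -> list[RestInterval]:
    """Fixed-clock nightly in-bed intervals covering each subject's recording.

    A convenience for simulated cohorts, standing in for the diary/event-marker
    adjudication used with device data.
    """
    intervals = []
    for s in subjects:
        first_day = s.timestamps[0].astype("datetime64[D]")
        last = s.timestamps[-1]
        night = 0
        day = first_day
        while True:
            lights_out = day.astype("datetime64[s]") + np.timedelta64(
                int(lights_out_hour * 3600), "s"
            )
            out_of_bed = (day + 1).astype("datetime64[s]") + np.timedelta64(
                int(rise_hour * 3600), "s"
            )
            if out_of_bed > last:
                break
            intervals.append(
                RestInterval(
                    subject_id=s.subject_id, night=night,
                    lights_out=lights_out, out_of_bed=out_of_bed,
                )
            )
            night += 1
            day = day + 1
    return intervals


def sleep_metrics_by_subject(
    subjects: list[EpochSeries],
    intervals: list[RestInterval],
    threshold: float = 40.0,
    onset_minutes: float = 10.0,
) -> dict:
    """Score sleep/wake and average nightly parameters per subject."""
    by_subject: dict[str, list] = {}
    series_map = {s.subject_id: s for s in subjects}
    scored: dict[str, np.ndarray] = {}
    for iv in intervals:
        s = series_map.get(iv.subject_id)
        if s is None:
            continue
        if iv.subject_id not in scored:
            scored[iv.subject_id] = score_sleep_wake(s, threshold=threshold)
        params = sleep_parameters(
            scored[iv.subject_id], s.timestamps, iv,
            onset_minutes=onset_minutes, epoch_seconds=s.epoch_seconds,
        )
        by_subject.setdefault(iv.subject_id, []).append(params)
    return {sid: average_sleep_parameters(nights) for sid, nights in by_subject.items()}


# ------------------------------------------------------------ end-to-end run


@dataclass
class PipelineConfig:
    out_dir: str | Path = "run"
    sim: SimConfig | None = None
    epoch_csv: str | Path | None = None
    covariates_csv: str | Path | None = None
    rest_intervals_csv: str | Path | None = None
    use_nominal_rest_intervals: bool = True  # for simulated cohorts
    bin_minutes: tuple[int, ...] = (30, 60)
    min_valid_days: int = 3
    max_missing_fraction: float = 0.5
    n_basis: int = 8
    periodic: bool = False
    alpha: float = 0.05
    n_sim: int = 2000
    n_perm: int = 499
    seed: int = 0
    write_epochs: bool = False


RAR_OUTCOMES = ["amplitude", "mesor", "acrophase_hours", "RA", "IS", "IV"]
SLEEP_OUTCOMES = ["TST", "WASO", "avg_wake_bout", "SE", "SOL"]


def _float_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Any stage failure raises :class:`PipelineError` naming the stage; outputs
    written before the failure are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "actirar_version": __version__,
        "seed": config.seed,
        "bin_minutes": list(config.bin_minutes),
        "alpha": config.alpha,
        "n_sim": config.n_sim,
        "n_perm": config.n_perm,
        "stages": [],
    }

    # ---- input stage
    try:
        if config.sim is not None:
            sim = dataclasses.replace(config.sim, rng_seed=config.seed)
            cohort = generate_cohort(sim)
            subjects, covariates = cohort.subjects, cohort.covariates
            if config.write_epochs:
                write_cohort(cohort, out / "cohort", overwrite=True)
            manifest["input"] = {"kind": "simulated", "rng_seed": sim.rng_seed}
        else:
            subjects = read_epoch_csv(config.epoch_csv)
            covariates = read_covariates_csv(config.covariates_csv)
            manifest["input"] = {
                "kind": "files",
                "epoch_csv": str(config.epoch_csv),
                "covariates_csv": str(config.covariates_csv),
            }
        manifest["stages"].append("input")
    except Exception as err:
        raise PipelineError("input", err) from err

    # ---- sleep stage (epoch scale, independent of binning)
    sleep_by_subject = None
    try:
        if config.rest_intervals_csv is not None:
            intervals = read_rest_intervals_csv(config.rest_intervals_csv)
        elif config.sim is not None and config.use_nominal_rest_intervals:
            intervals = nominal_rest_intervals(subjects)
        else:
            intervals = []
        if intervals:
            sleep_by_subject = sleep_metrics_by_subject(subjects, intervals)
        manifest["stages"].append("sleep")
    except Exception as err:
        raise PipelineError("sleep", err) from err

    ftests = {}
    for bm in config.bin_minutes:
        tag = f"{bm}min"
        # ---- preprocessing
        try:
            matrices = [
                preprocess_subject(
                    s, bin_minutes=bm,
                    max_missing_fraction=config.max_missing_fraction,
                    min_valid_days=config.min_valid_days,
                )
                for s in subjects
            ]
            rars = [subject_rar(m) for m in matrices if not m.excluded_from_rar]
            write_subject_rars(rars, out / f"subject_rars_{tag}.csv")
            manifest["stages"].append(f"preprocess_{tag}")
        except Exception as err:
            raise PipelineError(f"preprocess_{tag}", err) from err

        # ---- scalar metrics and comparisons
        try:
            metrics = build_metrics_table(matrices, covariates, sleep_by_subject)
            _float_csv(metrics, out / f"metrics_{tag}.csv")
            _float_csv(
                comparison_table(metrics, RAR_OUTCOMES),
                out / f"rar_comparison_{tag}.csv",
            )
            if sleep_by_subject and bm == config.bin_minutes[0]:
                _float_csv(
                    comparison_table(metrics, SLEEP_OUTCOMES),
                    out / "sleep_comparison.csv",
                )
            manifest["stages"].append(f"metrics_{tag}")
        except Exception as err:
            raise PipelineError(f"metrics_{tag}", err) from err

        # ---- functional regression, mean and SD outcomes
        for outcome in ("mean", "sd"):
            try:
                design = build_design(
                    rars, covariates, outcome=outcome,
                    n_basis=config.n_basis, periodic=config.periodic,
                )
                fit = fit_fosr(design)
                rows, window_rows = [], []
                for name in design.col_names:
                    pw = pointwise_band(fit, name, alpha=config.alpha)
                    sim_band = simultaneous_band(
                        fit, name, alpha=config.alpha, n_sim=config.n_sim,
                        seed=config.seed + 1,
                    )
                    j = design.column(name)
                    for k, t in enumerate(design.grid):
                        rows.append(
                            (name, t, fit.coef[j][k], fit.se[j][k],
                             pw.lo[k], pw.hi[k], sim_band.lo[k], sim_band.hi[k])
                        )
                    if name != "intercept":
                        for kind, band in (("pointwise", pw), ("simultaneous", sim_band)):
                            for w in significant_windows(band, design.grid, bm):
                                window_rows.append(
                                    (name, kind, w.start_clock, w.end_clock,
                                     w.sign, w.n_bins)
                                )
                _float_csv(
                    pd.DataFrame(
                        rows,
                        columns=["covariate", "t_hours", "estimate", "se",
                                 "pointwise_lo", "pointwise_hi",
                                 "simultaneous_lo", "simultaneous_hi"],
                    ),
                    out / f"fosr_{outcome}_{tag}_coefficients.csv",
                )
                pd.DataFrame(
                    window_rows,
                    columns=["covariate", "band", "start_clock", "end_clock",
                             "sign", "n_bins"],
                ).to_csv(out / f"fosr_{outcome}_{tag}_windows.csv", index=False)
                f_stat, f_p = global_f_test(
                    design, "abeta", fit=fit, n_perm=config.n_perm,
                    seed=config.seed + 2,
                )
                ftests[f"{outcome}_{tag}"] = {
                    "F": f_stat, "p": f_p, "n_perm": config.n_perm,
                }
                manifest["stages"].append(f"fosr_{outcome}_{tag}")
            except Exception as err:
                raise PipelineError(f"fosr_{outcome}_{tag}", err) from err

    (out / "ftests.json").write_text(json.dumps(ftests, indent=2, sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
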