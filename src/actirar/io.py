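"""Plain-text I/O: epoch CSV, covariate CSV, rest intervals, profile tables.

Epoch CSV: ``subject_id,timestamp,activity_count,off_wrist`` with ISO-8601
local timestamps and non-negative integer counts. Covariates CSV:
``subject_id,age,sex,education_years,abeta`` with sex in {F,M} and abeta in
{pos,neg}. Rest-interval CSV: ``subject_id,night,lights_out,out_of_bed``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocessing import EpochSeries, SubjectRAR
from .simulate import CohortDataset, SimConfig, config_from_dict, config_to_dict
from .sleep import RestInterval

__all__ = [
    "write_cohort",
    "read_cohort",
    "read_epoch_csv",
    "read_covariates_csv",
    "read_rest_intervals_csv",
    "write_subject_rars",
    "read_subject_rars",
    "write_sim_config",
    "read_sim_config",
]

_TS_FORMAT = "%Y-%m-%dT%H:%M:%S"


def write_cohort(dataset: CohortDataset, directory, overwrite: bool = False) -> dict:
    """Write a simulated cohort as epochs.csv / covariates.csv / ground_truth.csv.

    Refuses to clobber an existing epoch file unless ``overwrite`` is set.
    Returns the mapping of logical names to paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "epochs": directory / "epochs.csv",
        "covariates": directory / "covariates.csv",
        "ground_truth": directory / "ground_truth.csv",
        "config": directory / "sim_config.yaml",
    }
    if paths["epochs"].exists() and not overwrite:
        raise FileExistsError(f"{paths['epochs']} exists; pass overwrite=True")

    frames = []
    for s in dataset.subjects:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": s.subject_id,
                    "timestamp": pd.Series(s.timestamps).dt.strftime(_TS_FORMAT),
                    "activity_count": s.values.astype(np.int64),
                    "off_wrist": s.off_wrist.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(paths["epochs"], index=False)
    dataset.covariates.to_csv(paths["covariates"], index=False)
    pd.DataFrame(
        {
            "bin_midpoint_hours": dataset.grid_hours,
            "mu_neg": dataset.mu_neg,
            "delta": dataset.delta,
            "sigma_neg": dataset.sigma_neg,
            "sigma_pos": dataset.sigma_pos,
        }
    ).to_csv(paths["ground_truth"], index=False, float_format="%.12g")
    write_sim_config(dataset.config, paths["config"])
    return paths


def read_cohort(directory) -> CohortDataset:
    """Re-read a cohort written by :func:`write_cohort` (lossless round trip)."""
    directory = Path(directory)
    covariates = read_covariates_csv(directory / "covariates.csv")
    subjects = read_epoch_csv(directory / "epochs.csv")
    order = {sid: k for k, sid in enumerate(covariates["subject_id"])}
    subjects.sort(key=lambda s: order.get(s.subject_id, len(order)))
    gt = pd.read_csv(directory / "ground_truth.csv")
    config = read_sim_config(directory / "sim_config.yaml")
    return CohortDataset(
        subjects=subjects,
        covariates=covariates,
        grid_hours=gt["bin_midpoint_hours"].to_numpy(),
        mu_neg=gt["mu_neg"].to_numpy(),
        delta=gt["delta"].to_numpy(),
        sigma_neg=gt["sigma_neg"].to_numpy(),
        sigma_pos=gt["sigma_pos"].to_numpy(),
        config=config,
    )


def read_epoch_csv(path) -> list[EpochSeries]:
    """Parse an epoch CSV into one EpochSeries per subject (file order)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "timestamp", "activity_count", "off_wrist"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing epoch CSV columns {sorted(missing)}")
    ts = pd.to_datetime(df["timestamp"], format=_TS_FORMAT).to_numpy().astype("datetime64[s]")
    series = []
    for sid, idx in df.groupby("subject_id", sort=False).groups.items():
        idx = np.asarray(idx)
        stamps = ts[idx]
        step = np.diff(stamps.astype(np.int64))
        epoch_seconds = int(step[0]) if step.size else 30
        series.append(
            EpochSeries(
                subject_id=str(sid),
                timestamps=stamps,
                values=df["activity_count"].to_numpy(np.int64)[idx],
                off_wrist=df["off_wrist"].to_numpy(bool)[idx],
                epoch_seconds=epoch_seconds,
            )
        )
    return series


def read_covariates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "age", "sex", "education_years", "abeta"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing covariate columns {sorted(missing)}")
    bad_sex = set(df["sex"].unique()) - {"F", "M"}
    bad_ab = set(df["abeta"].unique()) - {"pos", "neg"}
    if bad_sex or bad_ab:
        raise ValueError(f"{path}: unexpected codes sex={bad_sex} abeta={bad_ab}")
    if df["subject_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated subject_id rows")
    return df


def read_rest_intervals_csv(path) -> list[RestInterval]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    return [
        RestInterval(
            subject_id=row.subject_id,
            night=int(row.night),
            lights_out=pd.Timestamp(row.lights_out),
            out_of_bed=pd.Timestamp(row.out_of_bed),
        )
        for row in df.itertuples()
    ]


def write_subject_rars(rars: list[SubjectRAR], path) -> None:
    """Long-format CSV of mean and SD profiles (one row per subject x bin)."""
    rows = []
    for r in rars:
        for t, m, s in zip(r.bin_midpoints_hours, r.mean_profile, r.sd_profile):
            rows.append((r.subject_id, r.bin_minutes, t, m, s, r.n_valid_days))
    pd.DataFrame(
        rows,
        columns=["subject_id", "bin_minutes", "bin_midpoint_hours",
                 "mean_log_activity", "sd_log_activity", "n_valid_days"],
    ).to_csv(path, index=False, float_format="%.10g")


def read_subject_rars(path) -> list[SubjectRAR]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    rars = []
    for sid, sub in df.groupby("subject_id", sort=False):
        sub = sub.sort_values("bin_midpoint_hours")
        rars.append(
            SubjectRAR(
                subject_id=str(sid),
                bin_minutes=int(sub["bin_minutes"].iloc[0]),
                mean_profile=sub["mean_log_activity"].to_numpy(),
                sd_profile=sub["sd_log_activity"].to_numpy(),
                n_valid_days=int(sub["n_valid_days"].iloc[0]),
            )
        )
    return rars


def write_daily_profiles(matrix, path) -> None:
    """Wide-format per-subject profile CSV: rows=days, columns=bin start clocks."""
    from .utils import hours_to_clock

    starts = matrix.bin_midpoints_hours - matrix.bin_minutes / 120.0
    cols = [hours_to_clock(h) for h in starts]
    df = pd.DataFrame(matrix.values, columns=cols)
    df.insert(0, "date", matrix.dates.astype(str))
    df.insert(1, "day_valid", matrix.day_valid.astype(int))
    df.to_csv(path, index=False, float_format="%.10g")


def write_sim_config(config: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def read_sim_config(path) -> SimConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
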