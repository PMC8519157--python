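import numpy as np
import pytest

from actirar.preprocessing import EpochSeries
from actirar.simulate import SimConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_series(counts, subject_id="sub-x", epoch_seconds=30, start="2020-01-06",
                off_wrist=None):
    counts = np.asarray(counts)
    start = np.datetime64(start, "s")
    ts = start + (np.arange(len(counts), dtype=np.int64) * epoch_seconds).astype(
        "timedelta64[s]"
    )
    return EpochSeries(
        subject_id=subject_id,
        timestamps=ts,
        values=counts,
        off_wrist=off_wrist,
        epoch_seconds=epoch_seconds,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny but structurally complete simulated cohort (fast)."""
    config = SimConfig(
        n_group_pos=5, n_group_neg=6, day_range=(4, 6), day_weights=(0.2, 0.3, 0.5),
        rng_seed=7,
    )
    return generate_cohort(config)
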