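import numpy as np
import pandas as pd
import pytest

from tagflux import TimeCourse, generate_paperlike_dataset

# Published per-day pathway table used by the pass-through checks
# (day: starch, de novo direct, de novo via PLs, total measured).
TABLE1 = pd.DataFrame(
    {
        "from_starch": [0.0, 36.2, 46.6, 38.0, 37.2, 27.3, 24.0, 25.2],
        "de_novo_direct": [8.0, 7.5, 6.25, 3.75, 3.1, 2.5, 2.5, 1.25],
        "de_novo_via_pl": [0.0, 17.5, 20.2, 12.9, 11.0, 10.1, 10.0, 4.2],
        "total_measured": [38.0, 66.0, 74.0, 50.0, 44.0, 34.0, 28.0, 24.0],
    },
    index=pd.RangeIndex(1, 9, name="day"),
)


def make_timecourse(
    pools: dict,
    tracer: str = "bicarbonate",
    label_end: float | None = None,
    experiment: str = "toy",
    n_replicates: int = 1,
) -> TimeCourse:
    """Build a TimeCourse from {pool: {day: value}} with exact replicates."""
    records = [
        (pool, float(day), r, float(value))
        for pool, series in pools.items()
        for day, value in series.items()
        for r in range(n_replicates)
    ]
    units = (
        "nmol_C_per_1e6_cells" if tracer == "bicarbonate" else "pmol_PlA_per_1e6_cells"
    )
    return TimeCourse(
        experiment=experiment,
        tracer=tracer,
        units=units,
        data=pd.DataFrame(records, columns=["pool", "day", "replicate", "value"]),
        label_end=label_end,
    )


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    return TABLE1.copy()


@pytest.fixture(scope="session")
def noisefree_dataset():
    return generate_paperlike_dataset(seed=0, noise_cv=0.0, n_replicates=1)


@pytest.fixture(scope="session")
def noisy_dataset():
    return generate_paperlike_dataset(seed=7, noise_cv=0.10, n_replicates=3)
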