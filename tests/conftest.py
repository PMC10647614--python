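"""Shared fixtures.

The session-scoped benchmark run is expensive (full pipeline, three
scenarios, five replicate trainings, baselines, attribution) and is shared
by the model-level signal-recovery checks and the end-to-end ordering
checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cogstage.benchmark import run_benchmark
from cogstage.cohort import CohortConfig, MeasureSpec, generate_cohort
from cogstage.measures import MEASURES, TRAJECTORIES


@pytest.fixture(scope="session")
def benchmark_result():
    """One full reference-benchmark run (seed 1)."""
    return run_benchmark(seed=1)


def quiet_measure_specs(**overrides) -> dict[str, MeasureSpec]:
    """All-zero measure dynamics except explicit overrides; baselines kept."""
    from cogstage.cohort import default_measure_specs

    specs = {
        name: MeasureSpec(baseline=spec.baseline)
        for name, spec in default_measure_specs().items()
    }
    specs.update(overrides)
    return specs


@pytest.fixture
def tiny_cohort():
    """Two subjects per trajectory, 120 days, default dynamics."""
    config = CohortConfig(
        subjects_per_trajectory={t: 2 for t in TRAJECTORIES},
        n_days=120,
        seed=42,
    )
    return config, *generate_cohort(config)


def activity_frame(subject_id: str, values_by_measure: dict) -> pd.DataFrame:
    """Build a single-subject activity table; unspecified measures are 1.0."""
    lengths = {len(v) for v in values_by_measure.values()}
    assert len(lengths) == 1
    n = lengths.pop()
    table = {"subject_id": subject_id, "day_index": np.arange(n)}
    for m in MEASURES:
        table[m] = np.asarray(
            values_by_measure.get(m, np.ones(n)), dtype=float
        )
    return pd.DataFrame(table)
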