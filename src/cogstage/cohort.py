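"""Synthetic longitudinal activity cohort generator.

Emulates the kind of dataset produced by an in-home ambient-sensor platform
monitoring older adults: one row per subject per day carrying 13 activity
measures (dwell times, out-of-home episodes, sleep measures, walking
measures), plus per-subject demographics and sparse clinical assessment
points carrying a cognitive-stage determination (CH / MCI / SI).

Each measure series is simulated as

    value(t) = baseline + stage drift(t) + weekly cycle(t) + AR(1) noise(t)

truncated at zero, with count-valued measures rounded to integers. Stage
drift accumulates from the subject's latent transition day(s): e.g. walking
speed declines and sleep disturbance (WASO, trips out of bed) increases once
a subject starts degenerating. Six transition trajectories are supported:
CH, CH>TR, CH>TR>MCI, TR, TR>MCI, MCI.

The calendar is abstract: days are integer offsets from each subject's
baseline; weeks are fixed 7-day blocks, months 30 days, quarters 90, years
360.

Assessment points never carry the TR stage — TR is a label inferred *between*
a CH and a subsequent MCI assessment by the labeling module. The generator
therefore anchors a TR phase with a CH assessment the day before TR onset
and an MCI assessment at the conversion day; for subjects who are still
transitioning when monitoring ends (trajectories CH>TR and TR), the MCI
assessment is dated after the last activity day, and for subjects already
transitioning at baseline (TR, TR>MCI) the anchoring CH assessment is dated
before day 0. Assessment day indices outside the activity span are
legitimate: clinical status is established at clinic visits, not by the
sensor platform.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measures import COUNT_MEASURES, MEASURES, TRAJECTORIES

# Fixed block sizes of the abstract calendar.
WEEK_DAYS = 7
MONTH_DAYS = 30
QUARTER_DAYS = 90
YEAR_DAYS = 360


@dataclass
class Subject:
    subject_id: str
    age_at_baseline: float
    gender: str  # "male" | "female"
    education_years: float
    trajectory: str
    is_synthetic: bool = False


@dataclass
class MeasureSpec:
    """Simulation parameters for one activity measure.

    ``tr_*`` effects apply while the subject is in the TR stage, ``mci_*``
    while in MCI; slopes are per day of time spent in the stage, shifts are
    step changes on stage entry, and variance inflation scales the noise
    standard deviation (as a variance multiplier) within the stage.
    """

    baseline: float
    noise_sd: float = 0.0
    weekly_amp: float = 0.0
    tr_slope: float = 0.0
    mci_slope: float = 0.0
    tr_shift: float = 0.0
    mci_shift: float = 0.0
    tr_var_inflation: float = 1.0
    mci_var_inflation: float = 1.0


def default_measure_specs() -> dict[str, MeasureSpec]:
    """Reference measure parameterization.

    Baselines are plausible day-level values for community-dwelling adults
    aged 70+ (e.g. walking speed ~100 cm/s, total sleep ~7 h). The injected
    degeneration signal follows the clinical picture the analysis targets
    and is expressed through two channels:

    * gradual level drift — declining walking speed/count and out-of-home
      activity, rising sleep disturbance (WASO, latency, night-time trips
      out of bed, daytime sleep in the living room) and bedroom/bathroom
      dwell. Decline is continuous across the TR -> MCI transition (the
      shift is gradual, not a step), so a late-TR window and an early-MCI
      window look locally alike;
    * variance inflation — degenerating subjects become more *erratic*,
      most strongly in the sleep measures (day-to-day variability in sleep
      quantity and quality is an established decline marker), and more so
      in MCI than in TR. Variability changes leave daily means untouched,
      so they are visible to distributional window statistics but not to
      raw window averages.
    """
    return {
        "dwell_bathroom_s": MeasureSpec(1800, 400, 100, tr_slope=0.5, mci_slope=0.5),
        "dwell_bedroom_s": MeasureSpec(30000, 3000, 1000, tr_slope=4, mci_slope=4),
        "dwell_living_s": MeasureSpec(20000, 3000, 1500, tr_slope=-3, mci_slope=-3),
        "oth_count": MeasureSpec(
            2.0, 1.0, 0.5, tr_slope=-0.001, mci_slope=-0.001,
            tr_var_inflation=1.3, mci_var_inflation=1.5,
        ),
        "oth_total_s": MeasureSpec(7200, 2400, 1200, tr_slope=-2, mci_slope=-2),
        "sleep_living_s": MeasureSpec(
            1200, 600, 120, tr_slope=3, mci_slope=3,
            tr_var_inflation=2.5, mci_var_inflation=3.0,
        ),
        "sleep_trips_out_count": MeasureSpec(
            1.5, 0.8, 0.2, tr_slope=0.008, mci_slope=0.008,
            tr_var_inflation=2.5, mci_var_inflation=3.0,
        ),
        "sleep_total_s": MeasureSpec(
            25200, 1800, 600, tr_slope=-4, mci_slope=-4,
            tr_var_inflation=2.5, mci_var_inflation=3.0,
        ),
        "waso_s": MeasureSpec(
            1800, 400, 100, tr_slope=1.2, mci_slope=1.2,
            tr_var_inflation=2.5, mci_var_inflation=3.0,
        ),
        "sleep_latency_s": MeasureSpec(
            900, 300, 60, tr_slope=0.7, mci_slope=0.7,
            tr_var_inflation=2.5, mci_var_inflation=3.0,
        ),
        "walk_speed_variability": MeasureSpec(
            0.10, 0.02, 0.005, tr_slope=3e-5, mci_slope=3e-5,
            tr_var_inflation=1.5, mci_var_inflation=2.0,
        ),
        "walk_speed_cm_s": MeasureSpec(
            100.0, 4.0, 2.0, tr_slope=-0.015, mci_slope=-0.015,
            tr_var_inflation=1.5, mci_var_inflation=2.0,
        ),
        "walk_count": MeasureSpec(
            30, 5, 3, tr_slope=-0.004, mci_slope=-0.004,
            tr_var_inflation=1.3, mci_var_inflation=1.5,
        ),
    }


@dataclass
class CohortConfig:
    """Study conditions for one generated cohort."""

    subjects_per_trajectory: dict[str, int] = field(
        default_factory=lambda: {t: 5 for t in TRAJECTORIES}
    )
    n_days: int = 360
    measures: dict[str, MeasureSpec] = field(default_factory=default_measure_specs)
    ar_coef: float = 0.5
    #: Probability that an individual (subject, day, measure) cell is missing.
    missing_day_rate: float = 0.03
    #: Per-day probability that a contiguous missing block starts for a
    #: (subject, measure) series.
    missing_block_rate: float = 0.01
    block_len_min: int = 2
    block_len_max: int = 6
    assessment_interval_days: int = YEAR_DAYS
    seed: int = 0

    def validate(self) -> None:
        if self.n_days <= 0:
            raise ValueError(f"n_days must be positive, got {self.n_days}")
        for traj, n in self.subjects_per_trajectory.items():
            if traj not in TRAJECTORIES:
                raise ValueError(f"unknown trajectory key: {traj!r}")
            if n < 0:
                raise ValueError(f"negative subject count for {traj!r}")
        for name in self.measures:
            if name not in MEASURES:
                raise ValueError(f"unknown measure: {name!r}")
        for rate in (self.missing_day_rate, self.missing_block_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate {rate} outside [0, 1]")
        if not abs(self.ar_coef) < 1.0:
            raise ValueError(f"|ar_coef| must be < 1, got {self.ar_coef}")


def _transition_days(trajectory: str, n_days: int, rng: np.random.Generator):
    """Latent stage-onset schedule [(stage, onset_day), ...] for one subject.

    Single transitions are drawn uniformly from the middle 60% of the span;
    for the two-transition trajectory the TR onset falls in the first and
    the MCI onset in the second half of that middle band. Trajectories that
    start degenerated (TR, TR>MCI, MCI) have their first stage at day 0.
    """
    lo, hi = int(0.2 * n_days), int(0.8 * n_days)
    mid = (lo + hi) // 2
    if trajectory == "CH":
        return [("CH", 0)]
    if trajectory == "CH>TR":
        return [("CH", 0), ("TR", int(rng.integers(lo, hi)))]
    if trajectory == "CH>TR>MCI":
        t1 = int(rng.integers(lo, mid))
        t2 = int(rng.integers(mid + 1, hi + 1))
        return [("CH", 0), ("TR", t1), ("MCI", t2)]
    if trajectory == "TR":
        return [("TR", 0)]
    if trajectory == "TR>MCI":
        return [("TR", 0), ("MCI", int(rng.integers(lo, hi)))]
    if trajectory == "MCI":
        return [("MCI", 0)]
    raise ValueError(f"unknown trajectory key: {trajectory!r}")


def _assessment_schedule(trajectory, schedule, n_days, interval):
    """Assessment points (day, stage) anchoring the latent schedule.

    Routine assessments repeat every ``interval`` days while the latent stage
    is CH or MCI; a TR phase is bracketed by a CH assessment the day before
    onset and the MCI assessment at conversion (dated past the span end when
    conversion is unobserved).
    """
    points: list[tuple[int, str]] = []
    last_day = n_days - 1
    onsets = dict(schedule)
    if trajectory == "CH":
        points = [(d, "CH") for d in range(0, n_days, interval)]
    elif trajectory in ("CH>TR", "CH>TR>MCI"):
        t1 = onsets["TR"]
        points = [(d, "CH") for d in range(0, max(t1 - 1, 0), interval)]
        points.append((t1 - 1, "CH"))
        if trajectory == "CH>TR>MCI":
            t2 = onsets["MCI"]
            points.extend((d, "MCI") for d in range(t2, n_days, interval))
        else:
            points.append((last_day + 180, "MCI"))
    elif trajectory == "TR":
        points = [(-180, "CH"), (last_day + 180, "MCI")]
    elif trajectory == "TR>MCI":
        t2 = onsets["MCI"]
        points = [(-180, "CH")]
        points.extend((d, "MCI") for d in range(t2, n_days, interval))
    elif trajectory == "MCI":
        points = [(d, "MCI") for d in range(0, n_days, interval)]
    return sorted(set(points))


def _simulate_measure(spec, stages, ar_coef, rng):
    """One measure series over the latent per-day stage vector."""
    n = len(stages)
    is_tr = stages == 1
    is_mci = stages == 2
    # Cumulative drift: slope accrues per day spent in the stage, step
    # shifts apply from stage entry onward.
    per_day = np.where(is_tr, spec.tr_slope, 0.0) + np.where(is_mci, spec.mci_slope, 0.0)
    drift = np.cumsum(per_day)
    # Step shifts persist once the stage has been entered (stages are
    # monotone, so MCI retains an earlier TR shift).
    drift = drift + np.where(np.maximum.accumulate(is_tr), spec.tr_shift, 0.0)
    drift = drift + np.where(is_mci, spec.mci_shift, 0.0)
    week = spec.weekly_amp * np.sin(2 * np.pi * (np.arange(n) % WEEK_DAYS) / WEEK_DAYS)
    sd = spec.noise_sd * np.sqrt(
        np.where(is_mci, spec.mci_var_inflation, np.where(is_tr, spec.tr_var_inflation, 1.0))
    )
    # AR(1) with stationary marginal sd: innovation sd = sd * sqrt(1 - ar^2).
    z = rng.standard_normal(n)
    noise = np.empty(n)
    innov = z * sd * np.sqrt(1.0 - ar_coef**2)
    for t in range(n):
        noise[t] = z[0] * sd[0] if t == 0 else ar_coef * noise[t - 1] + innov[t]
    return spec.baseline + drift + week + noise


_STAGE_CODE = {"CH": 0, "TR": 1, "MCI": 2, "SI": 3}


def generate_cohort(config: CohortConfig):
    """Generate (subjects, activity records, assessment points).

    Returns three DataFrames: subjects (subject_id, age_at_baseline, gender,
    education_years, trajectory, is_synthetic), activity (subject_id,
    day_index, 13 measure columns), assessments (subject_id, day_index,
    stage). Identical config + seed reproduces identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    days = np.arange(config.n_days)

    subjects, activity, assessments = [], [], []
    sid_counter = 0
    for traj in TRAJECTORIES:
        n_subj = config.subjects_per_trajectory.get(traj, 0)
        for _ in range(n_subj):
            sid = f"S{sid_counter:04d}"
            sid_counter += 1
            age = float(np.clip(rng.normal(84.0, 7.0), 70.0, 105.0))
            gender = "female" if rng.random() < 0.78 else "male"
            edu = float(np.clip(rng.normal(15.0, 2.5), 8.0, 22.0))
            subjects.append(Subject(sid, round(age, 1), gender, round(edu, 1), traj))

            schedule = _transition_days(traj, config.n_days, rng)
            stage_per_day = np.zeros(config.n_days, dtype=int)
            for stage, onset in schedule:
                stage_per_day[days >= max(onset, 0)] = _STAGE_CODE[stage]

            table = {"subject_id": sid, "day_index": days}
            for name in MEASURES:
                spec = config.measures.get(name, MeasureSpec(0.0))
                series = _simulate_measure(spec, stage_per_day, config.ar_coef, rng)
                series = np.maximum(series, 0.0)
                if name == "sleep_total_s":
                    series = np.minimum(series, 86400.0)
                if name in COUNT_MEASURES:
                    series = np.rint(series)
                table[name] = series
            activity.append(pd.DataFrame(table))

            for day, stage in _assessment_schedule(
                traj, schedule, config.n_days, config.assessment_interval_days
            ):
                assessments.append({"subject_id": sid, "day_index": day, "stage": stage})

    subjects_df = pd.DataFrame([dataclasses.asdict(s) for s in subjects])
    if subjects_df.empty:
        subjects_df = pd.DataFrame(
            columns=["subject_id", "age_at_baseline", "gender", "education_years",
                     "trajectory", "is_synthetic"]
        )
    activity_df = (
        pd.concat(activity, ignore_index=True)
        if activity
        else pd.DataFrame(columns=["subject_id", "day_index", *MEASURES])
    )
    assessments_df = pd.DataFrame(
        assessments, columns=["subject_id", "day_index", "stage"]
    )
    return subjects_df, activity_df, assessments_df


def inject_missingness(
    records: pd.DataFrame,
    missing_day_rate: float,
    block_spec: dict | None = None,
    seed: int = 0,
):
    """Blank out measure cells: isolated days plus contiguous blocks.

    ``block_spec`` is ``{"rate": p, "min_len": a, "max_len": b}``: per
    (subject, measure) series, each day independently starts a missing block
    of uniform length in [a, b] with probability p. Returns (records with
    NaN holes, log DataFrame of the blanked positions). Deterministic under
    ``seed``; the original values are discarded.
    """
    if not 0.0 <= missing_day_rate <= 1.0:
        raise ValueError("missing_day_rate outside [0, 1]")
    block_spec = block_spec or {"rate": 0.0, "min_len": 2, "max_len": 6}
    if not 0.0 <= block_spec["rate"] <= 1.0:
        raise ValueError("block rate outside [0, 1]")

    out = records.copy()
    rng = np.random.default_rng(seed)
    present = [m for m in MEASURES if m in out.columns]
    mask = rng.random((len(out), len(present))) < missing_day_rate

    if block_spec["rate"] > 0 and len(out):
        for sid, idx in out.groupby("subject_id", sort=True).groups.items():
            pos = out.index.get_indexer(idx)
            n = len(pos)
            for j in range(len(present)):
                starts = np.flatnonzero(rng.random(n) < block_spec["rate"])
                for s in starts:
                    length = int(
                        rng.integers(block_spec["min_len"], block_spec["max_len"] + 1)
                    )
                    mask[pos[s : s + length], j] = True

    log_rows = []
    cols = out.columns.get_indexer(present)
    row_pos, col_pos = np.nonzero(mask)
    for r, c in zip(row_pos, col_pos):
        log_rows.append(
            {
                "subject_id": out.iat[r, out.columns.get_loc("subject_id")],
                "day_index": out.iat[r, out.columns.get_loc("day_index")],
                "measure": present[c],
            }
        )
        out.iat[r, cols[c]] = np.nan
    log = pd.DataFrame(log_rows, columns=["subject_id", "day_index", "measure"])
    return out, log


def save_tables(out_dir, subjects, activity, assessments) -> None:
    """Write the three cohort tables as UTF-8 CSV (empty field = missing)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects.to_csv(out / "subjects.csv", index=False)
    activity.to_csv(out / "activity.csv", index=False)
    assessments.to_csv(out / "assessments.csv", index=False)


def load_activity(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["day_index"] = df["day_index"].astype(int)
    return df
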