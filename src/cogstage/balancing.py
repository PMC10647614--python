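"""Sequence-level synthesis of whole subjects to balance the cohort.

Healthy subjects vastly outnumber degenerating ones in longitudinal aging
cohorts. Duplicating minority rows would break the temporal structure the
sequence model relies on, so balancing instead synthesizes entire new
subjects: each is emulated from one minority-class donor by (a) copying the
donor's stage timeline with a small random time shift, and (b) per measure,
fitting a transparent parametric model on the donor's series — level +
linear trend per stage segment with AR(1) residuals — and simulating a
fresh series from the fit. Demographics are jittered copies of the donor's.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .measures import COUNT_MEASURES, MEASURES, STAGE_SEVERITY

#: Maximum |time shift| (days) applied to a synthetic subject's stage timeline.
MAX_TIMELINE_SHIFT = 14


def _fit_segment(values: np.ndarray):
    """Level + linear trend + AR(1) residual fit for one stage segment."""
    n = len(values)
    t = np.arange(n, dtype=float)
    if n >= 2:
        slope, level = np.polyfit(t, values, 1)
    else:
        slope, level = 0.0, float(values[0]) if n else 0.0
    resid = values - (level + slope * t)
    var = resid.var()
    if n >= 3 and var > 0:
        phi = float(np.corrcoef(resid[:-1], resid[1:])[0, 1])
        phi = float(np.clip(np.nan_to_num(phi), -0.95, 0.95))
    else:
        phi = 0.0
    sd = float(np.sqrt(var))
    return level, slope, phi, sd


def _simulate_segment(level, slope, phi, sd, n, rng):
    t = np.arange(n, dtype=float)
    noise = np.zeros(n)
    innov_sd = sd * np.sqrt(max(1.0 - phi**2, 0.0))
    for i in range(n):
        noise[i] = sd * rng.standard_normal() if i == 0 else (
            phi * noise[i - 1] + innov_sd * rng.standard_normal()
        )
    return level + slope * t + noise


def synthesize_subjects(
    donors: pd.DataFrame,
    records: pd.DataFrame,
    timelines: pd.DataFrame,
    n_new: dict[str, int],
    seed: int = 0,
):
    """Create ``n_new[trajectory]`` synthetic subjects per trajectory.

    ``donors`` is a subjects table, ``records`` their (fully imputed)
    activity table, ``timelines`` their per-day stage labels. Returns
    (subjects, activity records, timelines) for the synthetic subjects,
    with ``is_synthetic`` set and ids prefixed ``SYN``. Deterministic under
    ``seed``; requesting a trajectory with no donor raises ``ValueError``.
    """
    rng = np.random.default_rng(seed)
    present = [m for m in MEASURES if m in records.columns]
    new_subjects, new_records, new_timelines = [], [], []
    counter = 0
    for traj in sorted(n_new):
        count = n_new[traj]
        if count == 0:
            continue
        pool = donors[donors["trajectory"] == traj]
        if pool.empty:
            raise ValueError(f"no donor subjects for trajectory {traj!r}")
        for _ in range(count):
            donor = pool.iloc[int(rng.integers(len(pool)))]
            did = donor["subject_id"]
            sid = f"SYN{counter:04d}"
            counter += 1

            d_tl = timelines[timelines["subject_id"] == did].sort_values("day_index")
            d_rec = records[records["subject_id"] == did].sort_values("day_index")
            days = d_tl["day_index"].to_numpy()
            stages = d_tl["stage"].to_numpy()

            # Shift stage boundaries by a small uniform offset; day 0 and the
            # final day stay anchored so the span is unchanged.
            shift = int(rng.integers(-MAX_TIMELINE_SHIFT, MAX_TIMELINE_SHIFT + 1))
            sev = np.array([STAGE_SEVERITY[s] for s in stages])
            new_sev = np.empty_like(sev)
            for i, d in enumerate(days):
                src = np.clip(d - shift, days.min(), days.max())
                new_sev[i] = sev[np.searchsorted(days, src)]
            new_sev = np.maximum.accumulate(new_sev)  # keep monotone
            inv = {v: k for k, v in STAGE_SEVERITY.items()}
            new_stages = np.array([inv[v] for v in new_sev])

            # Per measure: fit per donor-stage segment, simulate over the
            # shifted segments.
            table = {"subject_id": sid, "day_index": days}
            donor_stage_per_day = stages
            for m in present:
                vals = d_rec[m].to_numpy(dtype=float)
                fits = {}
                for s in dict.fromkeys(donor_stage_per_day):
                    seg = vals[donor_stage_per_day == s]
                    fits[s] = _fit_segment(seg)
                sim = np.empty(len(days))
                for s in dict.fromkeys(new_stages):
                    mask = new_stages == s
                    fit = fits.get(s) or next(iter(fits.values()))
                    sim[mask] = _simulate_segment(*fit, int(mask.sum()), rng)
                sim = np.maximum(sim, 0.0)
                if m == "sleep_total_s":
                    sim = np.minimum(sim, 86400.0)
                if m in COUNT_MEASURES:
                    sim = np.rint(sim)
                table[m] = sim
            new_records.append(pd.DataFrame(table))
            new_timelines.append(
                pd.DataFrame(
                    {"subject_id": sid, "day_index": days, "stage": new_stages}
                )
            )
            new_subjects.append(
                {
                    "subject_id": sid,
                    "age_at_baseline": round(
                        float(max(70.0, donor["age_at_baseline"] + rng.normal(0, 2))), 1
                    ),
                    "gender": donor["gender"],
                    "education_years": round(
                        float(max(0.0, donor["education_years"] + rng.normal(0, 1))), 1
                    ),
                    "trajectory": traj,
                    "is_synthetic": True,
                }
            )

    cols = ["subject_id", "age_at_baseline", "gender", "education_years",
            "trajectory", "is_synthetic"]
    subjects_df = pd.DataFrame(new_subjects, columns=cols)
    records_df = (
        pd.concat(new_records, ignore_index=True)
        if new_records
        else pd.DataFrame(columns=["subject_id", "day_index", *present])
    )
    timelines_df = (
        pd.concat(new_timelines, ignore_index=True)
        if new_timelines
        else pd.DataFrame(columns=["subject_id", "day_index", "stage"])
    )
    return subjects_df, records_df, timelines_df


def balance_report(sizes_before: dict[str, int], sizes_after: dict[str, int]) -> pd.DataFrame:
    """Group sizes and majority/minority imbalance ratio before vs after.

    An empty minority group yields an infinite ratio (flagged as ``inf``).
    """
    def ratio(sizes):
        vals = list(sizes.values())
        if not vals:
            return float("nan")
        mn = min(vals)
        return float("inf") if mn == 0 else max(vals) / mn

    rows = []
    for phase, sizes in (("before", sizes_before), ("after", sizes_after)):
        row = {"phase": phase, **sizes, "imbalance_ratio": ratio(sizes)}
        rows.append(row)
    return pd.DataFrame(rows)
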