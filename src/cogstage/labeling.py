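"""Per-day cognitive-stage ground truth and subject grouping.

Clinical assessments determine the stage (CH / MCI / SI) only at discrete
visit dates; the decline from healthy cognition to MCI is gradual, so every
day strictly between a subject's last CH assessment and the first subsequent
MCI assessment is labeled with the bespoke intermediate stage TR
("transitioning"). Elsewhere a day inherits the stage of the most recent
assessment (days before the first assessment inherit its stage). Stages can
only worsen over time (CH -> TR -> MCI -> SI); assessments violating that
order are rejected.

Subjects are grouped by their observed trajectory: CH -> cognitively
healthy; {CH>TR, TR} -> transitioning to MCI; {CH>TR>MCI, TR>MCI, MCI} ->
mild cognitive impairment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .measures import STAGE_SEVERITY, TRAJECTORIES, TRAJECTORY_GROUP, GROUPS


class InconsistentAssessmentError(ValueError):
    """Assessment stages improve over time, which the model rules out."""


def label_timeline(assessments: pd.DataFrame, day_span) -> pd.DataFrame:
    """Ground-truth stage for every day in ``day_span`` for one subject.

    ``assessments`` holds the subject's (day_index, stage) rows with stage
    in {CH, MCI, SI}; ``day_span`` is an iterable of day indices to label
    (the subject's activity days). Assessment days may lie outside the span:
    a conversion established at a clinic visit after monitoring ended still
    anchors the TR phase inside it. Returns (subject_id, day_index, stage).
    """
    if len(assessments) == 0:
        raise ValueError("at least one assessment point is required")
    a = assessments.sort_values("day_index").reset_index(drop=True)
    sev = a["stage"].map(STAGE_SEVERITY)
    if sev.isna().any():
        bad = a.loc[sev.isna(), "stage"].tolist()
        raise ValueError(f"unknown assessment stage(s): {bad}")
    if (np.diff(sev.to_numpy()) < 0).any():
        raise InconsistentAssessmentError(
            "assessment stages must never improve over time"
        )

    days = np.asarray(sorted(day_span), dtype=int)
    a_days = a["day_index"].to_numpy()
    a_stages = a["stage"].to_numpy()

    # Most recent assessment at or before each day; before the first
    # assessment, inherit the first stage.
    idx = np.searchsorted(a_days, days, side="right") - 1
    stages = a_stages[np.clip(idx, 0, None)]

    # TR: days strictly between the last CH assessment and the first
    # subsequent MCI assessment.
    ch_days = a_days[a_stages == "CH"]
    mci_days = a_days[a_stages == "MCI"]
    if len(ch_days) and len(mci_days):
        last_ch = ch_days.max()
        after = mci_days[mci_days > last_ch]
        if len(after):
            first_mci = after.min()
            stages = np.where(
                (days > last_ch) & (days < first_mci), "TR", stages
            )

    sid = a["subject_id"].iloc[0] if "subject_id" in a else None
    return pd.DataFrame(
        {"subject_id": sid, "day_index": days, "stage": stages}
    )


def label_cohort(assessments: pd.DataFrame, activity: pd.DataFrame) -> pd.DataFrame:
    """label_timeline applied to every subject present in ``activity``."""
    frames = []
    for sid, act in activity.groupby("subject_id", sort=True):
        a = assessments[assessments["subject_id"] == sid]
        frames.append(label_timeline(a, act["day_index"].tolist()))
    if not frames:
        return pd.DataFrame(columns=["subject_id", "day_index", "stage"])
    return pd.concat(frames, ignore_index=True)


def derive_trajectory(timeline: pd.DataFrame) -> str:
    """Render a per-day stage timeline as one of the six trajectories.

    SI days (excluded from model targets) are ignored for the trajectory
    name; e.g. a timeline ending in SI after MCI is still trajectory "MCI".
    """
    if len(timeline) == 0:
        raise ValueError("empty timeline")
    ordered = timeline.sort_values("day_index")["stage"]
    distinct = list(dict.fromkeys(s for s in ordered if s != "SI"))
    name = ">".join(distinct)
    if name not in TRAJECTORIES:
        raise ValueError(f"timeline yields unknown trajectory {name!r}")
    return name


def assign_groups(trajectories: dict[str, str]) -> pd.DataFrame:
    """Partition subjects into the three study groups.

    ``trajectories`` maps subject_id -> trajectory label. Returns a
    DataFrame (group, subject_id); every group appears, possibly empty.
    """
    rows = []
    for sid, traj in trajectories.items():
        if traj not in TRAJECTORY_GROUP:
            raise ValueError(f"unknown trajectory {traj!r} for subject {sid!r}")
        rows.append({"group": TRAJECTORY_GROUP[traj], "subject_id": sid})
    df = pd.DataFrame(rows, columns=["group", "subject_id"])
    # Stable group ordering with empty groups retained.
    df["group"] = pd.Categorical(df["group"], categories=GROUPS)
    return df.sort_values(["group", "subject_id"]).reset_index(drop=True)


def group_sizes(groups: pd.DataFrame) -> dict[str, int]:
    counts = groups.groupby("group", observed=False)["subject_id"].count()
    return {g: int(counts.get(g, 0)) for g in GROUPS}
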