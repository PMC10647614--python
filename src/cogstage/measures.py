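"""Registry of the day-level activity measures and their groupings.

The monitored quantities are digital biomarkers derived from ambient in-home
sensors (passive infrared motion sensors, contact switches): room dwell
times, out-of-home episodes, sleep quality/quantity measures, and walking
measures. Each is recorded once per subject per day, in the units given
below, and belongs to one of four activity categories (dwell, out-of-home,
sleep, walk) used for the category-ablation experiments.
"""

from __future__ import annotations

# Measure names, in the fixed column order used throughout the package.
# Units are encoded in the suffix: _s seconds, _count counts, cm_s cm/second.
DWELL_MEASURES = [
    "dwell_bathroom_s",
    "dwell_bedroom_s",
    "dwell_living_s",
]
OTH_MEASURES = [
    "oth_count",
    "oth_total_s",
]
SLEEP_MEASURES = [
    "sleep_living_s",
    "sleep_trips_out_count",
    "sleep_total_s",
    "waso_s",
    "sleep_latency_s",
]
WALK_MEASURES = [
    "walk_speed_variability",
    "walk_speed_cm_s",
    "walk_count",
]

MEASURES = DWELL_MEASURES + OTH_MEASURES + SLEEP_MEASURES + WALK_MEASURES

CATEGORIES = {
    "dwell": DWELL_MEASURES,
    "oth": OTH_MEASURES,
    "sleep": SLEEP_MEASURES,
    "walk": WALK_MEASURES,
}

#: Measures that are semantically integer counts (rounded after simulation).
COUNT_MEASURES = {"oth_count", "sleep_trips_out_count", "walk_count"}

#: The six per-window time-series statistics, in fixed order.
TS_STATS = ["median", "mean", "std", "varcoeff", "skew", "kurtosis"]

#: Demographic feature columns appended to every window row.
DEMOGRAPHICS = ["age", "gender", "edu"]

#: Cognitive stages in severity order (a subject never improves).
STAGES = ["CH", "TR", "MCI", "SI"]
STAGE_SEVERITY = {s: i for i, s in enumerate(STAGES)}

#: The classifier's target classes, in the fixed one-hot order.
TARGET_STAGES = ["CH", "TR", "MCI"]

#: The six admissible stage-transition trajectories.
TRAJECTORIES = ["CH", "CH>TR", "CH>TR>MCI", "TR", "TR>MCI", "MCI"]

#: Trajectory -> subject-group rule.
TRAJECTORY_GROUP = {
    "CH": "cognitively_healthy",
    "CH>TR": "transitioning_to_MCI",
    "TR": "transitioning_to_MCI",
    "CH>TR>MCI": "mild_cognitive_impairment",
    "TR>MCI": "mild_cognitive_impairment",
    "MCI": "mild_cognitive_impairment",
}
GROUPS = [
    "cognitively_healthy",
    "transitioning_to_MCI",
    "mild_cognitive_impairment",
]


def measures_for_categories(categories) -> list[str]:
    """Expand a set of category names into the measure list, in fixed order.

    Raises ``ValueError`` on an unknown category or an empty selection.
    """
    cats = [c.lower() for c in categories]
    if not cats:
        raise ValueError("category set must be non-empty")
    unknown = [c for c in cats if c not in CATEGORIES]
    if unknown:
        raise ValueError(f"unknown activity categories: {unknown}")
    return [m for m in MEASURES if any(m in CATEGORIES[c] for c in cats)]
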