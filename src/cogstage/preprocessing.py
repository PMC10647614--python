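"""Record cleanup and hierarchical block-average imputation.

Cleanup drops, in order: exactly duplicated rows; all rows of subjects with
no clinical assessment data; all rows of subjects whose overall fraction of
missing measure cells reaches a threshold (default 0.80); and individual
rows with (almost) all measures blank (default 0.90).

Imputation fills a missing day from the subject's own observed block
averages, escalating week (7-day block) -> month (30) -> quarter (90) ->
year (360) until an observed average exists; this preserves the subject's
activity trend rather than smearing neighbours' values. Observed cells are
never altered, and imputation is idempotent. A (subject, measure) with no
observation anywhere cannot be imputed and raises ``UnimputableError``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import MONTH_DAYS, QUARTER_DAYS, WEEK_DAYS, YEAR_DAYS
from .measures import MEASURES

logger = logging.getLogger(__name__)

BLOCK_SIZES = {
    "week": WEEK_DAYS,
    "month": MONTH_DAYS,
    "quarter": QUARTER_DAYS,
    "year": YEAR_DAYS,
}
#: Escalation order for the imputation fallback.
BLOCK_LEVELS = ["week", "month", "quarter", "year"]


class UnimputableError(ValueError):
    """A (subject, measure) series has zero observed values anywhere."""


def clean_records(
    records: pd.DataFrame,
    subjects: pd.DataFrame,
    assessments: pd.DataFrame,
    subject_missing_threshold: float = 0.80,
    record_blank_threshold: float = 0.90,
):
    """Apply the four cleanup rules; returns (clean records, removal log).

    The log has one row per dropped subject or record with the rule that
    fired. Thresholds are fractions in [0, 1].
    """
    for thr in (subject_missing_threshold, record_blank_threshold):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"threshold {thr} outside [0, 1]")
    log_rows: list[dict] = []
    if records.empty:
        logger.warning("clean_records received an empty activity table")
        return records.copy(), pd.DataFrame(columns=["rule", "subject_id", "day_index"])

    out = records.copy()
    present = [m for m in MEASURES if m in out.columns]

    # Rule 1: exact duplicates (equality on all columns; NaNs compare equal
    # for this purpose via the key tuple).
    dup = out.duplicated(keep="first")
    for _, row in out[dup].iterrows():
        log_rows.append(
            {"rule": "duplicate", "subject_id": row["subject_id"],
             "day_index": row["day_index"]}
        )
    out = out[~dup]

    # Rule 2: subjects with no assessment rows.
    assessed = set(assessments["subject_id"]) if len(assessments) else set()
    no_assess = sorted(set(out["subject_id"]) - assessed)
    for sid in no_assess:
        log_rows.append({"rule": "no_assessment", "subject_id": sid, "day_index": None})
    out = out[out["subject_id"].isin(assessed)]

    # Rule 3: subjects missing >= threshold of their measure cells overall.
    if len(out):
        frac = out.groupby("subject_id")[present].apply(
            lambda g: g.isna().to_numpy().mean()
        )
        too_sparse = sorted(frac[frac >= subject_missing_threshold].index)
        for sid in too_sparse:
            log_rows.append(
                {"rule": "subject_mostly_missing", "subject_id": sid, "day_index": None}
            )
        out = out[~out["subject_id"].isin(too_sparse)]

    # Rule 4: individual records with >= threshold of measures blank.
    if len(out):
        row_frac = out[present].isna().mean(axis=1)
        blank = out[row_frac >= record_blank_threshold]
        for _, row in blank.iterrows():
            log_rows.append(
                {"rule": "record_mostly_blank", "subject_id": row["subject_id"],
                 "day_index": row["day_index"]}
            )
        out = out[row_frac < record_blank_threshold]

    log = pd.DataFrame(log_rows, columns=["rule", "subject_id", "day_index"])
    return out.reset_index(drop=True), log


def build_reference_averages(records: pd.DataFrame) -> pd.DataFrame:
    """Per-subject observed-value means by week/month/quarter/year block.

    Returns a long DataFrame (subject_id, measure, level, block, mean);
    blocks with zero observations are absent.
    """
    present = [m for m in MEASURES if m in records.columns]
    frames = []
    for level, size in BLOCK_SIZES.items():
        block = records["day_index"] // size
        melted = records[["subject_id", *present]].assign(block=block).melt(
            id_vars=["subject_id", "block"], var_name="measure", value_name="value"
        )
        grp = (
            melted.dropna(subset=["value"])
            .groupby(["subject_id", "measure", "block"], as_index=False)["value"]
            .mean()
            .rename(columns={"value": "mean"})
        )
        grp["level"] = level
        frames.append(grp)
    if not frames:
        return pd.DataFrame(columns=["subject_id", "measure", "level", "block", "mean"])
    return pd.concat(frames, ignore_index=True)[
        ["subject_id", "measure", "level", "block", "mean"]
    ]


def impute_missing(records: pd.DataFrame, reference: pd.DataFrame):
    """Fill missing cells from block averages; returns (records, log).

    A missing (subject, day, measure) cell takes its week-block mean; if the
    whole week is unobserved, the month mean, then quarter, then year. If
    even the year block holds no observation the subject-measure overall
    mean is used (final fallback). Observed cells pass through bit-identical.
    """
    present = [m for m in MEASURES if m in records.columns]
    out = records.copy()
    # level -> {(subject, measure, block): mean}
    lookup = {
        level: sub.set_index(["subject_id", "measure", "block"])["mean"].to_dict()
        for level, sub in reference.groupby("level")
    }
    overall = (
        out.melt(
            id_vars=["subject_id", "day_index"],
            value_vars=present,
            var_name="measure",
        )
        .dropna(subset=["value"])
        .groupby(["subject_id", "measure"])["value"]
        .mean()
        .to_dict()
    )

    log_rows = []
    for measure in present:
        col = out[measure]
        miss = np.flatnonzero(col.isna().to_numpy())
        for r in miss:
            sid = out.iat[r, out.columns.get_loc("subject_id")]
            day = out.iat[r, out.columns.get_loc("day_index")]
            filled = None
            for level in BLOCK_LEVELS:
                key = (sid, measure, day // BLOCK_SIZES[level])
                if key in lookup.get(level, {}):
                    filled = (level, lookup[level][key])
                    break
            if filled is None:
                if (sid, measure) in overall:
                    filled = ("overall", overall[(sid, measure)])
                else:
                    raise UnimputableError(
                        f"no observed values anywhere for subject {sid!r}, "
                        f"measure {measure!r}"
                    )
            out.iat[r, out.columns.get_loc(measure)] = filled[1]
            log_rows.append(
                {"subject_id": sid, "day_index": day, "measure": measure,
                 "level": filled[0], "value": filled[1]}
            )
    log = pd.DataFrame(
        log_rows, columns=["subject_id", "day_index", "measure", "level", "value"]
    )
    return out, log
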