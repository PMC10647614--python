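"""Window-level feature engineering: TS statistics, DTW distances, assembly.

Each subject's per-measure daily series is segmented with a sliding window
(default 10 days, stride 3 ~ 75% overlap) and summarized by six time-series
statistics per window (median, mean, sample SD, coefficient of variation,
adjusted skewness, excess kurtosis). Inter-subject context is added as
dynamic-time-warping distances between each subject's full-length measure
series and every reference-cohort subject's series. A window row is the
concatenation of TS statistics (grouped by measure), DTW distances (grouped
by measure, constant across the subject's rows), and demographics (age,
gender, education). The row's label is the cognitive stage on the window's
last day; SI-labeled windows are dropped since the classifier is 3-class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .measures import DEMOGRAPHICS, MEASURES, TS_STATS, measures_for_categories

logger = logging.getLogger(__name__)

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: 10-day windows every 3 days by default.

    A 75% overlap of a 10-day window is a 2.5-day skip; the stride is
    rounded to whole days (3), giving an actual overlap of 7 days.
    """

    window_length: int = 10
    stride: int = 3

    def __post_init__(self):
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if not 1 <= self.stride <= self.window_length:
            raise ValueError("stride must be in [1, window_length]")


def sliding_windows(series_length: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Inclusive (start, end) index pairs: [s, s+L-1] for s = 0, stride, ...

    A series shorter than one window yields an empty list.
    """
    if series_length < 0:
        raise ValueError("series_length must be >= 0")
    L = spec.window_length
    if series_length < L:
        logger.warning(
            "series length %d shorter than window %d: no windows", series_length, L
        )
        return []
    return [(s, s + L - 1) for s in range(0, series_length - L + 1, spec.stride)]


def compute_ts_stats(values) -> dict[str, float]:
    """The six per-window statistics of one measure.

    SD is the sample standard deviation (n-1); the coefficient of variation
    is SD/mean, defined as 0 for a constant window and flagged to 0 when the
    mean is 0; skewness is the adjusted Fisher-Pearson coefficient and
    kurtosis the bias-adjusted excess kurtosis, both 0 for constant windows
    (and for windows too short for the bias adjustment).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("window must be a 1-d array of length >= 2")
    if np.isnan(x).any():
        raise ValueError("window contains missing values; impute first")
    mean = float(np.mean(x))
    std = float(np.std(x, ddof=1))
    if std == 0.0:
        varcoeff = skew = kurt = 0.0
    else:
        if mean == 0.0:
            logger.warning("zero-mean window: coefficient of variation set to 0")
            varcoeff = 0.0
        else:
            varcoeff = std / mean
        skew = float(sps.skew(x, bias=False)) if len(x) >= 3 else 0.0
        kurt = float(sps.kurtosis(x, fisher=True, bias=False)) if len(x) >= 4 else 0.0
    return {
        "median": float(np.median(x)),
        "mean": mean,
        "std": std,
        "varcoeff": varcoeff,
        "skew": 0.0 if np.isnan(skew) else skew,
        "kurtosis": 0.0 if np.isnan(kurt) else kurt,
    }


def _window_stats_array(series: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Vectorized six-statistic table, one row per sliding window.

    Equivalent to :func:`compute_ts_stats` applied per window (column order
    = TS_STATS); used for bulk feature assembly.
    """
    L = spec.window_length
    W = np.lib.stride_tricks.sliding_window_view(series, L)[:: spec.stride]
    mean = W.mean(axis=1)
    std = W.std(axis=1, ddof=1)
    median = np.median(W, axis=1)
    const = std == 0.0
    zero_mean = (mean == 0.0) & ~const
    # Near-constant windows (common for counts) trip benign precision
    # warnings inside the moment computations; their outputs are fixed to 0
    # below anyway.
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        varcoeff = np.where(const | zero_mean, 0.0, std / np.where(mean == 0, 1, mean))
        skew = np.where(const, 0.0, np.nan_to_num(sps.skew(W, axis=1, bias=False)))
        kurt = np.where(
            const, 0.0, np.nan_to_num(sps.kurtosis(W, axis=1, fisher=True, bias=False))
        )
    return np.column_stack([median, mean, std, varcoeff, skew, kurt])


@njit(cache=False)
def _dtw_core(a, b):  # pragma: no cover - exercised through dtw_distance
    n, m = len(a), len(b)
    D = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            cost = abs(a[i] - b[j])
            if i == 0 and j == 0:
                D[i, j] = cost
            elif i == 0:
                D[i, j] = cost + D[i, j - 1]
            elif j == 0:
                D[i, j] = cost + D[i - 1, j]
            else:
                best = D[i - 1, j - 1]
                if D[i - 1, j] < best:
                    best = D[i - 1, j]
                if D[i, j - 1] < best:
                    best = D[i, j - 1]
                D[i, j] = cost + best
    return D[n - 1, m - 1]


def dtw_distance(series_a, series_b) -> float:
    """Classic unconstrained DTW distance with absolute-difference cost.

    Dynamic program D(i,j) = |a_i - b_j| + min(D(i-1,j), D(i,j-1),
    D(i-1,j-1)); no warping-window constraint, no path normalization.
    Handles unequal lengths; empty input is an error.
    """
    a = np.ascontiguousarray(series_a, dtype=np.float64)
    b = np.ascontiguousarray(series_b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("DTW requires non-empty series")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("DTW input contains missing values; impute first")
    return float(_dtw_core(a, b))


def dtw_feature_block(
    subject_id: str,
    series_by_subject: dict[str, pd.DataFrame],
    reference_ids: list[str],
    measures: list[str] | None = None,
) -> pd.Series:
    """Distances from one subject's full series to every reference subject.

    ``series_by_subject`` maps subject_id -> day-sorted activity frame.
    Returns a Series indexed ``dtw_<measure>_<ref>`` in fixed (measure-major,
    reference-order) layout; the self-distance 0 is included so the feature
    dimensionality is N_reference x n_measures for every subject.
    """
    if subject_id not in series_by_subject:
        raise KeyError(f"unknown subject {subject_id!r}")
    measures = measures or [
        m for m in MEASURES if m in series_by_subject[subject_id].columns
    ]
    own = series_by_subject[subject_id]
    out = {}
    for m in measures:
        a = own[m].to_numpy(dtype=float)
        for ref in reference_ids:
            if ref == subject_id:
                out[f"dtw_{m}_{ref}"] = 0.0
            else:
                b = series_by_subject[ref][m].to_numpy(dtype=float)
                out[f"dtw_{m}_{ref}"] = dtw_distance(a, b)
    return pd.Series(out)


def dtw_distance_matrix(series_by_subject, subject_ids, measures):
    """Symmetric pairwise DTW per measure; returns {measure: DataFrame}."""
    mats = {}
    for m in measures:
        arrs = {s: series_by_subject[s][m].to_numpy(dtype=float) for s in subject_ids}
        n = len(subject_ids)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = dtw_distance(arrs[subject_ids[i]], arrs[subject_ids[j]])
                D[i, j] = D[j, i] = d
        mats[m] = pd.DataFrame(D, index=subject_ids, columns=subject_ids)
    return mats


GENDER_CODE = {"male": 0.0, "female": 1.0}


def assemble_feature_matrix(
    subject: pd.Series,
    activity: pd.DataFrame,
    timeline: pd.DataFrame,
    dtw_block: pd.Series,
    spec: WindowSpec = WindowSpec(),
) -> pd.DataFrame:
    """Per-window feature rows + label for one subject.

    Column order: ``<measure>_<stat>`` grouped by measure, then the DTW
    block, then age, gender (male=0, female=1), edu. Adds bookkeeping
    columns (subject_id, window_index, start_day, end_day, label); the
    label is the stage of the window's last day and SI windows are dropped.
    """
    act = activity.sort_values("day_index").reset_index(drop=True)
    tl = timeline.set_index("day_index")["stage"]
    present = [m for m in MEASURES if m in act.columns]
    windows = sliding_windows(len(act), spec)

    stats_by_measure = {}
    for m in present:
        series = act[m].to_numpy(dtype=float)
        if np.isnan(series).any():
            raise ValueError(f"measure {m} contains missing values; impute first")
        stats_by_measure[m] = _window_stats_array(series, spec) if windows else None

    rows = []
    for w, (s, e) in enumerate(windows):
        row: dict[str, float] = {}
        for m in present:
            for col, stat in enumerate(TS_STATS):
                row[f"{m}_{stat}"] = float(stats_by_measure[m][w, col])
        row.update(dtw_block.to_dict())
        row["age"] = float(subject["age_at_baseline"])
        row["gender"] = GENDER_CODE[subject["gender"]]
        row["edu"] = float(subject["education_years"])
        end_day = int(act["day_index"].iloc[e])
        label = tl.loc[end_day]
        row.update(
            subject_id=subject["subject_id"], window_index=w,
            start_day=int(act["day_index"].iloc[s]), end_day=end_day, label=label,
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df[df["label"] != "SI"].reset_index(drop=True)
    meta = ["subject_id", "window_index", "start_day", "end_day", "label"]
    feat_cols = [c for c in df.columns if c not in meta]
    return df[meta + feat_cols]


META_COLUMNS = ["subject_id", "window_index", "start_day", "end_day", "label"]


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c not in META_COLUMNS]


def select_scenario_features(
    matrix: pd.DataFrame,
    scenario: int,
    categories=("walk", "sleep", "dwell", "oth"),
) -> pd.DataFrame:
    """Reduce the assembled matrix to one of the three modeling scenarios.

    1: per-window raw measure values (the within-window mean stands in as
       the window's raw value) + demographics;
    2: TS statistics of the selected categories + demographics;
    3: TS statistics + DTW distances of the selected categories +
       demographics.
    """
    if scenario not in (1, 2, 3):
        raise ValueError(f"scenario must be 1, 2 or 3, got {scenario}")
    measures = measures_for_categories(categories)
    keep: list[str] = []
    if scenario == 1:
        keep += [f"{m}_mean" for m in measures]
    else:
        keep += [f"{m}_{s}" for m in measures for s in TS_STATS]
    if scenario == 3:
        keep += [
            c
            for c in matrix.columns
            if c.startswith("dtw_") and any(c.startswith(f"dtw_{m}_") for m in measures)
        ]
    keep += DEMOGRAPHICS
    missing = [c for c in keep if c not in matrix.columns]
    if missing:
        raise ValueError(f"matrix lacks expected columns: {missing[:5]}...")
    out = matrix[META_COLUMNS + keep].copy()
    if scenario == 1:
        out = out.rename(columns={f"{m}_mean": m for m in measures})
    return out
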