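"""Accuracy metrics, replicate runs, scenario grid, baselines, Wilcoxon.

Four accuracies are reported, all as percentages of correctly predicted
stage labels within a subset of the true labels:

* overall          — all test cases;
* DIA (degeneration identification) — cases whose true stage is TR or MCI;
* TIA (transition identification)   — true-TR cases;
* MIA (MCI identification)          — true-MCI cases.

A metric whose denominator is empty is *undefined* (``None``), never 0 or
100, and undefined values are skipped (not zero-filled) when averaging over
replicate runs. When both degenerating classes are present the identity
DIA = (n_TR * TIA + n_MCI * MIA) / (n_TR + n_MCI) holds exactly.

Baselines flatten each 10-timestep sample to a single vector and fit
default-configuration RBF-kernel SVM and random-forest classifiers on the
same splits. Paired model comparisons use the two-sided Wilcoxon
signed-rank test (exact small-sample distribution, zero differences
dropped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

METRIC_NAMES = ["overall", "DIA", "TIA", "MIA"]


@dataclass
class MetricsReport:
    overall: float | None
    DIA: float | None
    TIA: float | None
    MIA: float | None
    class_counts: dict[str, int] = field(default_factory=dict)
    run_id: str | None = None
    scenario: int | None = None
    categories: tuple[str, ...] | None = None

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def compute_metrics(true_labels, predicted_labels, **meta) -> MetricsReport:
    """Overall, DIA, TIA and MIA as percentages (undefined -> None)."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if len(t) != len(p):
        raise ValueError(f"label vectors differ in length: {len(t)} vs {len(p)}")
    if len(t) == 0:
        raise ValueError("label vectors are empty")

    def rate(mask):
        n = int(mask.sum())
        return None if n == 0 else float(100.0 * (t[mask] == p[mask]).mean())

    correct_all = rate(np.ones(len(t), dtype=bool))
    counts = {c: int((t == c).sum()) for c in ("CH", "TR", "MCI")}
    return MetricsReport(
        overall=correct_all,
        DIA=rate(np.isin(t, ["TR", "MCI"])),
        TIA=rate(t == "TR"),
        MIA=rate(t == "MCI"),
        class_counts=counts,
        **meta,
    )


def average_reports(reports: list[MetricsReport], **meta) -> MetricsReport:
    """Arithmetic mean per metric over the runs where it is defined."""
    def mean_of(name):
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        return float(np.mean(vals)) if vals else None

    return MetricsReport(
        overall=mean_of("overall"), DIA=mean_of("DIA"),
        TIA=mean_of("TIA"), MIA=mean_of("MIA"),
        class_counts=reports[0].class_counts if reports else {},
        **meta,
    )


def run_replicates(run_fn, seeds, **meta):
    """Execute ``run_fn(seed) -> MetricsReport`` per seed and average.

    Failures are logged and excluded; returns (averaged report, per-run
    reports, failure log).
    """
    if len(seeds) < 1:
        raise ValueError("at least one replicate seed is required")
    reports, failures = [], []
    for seed in seeds:
        try:
            rep = run_fn(seed)
            rep.run_id = f"seed={seed}"
            reports.append(rep)
        except Exception as exc:  # noqa: BLE001 - partial report contract
            logger.error("replicate seed=%s failed: %s", seed, exc)
            failures.append({"seed": seed, "error": str(exc)})
    avg = average_reports(reports, **meta) if reports else None
    return avg, reports, failures


#: The 12 activity-category combinations of the ablation grid.
DEFAULT_CATEGORY_GRID = [
    ("walk", "sleep", "dwell", "oth"),
    ("walk", "sleep", "oth"),
    ("walk", "sleep"),
    ("sleep", "oth"),
    ("sleep", "dwell"),
    ("walk", "dwell"),
    ("walk", "oth"),
    ("oth", "dwell"),
    ("sleep",),
    ("walk",),
    ("dwell",),
    ("oth",),
]


def run_scenario_grid(cell_fn, scenarios=(1, 2, 3), category_grid=None, seeds=(0,)):
    """Averaged metrics per (scenario, category-set) cell.

    ``cell_fn(scenario, categories, seed) -> MetricsReport``. Returns a
    DataFrame sorted within scenario by descending overall accuracy.
    """
    category_grid = category_grid or DEFAULT_CATEGORY_GRID
    rows = []
    for scenario in scenarios:
        for categories in category_grid:
            avg, _, _ = run_replicates(
                lambda s: cell_fn(scenario, categories, s), list(seeds)
            )
            rows.append(
                {
                    "scenario": scenario,
                    "model": "+".join(categories),
                    **(avg.as_dict() if avg else dict.fromkeys(METRIC_NAMES)),
                }
            )
    df = pd.DataFrame(rows)
    return (
        df.sort_values(["scenario", "overall"], ascending=[True, False])
        .reset_index(drop=True)
    )


def run_baselines(train, test, seed=0):
    """Default-configuration SVM (RBF) and random forest on flattened samples.

    Each (timesteps x features) sample becomes one flat vector so the
    baselines see the same information as the sequence model. Returns
    {"SVM": MetricsReport, "RF": MetricsReport}.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.svm import SVC

    from .measures import TARGET_STAGES

    Xtr = train.X.reshape(len(train), -1)
    Xte = test.X.reshape(len(test), -1)
    true = np.array([TARGET_STAGES[i] for i in test.y])
    out = {}
    for name, clf in (
        ("SVM", SVC(random_state=seed)),
        ("RF", RandomForestClassifier(random_state=seed)),
    ):
        clf.fit(Xtr, train.y)
        pred = np.array([TARGET_STAGES[i] for i in clf.predict(Xte)])
        out[name] = compute_metrics(true, pred, run_id=f"{name}-seed={seed}")
    return out


def wilcoxon_compare(values_a, values_b, alpha: float = 0.05):
    """Two-sided Wilcoxon signed-rank test on paired metric vectors.

    Zero differences are dropped (Wilcoxon's convention); with all
    differences zero the comparison is vacuous and p is reported as 1 with
    a warning. Uses the exact null distribution for small samples. Returns
    (statistic, p_value, significant).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired vectors must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs for the signed-rank test")
    diff = a - b
    if np.all(diff == 0):
        logger.warning("all paired differences are zero; p reported as 1")
        return 0.0, 1.0, False
    res = sps.wilcoxon(
        a, b, zero_method="wilcox", alternative="two-sided", method="exact"
    )
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)
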