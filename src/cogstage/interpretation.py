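"""Model-agnostic Shapley-value attribution of predictions to features.

Each feature column is a *player*; a prediction is the payoff. The value of
a feature coalition S for a sample x is the model's mean output when the
features in S keep x's values and all other features are replaced by
background-sample values (averaged over the whole background set). The
Shapley value of a feature is its average marginal contribution over
orderings of the players, estimated by Monte-Carlo permutation sampling;
because coalition values are evaluated against the full background, the
efficiency axiom (base value + sum of attributions = predicted output)
holds exactly for every sampled permutation and hence for the estimate.

Inputs may carry extra leading axes before the feature axis — for the
sequence classifier a sample is (timesteps x features) — and a player is
always the trailing-axis feature *column*: joining a coalition swaps the
column in at every timestep simultaneously, so the attribution is the
column's aggregate (timestep-summed) contribution to the prediction.

An exact oracle (full coalition enumeration, <= 10 players) is provided for
verification of the sampler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _as_rows(out) -> np.ndarray:
    """Model output as (n_rows, n_classes); scalar outputs become one column."""
    out = np.asarray(out, dtype=float)
    return out[:, None] if out.ndim == 1 else out


@dataclass
class AttributionReport:
    """Per-sample attributions plus global summaries.

    ``values`` has shape (n_samples, n_features, n_classes) in probability
    units; ``base_values`` (n_classes,) is the model's mean output over the
    background set.
    """

    values: np.ndarray
    base_values: np.ndarray
    feature_names: list[str]
    class_names: list[str]
    predictions: np.ndarray  # (n_samples, n_classes)

    def mean_abs(self) -> pd.DataFrame:
        """Mean |Shapley value| per (feature, class)."""
        m = np.abs(self.values).mean(axis=0)
        return pd.DataFrame(m, index=self.feature_names, columns=self.class_names)


def _coalition_value(predict_fn, x, background, members, cache=None):
    """Mean model output with coalition columns taken from x, rest from the
    background rows. ``x``: (..., F); ``background``: (n_b, ..., F)."""
    key = None
    if cache is not None:
        key = frozenset(members)
        if key in cache:
            return cache[key]
    comp = background.copy()
    if len(members):
        idx = np.asarray(sorted(members), dtype=int)
        comp[..., idx] = x[..., idx]
    val = _as_rows(predict_fn(comp)).mean(axis=0)
    if cache is not None:
        cache[key] = val
    return val


def shapley_attribution(
    predict_fn,
    background: np.ndarray,
    explain: np.ndarray,
    n_permutations: int,
    seed: int = 0,
    feature_names=None,
    class_names=None,
) -> AttributionReport:
    """Permutation-sampling Shapley estimates.

    ``predict_fn`` maps a batch of inputs (first axis = batch, last axis =
    features) to per-class outputs; ``background`` supplies replacement
    values for absent features; ``explain`` holds the samples to attribute.
    Deterministic under ``seed``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    background = np.asarray(background, dtype=float)
    explain = np.asarray(explain, dtype=float)
    if background.size == 0:
        raise ValueError("background set must be non-empty")
    if background.ndim == 1:
        background = background[None, :]
    if explain.ndim == background.ndim - 1:
        explain = explain[None, ...]
    n = explain.shape[0]
    F = explain.shape[-1]
    rng = np.random.default_rng(seed)

    base = _as_rows(predict_fn(background)).mean(axis=0)
    C = len(base)
    n_b = background.shape[0]
    values = np.zeros((n, F, C))
    predictions = np.zeros((n, C))
    for s in range(n):
        x = explain[s]
        acc = np.zeros((F, C))
        for _ in range(n_permutations):
            order = rng.permutation(F)
            # All F+1 prefix coalitions of this ordering, evaluated in one
            # batched model call: the marginal contribution of order[p] is
            # v(prefix p+1) - v(prefix p).
            comps = np.empty((F + 1, *background.shape))
            cur = background.copy()
            comps[0] = cur
            for pos, j in enumerate(order):
                cur[..., j] = x[..., j]
                comps[pos + 1] = cur
            flat = comps.reshape((F + 1) * n_b, *background.shape[1:])
            out = _as_rows(predict_fn(flat)).reshape(F + 1, n_b, C)
            v = out.mean(axis=1)
            acc[order] += np.diff(v, axis=0)
            predictions[s] = v[-1]
        values[s] = acc / n_permutations

    feature_names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(F)
    ]
    class_names = list(class_names) if class_names is not None else [
        f"class{i}" for i in range(C)
    ]
    return AttributionReport(values, base, feature_names, class_names, predictions)


def exact_shapley(predict_fn, background, x, feature_names=None, class_names=None):
    """Exact Shapley values by full coalition enumeration (<= 10 players).

    Same replacement semantics as the sampler; refuses more than 10
    features (2^10 coalitions).
    """
    background = np.asarray(background, dtype=float)
    if background.ndim == 1:
        background = background[None, :]
    x = np.asarray(x, dtype=float)
    F = x.shape[-1]
    if F > 10:
        raise ValueError(f"exact enumeration limited to 10 features, got {F}")
    vals = {}
    for r in range(F + 1):
        for S in combinations(range(F), r):
            vals[S] = _coalition_value(predict_fn, x, background, list(S))
    C = len(np.atleast_1d(vals[()]))
    phi = np.zeros((F, C))
    for j in range(F):
        rest = [i for i in range(F) if i != j]
        for r in range(F):
            w = factorial(r) * factorial(F - r - 1) / factorial(F)
            for S in combinations(rest, r):
                phi[j] += w * (vals[tuple(sorted((*S, j)))] - vals[S])
    base = np.atleast_1d(vals[()]).astype(float)
    feature_names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(F)
    ]
    class_names = list(class_names) if class_names is not None else [
        f"class{i}" for i in range(C)
    ]
    return AttributionReport(
        phi[None, ...], base, feature_names, class_names,
        np.atleast_1d(vals[tuple(range(F))]).astype(float)[None, :],
    )


def global_summary(report: AttributionReport, k: int = 10):
    """Top-k features by mean |Shapley value|, per class and combined.

    Combined importance sums the per-class mean |value|. Returns (combined
    DataFrame, {class: DataFrame}); if every attribution is zero the
    ranking is flagged empty.
    """
    if report.values.size == 0:
        raise ValueError("empty attribution report")
    m = report.mean_abs()
    if k > len(m):
        logger.warning("k=%d exceeds feature count %d; returning all", k, len(m))
        k = len(m)
    combined = m.sum(axis=1).sort_values(ascending=False)
    if float(combined.iloc[0]) == 0.0:
        logger.warning("all attributions are zero; ranking is vacuous")
        combined_df = pd.DataFrame({"feature": [], "importance": []})
    else:
        combined_df = (
            combined.head(k).rename("importance").rename_axis("feature").reset_index()
        )
    per_class = {
        c: m[c].sort_values(ascending=False).head(k).rename("importance")
        .rename_axis("feature").reset_index()
        for c in report.class_names
    }
    return combined_df, per_class
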