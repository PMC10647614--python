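"""Many-to-one stacked LSTM sequence classifier and sample construction.

The classifier consumes blocks of 10 consecutive window-feature rows and
predicts the cognitive stage (CH / TR / MCI) of the window immediately
following the block — a forecasting framing: the future stage is a function
of the activity features at the preceding time steps. Overlapping samples
are cut from every subject's window matrix with a stride of 2 windows
(8 overlapping timesteps), split chronologically per subject 75/15/10 into
train/validation/test, and z-scored with training-split statistics.

The network is a stack of three LSTM layers (100, 64, 16 units) with
dropout 0.5 between them and a 3-node softmax head on the final timestep,
trained with categorical cross-entropy and Adam (learning rate 1e-4). It is
implemented directly in NumPy — forward pass, backpropagation through time,
and the Adam update — so training is fully deterministic under a seed and
single-threaded execution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import feature_columns
from .measures import TARGET_STAGES

logger = logging.getLogger(__name__)

STAGE_TO_INDEX = {s: i for i, s in enumerate(TARGET_STAGES)}


# --------------------------------------------------------------------------
# Sample construction
# --------------------------------------------------------------------------

@dataclass
class SequenceSampleSet:
    """Inputs (samples x timesteps x features) with one future-label each."""

    X: np.ndarray
    y: np.ndarray  # int class index per sample
    subject_ids: np.ndarray
    target_windows: np.ndarray  # window index of each sample's target
    columns: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, idx) -> "SequenceSampleSet":
        idx = np.asarray(idx, dtype=int)
        return SequenceSampleSet(
            self.X[idx], self.y[idx], self.subject_ids[idx],
            self.target_windows[idx], self.columns,
        )

    @staticmethod
    def concat(parts: list["SequenceSampleSet"]) -> "SequenceSampleSet":
        parts = [p for p in parts if len(p)]
        if not parts:
            raise ValueError("no samples to concatenate")
        return SequenceSampleSet(
            np.concatenate([p.X for p in parts]),
            np.concatenate([p.y for p in parts]),
            np.concatenate([p.subject_ids for p in parts]),
            np.concatenate([p.target_windows for p in parts]),
            parts[0].columns,
        )


def make_samples(
    matrix: pd.DataFrame, timesteps: int = 10, sample_stride: int = 2
) -> SequenceSampleSet:
    """Overlapping input blocks from one subject's window-feature matrix.

    Sample j uses windows [s, s + timesteps - 1] as input and the label of
    window s + timesteps as target, for s = 0, sample_stride, ... while the
    target exists. The default stride of 2 realizes an overlap of 8
    timesteps between consecutive 10-step samples. A matrix with at most
    ``timesteps`` rows yields zero samples.
    """
    cols = feature_columns(matrix)
    values = matrix[cols].to_numpy(dtype=float)
    labels = matrix["label"].to_numpy()
    k = len(matrix)
    starts = [s for s in range(0, max(k - timesteps, 0), sample_stride)
              if s + timesteps <= k - 1]
    if not starts:
        logger.warning("matrix with %d windows yields no %d-step samples", k, timesteps)
        empty = np.empty((0, timesteps, len(cols)))
        return SequenceSampleSet(
            empty, np.empty(0, dtype=int),
            np.empty(0, dtype=object), np.empty(0, dtype=int), cols,
        )
    X = np.stack([values[s : s + timesteps] for s in starts])
    y = np.array([STAGE_TO_INDEX[labels[s + timesteps]] for s in starts])
    sid = matrix["subject_id"].iloc[0]
    return SequenceSampleSet(
        X, y,
        np.array([sid] * len(starts), dtype=object),
        np.array([s + timesteps for s in starts]),
        cols,
    )


def split_counts(n: int, fractions=(0.75, 0.15, 0.10)) -> tuple[int, int, int]:
    """Chronological train/validation/test counts for n samples.

    train = ceil(f_train * n), capped at n - 2 once n >= 3 so that every
    subject with at least three samples contributes to all three sets;
    validation = ceil(f_val * n) capped to leave at least one test sample;
    test takes the rest.
    """
    if not math.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    if n <= 0:
        return 0, 0, 0
    train = math.ceil(fractions[0] * n)
    if n >= 3:
        train = min(train, n - 2)
    rest = n - train
    val = min(math.ceil(fractions[1] * n), max(rest - 1, 0))
    return train, val, n - train - val


def split_samples(
    samples: SequenceSampleSet,
    fractions=(0.75, 0.15, 0.10),
    timesteps: int = 10,
    discard_boundary_overlaps: bool = True,
):
    """Per-subject chronological split into (train, validation, test).

    Within each subject, samples ordered by target window are cut into the
    three fractions (earliest -> train, latest -> test). When
    ``discard_boundary_overlaps`` is set, validation/test samples whose
    input block reaches back to any window at or before the subject's last
    training target are dropped, eliminating train-to-evaluation leakage
    through shared windows.
    """
    tr_idx, va_idx, te_idx = [], [], []
    for sid in pd.unique(samples.subject_ids):
        idx = np.flatnonzero(samples.subject_ids == sid)
        idx = idx[np.argsort(samples.target_windows[idx])]
        n = len(idx)
        if n == 0:
            logger.warning("subject %s has no samples; excluded", sid)
            continue
        n_tr, n_va, n_te = split_counts(n, fractions)
        tr, va, te = idx[:n_tr], idx[n_tr : n_tr + n_va], idx[n_tr + n_va :]
        if discard_boundary_overlaps and n_tr:
            last_train_target = samples.target_windows[tr].max()
            keep = lambda i: samples.target_windows[i] - timesteps > last_train_target
            va = np.array([i for i in va if keep(i)], dtype=int)
            te = np.array([i for i in te if keep(i)], dtype=int)
        tr_idx.extend(tr)
        va_idx.extend(va)
        te_idx.extend(te)
    return samples.subset(tr_idx), samples.subset(va_idx), samples.subset(te_idx)


def standardize_splits(train, val, test):
    """Z-score all feature columns using training-split statistics."""
    flat = train.X.reshape(-1, train.X.shape[-1])
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0)
    sd[sd == 0] = 1.0
    out = []
    for part in (train, val, test):
        scaled = (part.X - mean) / sd
        out.append(
            SequenceSampleSet(scaled, part.y, part.subject_ids,
                              part.target_windows, part.columns)
        )
    return (*out, (mean, sd))


# --------------------------------------------------------------------------
# Stacked LSTM classifier
# --------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Network and training hyperparameters (all overridable)."""

    layer_units: tuple[int, ...] = (100, 64, 16)
    dropout: float = 0.5
    n_classes: int = 3
    learning_rate: float = 1e-4
    epochs: int = 150
    batch_size: int = 16
    clip_norm: float = 5.0
    #: "float32" (default, matches common deep-learning practice) or "float64".
    dtype: str = "float32"
    seed: int = 0


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class StackedLSTMClassifier:
    """Many-to-one stacked LSTM with a softmax head, in NumPy.

    Weight layout per layer: ``Wx`` (input x 4H), ``Wh`` (H x 4H), ``b``
    (4H), gate order (input, forget, cell, output); forget-gate biases are
    initialized to 1. The softmax head reads the top layer's final hidden
    state. ``fit`` trains with mini-batch Adam on categorical cross-entropy
    and records per-epoch train/validation loss and accuracy.
    """

    def __init__(self, n_features: int, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.n_features = n_features
        self.dtype = np.dtype(self.config.dtype)
        rng = np.random.default_rng(self.config.seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(self.config.seed).spawn(1)[0]
        )
        self.params: dict[str, np.ndarray] = {}
        in_dim = n_features
        for l, H in enumerate(self.config.layer_units):
            scale_x = np.sqrt(6.0 / (in_dim + 4 * H))
            scale_h = np.sqrt(6.0 / (H + 4 * H))
            self.params[f"Wx{l}"] = rng.uniform(-scale_x, scale_x, (in_dim, 4 * H))
            self.params[f"Wh{l}"] = rng.uniform(-scale_h, scale_h, (H, 4 * H))
            b = np.zeros(4 * H)
            b[H : 2 * H] = 1.0  # forget-gate bias
            self.params[f"b{l}"] = b
            in_dim = H
        C = self.config.n_classes
        scale_d = np.sqrt(6.0 / (in_dim + C))
        self.params["Wd"] = rng.uniform(-scale_d, scale_d, (in_dim, C))
        self.params["bd"] = np.zeros(C)
        self.params = {k: v.astype(self.dtype) for k, v in self.params.items()}
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self.history: pd.DataFrame | None = None

    # -- forward ----------------------------------------------------------

    def _forward(self, X, training=False):
        """Returns (probs, caches); caches hold per-layer BPTT state."""
        B, T, _ = X.shape
        inputs = X
        caches = []
        for l, H in enumerate(self.config.layer_units):
            Wx, Wh, b = (self.params[f"Wx{l}"], self.params[f"Wh{l}"],
                         self.params[f"b{l}"])
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            hs = np.empty((B, T, H))
            cache_t = []
            for t in range(T):
                x_t = inputs[:, t, :]
                z = x_t @ Wx + h @ Wh + b
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H : 2 * H])
                g = np.tanh(z[:, 2 * H : 3 * H])
                o = _sigmoid(z[:, 3 * H :])
                c_new = f * c + i * g
                tc = np.tanh(c_new)
                h_new = o * tc
                cache_t.append((x_t, h, c, i, f, g, o, tc))
                h, c = h_new, c_new
                hs[:, t, :] = h
            mask = None
            out = hs
            if l < len(self.config.layer_units) - 1:
                if training and self.config.dropout > 0:
                    keep = 1.0 - self.config.dropout
                    mask = (
                        self._dropout_rng.random(hs.shape) < keep
                    ).astype(self.dtype) / self.dtype.type(keep)
                    out = hs * mask
            caches.append({"cache_t": cache_t, "hs": hs, "mask": mask, "out": out})
            inputs = out
        logits = caches[-1]["hs"][:, -1, :] @ self.params["Wd"] + self.params["bd"]
        probs = _softmax(logits)
        return probs, caches

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if X.shape[-1] != self.n_features:
            raise ValueError(
                f"feature dimension {X.shape[-1]} != trained {self.n_features}"
            )
        probs, _ = self._forward(np.asarray(X, dtype=self.dtype), training=False)
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class indices; exact probability ties break toward severity."""
        p = self.predict_proba(X)
        # reversed argmax prefers the highest class index (MCI) on ties
        return (p.shape[1] - 1) - np.argmax(p[:, ::-1], axis=1)

    # -- backward ---------------------------------------------------------

    def _backward(self, X, y_onehot, probs, caches):
        B = len(X)
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        h_last = caches[-1]["hs"][:, -1, :]
        dlogits = (probs - y_onehot) / B
        grads["Wd"] = h_last.T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)

        T = X.shape[1]
        # Gradient w.r.t. each layer's output sequence, top-down.
        n_layers = len(self.config.layer_units)
        d_out = [np.zeros_like(c["hs"]) for c in caches]
        d_out[-1][:, -1, :] = dlogits @ self.params["Wd"].T
        for l in range(n_layers - 1, -1, -1):
            H = self.config.layer_units[l]
            Wx, Wh = self.params[f"Wx{l}"], self.params[f"Wh{l}"]
            cache_t = caches[l]["cache_t"]
            dWx = np.zeros_like(Wx)
            dWh = np.zeros_like(Wh)
            db = np.zeros(4 * H)
            d_below = None
            if l > 0:
                d_below = np.zeros_like(caches[l - 1]["out"])
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                x_t, h_prev, c_prev, i, f, g, o, tc = cache_t[t]
                dh = d_out[l][:, t, :] + dh_next
                do = dh * tc
                dc = dh * o * (1.0 - tc**2) + dc_next
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dc_next = dc * f
                dz = np.concatenate(
                    [
                        di * i * (1 - i),
                        df * f * (1 - f),
                        dg * (1 - g**2),
                        do * o * (1 - o),
                    ],
                    axis=1,
                )
                dWx += x_t.T @ dz
                dWh += h_prev.T @ dz
                db += dz.sum(axis=0)
                dh_next = dz @ Wh.T
                if l > 0:
                    d_below[:, t, :] = dz @ Wx.T
            grads[f"Wx{l}"] = dWx
            grads[f"Wh{l}"] = dWh
            grads[f"b{l}"] = db
            if l > 0:
                mask = caches[l - 1]["mask"]
                d_out[l - 1] += d_below * mask if mask is not None else d_below
        return grads

    def _adam_step(self, grads):
        cfg = self.config
        norm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
        if cfg.clip_norm and norm > cfg.clip_norm:
            grads = {k: g * (cfg.clip_norm / norm) for k, g in grads.items()}
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-7
        lr = cfg.learning_rate * np.sqrt(1 - b2**self._adam_t) / (1 - b1**self._adam_t)
        for k, g in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g**2
            self.params[k] -= lr * self._adam_m[k] / (np.sqrt(self._adam_v[k]) + eps)

    def _loss_acc(self, X, y):
        probs = self.predict_proba(X)
        eps = 1e-12
        loss = float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))
        acc = float(np.mean(self.predict(X) == y))
        return loss, acc

    def fit(self, train: SequenceSampleSet, validation: SequenceSampleSet | None = None):
        """Train for ``config.epochs``; returns the history DataFrame."""
        if len(train) == 0:
            raise ValueError("training set is empty")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        C = cfg.n_classes
        onehot = np.eye(C)[train.y]
        rows = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(train))
            for start in range(0, len(train), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                Xb = train.X[idx].astype(self.dtype, copy=False)
                yb = onehot[idx].astype(self.dtype, copy=False)
                probs, caches = self._forward(Xb, training=True)
                if not np.isfinite(probs).all():
                    raise FloatingPointError(
                        "NaN in forward pass: check that features are scaled"
                    )
                grads = self._backward(Xb, yb, probs, caches)
                self._adam_step(grads)
            tr_loss, tr_acc = self._loss_acc(train.X, train.y)
            if not np.isfinite(tr_loss):
                raise FloatingPointError(
                    "NaN training loss: check that features are scaled"
                )
            row = {"epoch": epoch, "loss": tr_loss, "accuracy": tr_acc}
            if validation is not None and len(validation):
                va_loss, va_acc = self._loss_acc(validation.X, validation.y)
                row.update(val_loss=va_loss, val_accuracy=va_acc)
            rows.append(row)
        self.history = pd.DataFrame(rows)
        return self.history

    def save(self, path) -> None:
        """Checkpoint weights + config to an .npz file."""
        import json

        meta = {
            "n_features": self.n_features,
            "config": {
                "layer_units": list(self.config.layer_units),
                "dropout": self.config.dropout,
                "n_classes": self.config.n_classes,
                "learning_rate": self.config.learning_rate,
                "epochs": self.config.epochs,
                "batch_size": self.config.batch_size,
                "clip_norm": self.config.clip_norm,
                "seed": self.config.seed,
            },
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "StackedLSTMClassifier":
        import json

        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = meta["config"]
        cfg["layer_units"] = tuple(cfg["layer_units"])
        model = cls(meta["n_features"], ModelConfig(**cfg))
        for k in model.params:
            model.params[k] = data[k]
        return model

    def weights_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k]).tobytes())
        return h.hexdigest()


def build_and_train(
    config: ModelConfig, train: SequenceSampleSet, validation: SequenceSampleSet
):
    """Construct and fit the classifier; returns (model, history)."""
    model = StackedLSTMClassifier(train.X.shape[-1], config)
    history = model.fit(train, validation)
    return model, history


def probabilities_to_labels(probs: np.ndarray) -> np.ndarray:
    """Argmax over class probabilities; ties break toward the more severe
    stage (MCI > TR > CH)."""
    probs = np.atleast_2d(probs)
    idx = (probs.shape[1] - 1) - np.argmax(probs[:, ::-1], axis=1)
    return np.array([TARGET_STAGES[i] for i in idx])


def predict_stages(model: StackedLSTMClassifier, samples: SequenceSampleSet):
    """Predicted stage labels and class probabilities for a sample set."""
    probs = model.predict_proba(samples.X)
    return probabilities_to_labels(probs), probs
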