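"""Compact trainable predictor mapping multimodal features to bit or class
probabilities.

The predictor contract has two heads:

* ``ecoc`` — n output nodes, each a sigmoid binary classifier trained
  jointly; the output vector feeds the decoder.  Training minimizes the mean
  binary cross-entropy over the codebook's active bits (optionally weighted
  per bit by inverse positive fraction).
* ``multiclass`` — K softmax outputs trained with the refined focal loss,
  the direct-classification baseline.

The learner itself is a small fully connected network (tanh hidden layers,
Adam, early stopping on validation loss) over a multimodal feature vector:
compact image descriptors of both preprocessed films concatenated with the
one-hot / z-scored tabular features.  It runs in seconds on one CPU and is
fully deterministic given its seed.  A deep convolutional trunk can be
slotted in by implementing the same ``fit`` / ``predict_proba`` surface over
raw images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .codes import CodeBook
from .losses import EPS, FocalLossParams, class_balance_weights
from .preprocessing import RadiographPair, TrainStats, encode_tabular, image_descriptor

__all__ = [
    "PredictorConfig",
    "Predictor",
    "assemble_features",
    "train_predictor",
    "predict_outputs",
]


@dataclass
class PredictorConfig:
    """Architecture and optimization settings.  ``seed`` is mandatory."""

    head: str  # "ecoc" or "multiclass"
    n_out: int  # codebook n for ecoc, class count K for multiclass
    seed: int
    hidden: tuple[int, ...] = (32,)
    learning_rate: float = 0.01
    epochs: int = 100
    batch_size: int = 32
    patience: int = 10
    beta: float = 2.0  # focal focusing exponent (multiclass head)
    gamma: float = 1.0  # focal class-weight exponent (multiclass head)
    bit_weighting: str = "none"  # "none" | "inverse_positive_fraction"

    def __post_init__(self):
        if self.head not in ("ecoc", "multiclass"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.bit_weighting not in ("none", "inverse_positive_fraction"):
            raise ValueError(f"unknown bit_weighting {self.bit_weighting!r}")


def assemble_features(
    cohort: pd.DataFrame,
    train_stats: TrainStats,
    images: dict[str, RadiographPair] | None = None,
    grid: int = 8,
    use_bmi: bool = False,
) -> np.ndarray:
    """Build the multimodal design matrix for a cohort table.

    Tabular features are encoded against ``train_stats``; when ``images``
    maps patient ids to preprocessed film pairs, image descriptors of both
    views are concatenated in front of the tabular block.
    """
    rows = []
    for _, rec in cohort.iterrows():
        tab = encode_tabular(
            rec["gender"], rec["height_cm"], rec["weight_kg"], train_stats
        ).as_vector(use_bmi=use_bmi)
        if images is not None:
            pair = images[rec["id"]]
            rows.append(
                np.concatenate(
                    [image_descriptor(pair.ap, grid), image_descriptor(pair.lateral, grid), tab]
                )
            )
        else:
            rows.append(tab)
    return np.array(rows)


class Predictor:
    """A fitted feed-forward predictor with its config and training history."""

    def __init__(self, config: PredictorConfig, n_features: int):
        self.config = config
        self.n_features = n_features
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        rng = np.random.default_rng(config.seed)
        sizes = [n_features, *config.hidden, config.n_out]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / (fan_in + fan_out))
            self.weights.append(rng.normal(scale=scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        # context filled in by train_predictor
        self.classes: list | None = None
        self.active_bits: np.ndarray | None = None

    # -- forward ----------------------------------------------------------

    def _forward(self, x: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        hs = [x]
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            hs.append(np.tanh(hs[-1] @ w + b))
        z = hs[-1] @ self.weights[-1] + self.biases[-1]
        return hs, z

    def predict_raw(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"feature schema mismatch: got {x.shape[1]}, trained on {self.n_features}"
            )
        _, z = self._forward(x)
        return z

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Bit probabilities (ecoc head) or class simplex (multiclass head)."""
        z = self.predict_raw(x)
        if self.config.head == "ecoc":
            return 1.0 / (1.0 + np.exp(-z))
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize parameters + config + context to one JSON file."""
        payload = {
            "config": asdict(self.config),
            "n_features": self.n_features,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "classes": self.classes,
            "active_bits": None if self.active_bits is None else [int(b) for b in self.active_bits],
            "history": self.history,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "Predictor":
        payload = json.loads(Path(path).read_text())
        cfg = payload["config"]
        cfg["hidden"] = tuple(cfg["hidden"])
        config = PredictorConfig(**cfg)
        pred = cls(config, payload["n_features"])
        pred.weights = [np.array(w) for w in payload["weights"]]
        pred.biases = [np.array(b) for b in payload["biases"]]
        pred.classes = payload["classes"]
        pred.active_bits = (
            None if payload["active_bits"] is None else np.array(payload["active_bits"], dtype=bool)
        )
        pred.history = payload["history"]
        return pred


def _loss_and_grad_ecoc(z, targets, bit_w):
    """Mean active-bit weighted BCE and its gradient in the logits."""
    p = 1.0 / (1.0 + np.exp(-z))
    pc = np.clip(p, EPS, 1 - EPS)
    bce = -(targets * np.log(pc) + (1 - targets) * np.log(1 - pc))
    loss = float((bit_w * bce).sum() / (bit_w.sum() * z.shape[0]))
    grad = bit_w * (p - targets) / (bit_w.sum() * z.shape[0])
    return loss, grad


def _loss_and_grad_focal(z, y_idx, alpha, beta):
    """Mean refined focal loss and its gradient in the logits."""
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    b = np.arange(z.shape[0])
    q = np.clip(p[b, y_idx], EPS, 1 - EPS)
    a = alpha[y_idx]
    loss = float(np.mean(a * (1 - q) ** beta * (-np.log(q))))
    # dL/dq, with the beta = 0 factor vanishing cleanly
    dldq = a * (beta * (1 - q) ** (beta - 1) * np.log(q) - (1 - q) ** beta / q) if beta > 0 else -a / q
    onehot = np.zeros_like(p)
    onehot[b, y_idx] = 1.0
    grad = (dldq * q)[:, None] * (onehot - p) / z.shape[0]
    return loss, grad


def train_predictor(
    train: tuple[np.ndarray, Sequence],
    val: tuple[np.ndarray, Sequence],
    config: PredictorConfig,
    codebook: CodeBook | None = None,
    classes: Sequence | None = None,
) -> Predictor:
    """Fit the compact learner on (features, labels) splits.

    For the ``ecoc`` head a ``codebook`` is required: labels are mapped to
    codeword bit targets and the loss runs over active bits only.  For the
    ``multiclass`` head ``classes`` fixes the output order and the focal
    loss's class weights come from the training label counts.  Training is
    deterministic per ``config.seed``; per-epoch train/validation losses are
    recorded and the parameters with the best validation loss are restored
    (early stop after ``config.patience`` epochs without improvement).
    """
    x_train, y_train = np.asarray(train[0], dtype=float), list(train[1])
    x_val, y_val = np.asarray(val[0], dtype=float), list(val[1])
    if x_train.size == 0 or x_val.size == 0:
        raise ValueError("training and validation splits must be non-empty")

    if config.head == "ecoc":
        if codebook is None:
            raise ValueError("ecoc head requires a codebook")
        if config.n_out != codebook.n:
            raise ValueError(
                f"config head size {config.n_out} does not match codebook n {codebook.n}"
            )
        missing = set(y_train) | set(y_val)
        missing -= set(codebook.classes)
        if missing:
            raise ValueError(f"labels outside the codebook: {sorted(missing)}")
        t_train = np.array([codebook.codeword_for(y) for y in y_train], dtype=float)
        t_val = np.array([codebook.codeword_for(y) for y in y_val], dtype=float)
        bit_w = codebook.active_bits.astype(float)
        if config.bit_weighting == "inverse_positive_fraction":
            pos_frac = np.clip(t_train.mean(axis=0), 0.05, 0.95)
            bit_w = bit_w / pos_frac
    else:
        if classes is None:
            classes = sorted(set(y_train))
        classes = list(classes)
        if config.n_out != len(classes):
            raise ValueError(
                f"config head size {config.n_out} does not match {len(classes)} classes"
            )
        outside = (set(y_train) | set(y_val)) - set(classes)
        if outside:
            raise ValueError(f"labels outside the class set: {sorted(outside)}")
        idx = {c: i for i, c in enumerate(classes)}
        y_train_idx = np.array([idx[y] for y in y_train])
        y_val_idx = np.array([idx[y] for y in y_val])
        counts = np.bincount(y_train_idx, minlength=len(classes))
        if (counts == 0).any():
            raise ValueError("every class must appear in the training split")
        alpha = class_balance_weights(counts, config.gamma)
        params = FocalLossParams(beta=config.beta, gamma=config.gamma)

    pred = Predictor(config, x_train.shape[1])
    pred.classes = list(codebook.classes) if config.head == "ecoc" else classes
    pred.active_bits = codebook.active_bits.copy() if config.head == "ecoc" else None

    rng = np.random.default_rng(config.seed + 1)
    # Adam state
    m = [np.zeros_like(w) for w in pred.weights + pred.biases]
    v = [np.zeros_like(w) for w in pred.weights + pred.biases]
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0

    def batch_loss_grad(xb, tb):
        hs, z = pred._forward(xb)
        if config.head == "ecoc":
            loss, dz = _loss_and_grad_ecoc(z, tb, bit_w)
        else:
            loss, dz = _loss_and_grad_focal(z, tb, alpha, params.beta)
        grads_w, grads_b = [], []
        delta = dz
        for layer in range(len(pred.weights) - 1, -1, -1):
            grads_w.insert(0, hs[layer].T @ delta)
            grads_b.insert(0, delta.sum(axis=0))
            if layer > 0:
                delta = (delta @ pred.weights[layer].T) * (1 - hs[layer] ** 2)
        return loss, grads_w, grads_b

    def eval_loss(x, t):
        _, z = pred._forward(x)
        if config.head == "ecoc":
            return _loss_and_grad_ecoc(z, t, bit_w)[0]
        return _loss_and_grad_focal(z, t, alpha, params.beta)[0]

    targets_train = t_train if config.head == "ecoc" else y_train_idx
    targets_val = t_val if config.head == "ecoc" else y_val_idx

    best_val = np.inf
    best_params = None
    stall = 0
    n = x_train.shape[0]
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            sel = order[start: start + config.batch_size]
            loss, gw, gb = batch_loss_grad(x_train[sel], targets_train[sel])
            epoch_loss += loss
            n_batches += 1
            step += 1
            grads = gw + gb
            theta = pred.weights + pred.biases
            for i, (g, p) in enumerate(zip(grads, theta)):
                m[i] = b1 * m[i] + (1 - b1) * g
                v[i] = b2 * v[i] + (1 - b2) * g * g
                mh = m[i] / (1 - b1 ** step)
                vh = v[i] / (1 - b2 ** step)
                p -= config.learning_rate * mh / (np.sqrt(vh) + eps)
        val_loss = eval_loss(x_val, targets_val)
        pred.history["train_loss"].append(epoch_loss / n_batches)
        pred.history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = ([w.copy() for w in pred.weights], [b.copy() for b in pred.biases])
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    if best_params is not None:
        pred.weights, pred.biases = best_params
    return pred


def predict_outputs(predictor: Predictor, samples: np.ndarray) -> np.ndarray:
    """Per-bit probabilities (ecoc) or class simplex rows (multiclass)."""
    return predictor.predict_proba(samples)
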