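"""Imbalance-aware training losses.

The direct multiclass head trains with a refined focal loss

    L_i = -alpha_i * (1 - P_i)^beta * log(P_i),
    P_i = e^{f_i} / sum_j e^{f_j},
    alpha_i = (1/N_i)^gamma / sum_j (1/N_j)^gamma,

where ``N_i`` is the training count of class ``i``.  The ``alpha_i`` factor
upweights rare classes; the ``(1 - P_i)^beta`` factor focuses on
hard-to-classify samples.  With ``beta = gamma = 0`` the loss collapses to
``(1/K)`` times the ordinary cross-entropy.

The ECOC head trains ``n`` sigmoid-output binary classifiers jointly with a
(mean, optionally bit-weighted) binary cross-entropy over the active bits.
Natural logarithms throughout; probabilities are clamped to
``[eps, 1 - eps]`` with ``eps = 1e-7`` to keep losses finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "EPS",
    "FocalLossParams",
    "softmax_probabilities",
    "class_balance_weights",
    "focal_loss",
    "ecoc_bit_loss",
]

EPS = 1e-7


@dataclass
class FocalLossParams:
    """Focal-loss hyperparameters: focusing exponent ``beta`` and
    class-weight exponent ``gamma`` (both >= 0, tunable)."""

    beta: float = 2.0
    gamma: float = 1.0

    def __post_init__(self):
        if not (np.isfinite(self.beta) and np.isfinite(self.gamma)):
            raise ValueError("beta and gamma must be finite")
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("beta and gamma must be nonnegative")


def softmax_probabilities(scores: Sequence[float]) -> np.ndarray:
    """Softmax of a score vector, shift-invariant and numerically stable."""
    f = np.asarray(scores, dtype=float)
    if f.size == 0:
        raise ValueError("scores must be non-empty")
    if not np.isfinite(f).all():
        raise ValueError("scores must be finite")
    z = np.exp(f - f.max())
    return z / z.sum()


def class_balance_weights(counts: Sequence[int], gamma: float) -> np.ndarray:
    """Normalized inverse-frequency class weights ``alpha``.

    ``alpha_i = (1/N_i)^gamma / sum_j (1/N_j)^gamma``; sums to 1 and, for
    ``gamma > 0``, strictly decreases in ``N_i``.
    """
    n = np.asarray(counts, dtype=float)
    if (n < 1).any():
        raise ValueError("every class must have at least one training sample")
    w = (1.0 / n) ** gamma
    return w / w.sum()


def focal_loss(
    scores: Sequence[float],
    true_class: int,
    counts: Sequence[int],
    params: FocalLossParams,
) -> float:
    """Refined focal loss of one sample given raw scores and class counts."""
    p = softmax_probabilities(scores)
    if not 0 <= true_class < p.size:
        raise ValueError(f"true_class {true_class} out of range for {p.size} classes")
    alpha = class_balance_weights(counts, params.gamma)
    p_t = float(np.clip(p[true_class], EPS, 1 - EPS))
    # exact one-hot limit: zero loss regardless of beta
    if p[true_class] >= 1.0:
        return 0.0
    return float(alpha[true_class] * (1 - p_t) ** params.beta * (-np.log(p_t)))


def ecoc_bit_loss(
    outputs: Sequence[float],
    codeword: Sequence[int],
    bit_weights: Sequence[float] | None = None,
    active: Sequence[bool] | None = None,
) -> float:
    """Mean weighted binary cross-entropy between bit outputs and a codeword.

    ``-[c log p + (1 - c) log(1 - p)]`` averaged over the active bits, with
    optional per-bit weights (e.g. inverse positive-fraction); weights
    default to 1, in which case the plain mean BCE is returned.
    """
    p = np.asarray(outputs, dtype=float)
    c = np.asarray(codeword, dtype=float)
    if p.shape != c.shape:
        raise ValueError("outputs and codeword must have equal length")
    mask = np.ones(p.size, dtype=bool) if active is None else np.asarray(active, dtype=bool)
    w = np.ones(p.size) if bit_weights is None else np.asarray(bit_weights, dtype=float)
    if w.shape != p.shape:
        raise ValueError("bit_weights must match outputs length")
    pc = np.clip(p[mask], EPS, 1 - EPS)
    bce = -(c[mask] * np.log(pc) + (1 - c[mask]) * np.log(1 - pc))
    return float(np.mean(w[mask] * bce))
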