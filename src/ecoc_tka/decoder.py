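"""Decoding rules: map per-bit classifier outputs to a ranked list of classes.

The joint learner emits one positive-class probability per bit.  Four
decision rules turn that vector into class scores:

* **Method I** (``hard_hamming``) — binarize at 0.5, then Hamming distance to
  each class codeword.
* **Method II** (``hard_revised``) — binarize at a per-bit threshold equal to
  the positive fraction of the training set for that bit, which compensates
  for imbalanced binary tasks; Hamming distance on the hardened bits.
* **Method III** (``soft_euclidean``) — Euclidean distance between the raw
  probability vector and the 0/1 codeword; soft decisions keep the confidence
  information a hard threshold throws away.
* **Method IV** (``soft_sigmoid``) — sum of per-bit sigmoid-based distances
  ``1 / (1 + exp(-(|p - label| - 0.5) * 10))``, which expands resolution in
  the ambiguous region around ``|p - label| = 0.5`` and saturates where the
  bit is clearly right or clearly wrong.

Degenerate codebook bits are excluded from every metric.  Ties in the class
ranking break toward the lower class index; sizes are ordinal, so this
prefers the smaller component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .codes import CodeBook

__all__ = [
    "METHODS",
    "METHOD_LABELS",
    "BitLabelCounts",
    "DecodeResult",
    "sigmoid_bit_distance",
    "revised_thresholds",
    "harden_outputs",
    "vector_distance",
    "decode_rank",
]

#: Decision-rule identifiers, in the conventional I..IV order.
METHODS: tuple[str, ...] = ("hard_hamming", "hard_revised", "soft_euclidean", "soft_sigmoid")
METHOD_LABELS: dict[str, str] = {
    "hard_hamming": "I",
    "hard_revised": "II",
    "soft_euclidean": "III",
    "soft_sigmoid": "IV",
}

_EPS = 1e-6


def _check_probs(p: Sequence[float]) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("bit outputs must be a 1-D probability vector")
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("bit outputs must lie in [0, 1]")
    return arr


@dataclass
class BitLabelCounts:
    """Per-bit positive/negative training-sample counts."""

    n_pos: np.ndarray
    n_neg: np.ndarray

    def __post_init__(self):
        self.n_pos = np.asarray(self.n_pos, dtype=np.int64)
        self.n_neg = np.asarray(self.n_neg, dtype=np.int64)
        if self.n_pos.shape != self.n_neg.shape:
            raise ValueError("n_pos and n_neg must have equal length")
        if (self.n_pos < 0).any() or (self.n_neg < 0).any():
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_labels(cls, labels: Sequence, codebook: CodeBook) -> "BitLabelCounts":
        """Count per-bit positives/negatives induced by training labels."""
        rows = np.array([codebook.codeword_for(lbl) for lbl in labels], dtype=np.int64)
        n_pos = rows.sum(axis=0)
        return cls(n_pos=n_pos, n_neg=len(labels) - n_pos)


@dataclass
class DecodeResult:
    """Classes ranked by ascending distance under one decision rule."""

    ranked_classes: list
    distances: np.ndarray
    method: str

    @property
    def top(self):
        return self.ranked_classes[0]

    def top_k(self, k: int) -> list:
        return self.ranked_classes[:k]


def sigmoid_bit_distance(p: float | np.ndarray, label: int | np.ndarray) -> float | np.ndarray:
    """Per-bit sigmoid-based dissimilarity ``1/(1 + e^{-(|p-label|-0.5)*10})``.

    Strictly increasing in ``|p - label|``, exactly 0.5 at ``|p - label| =
    0.5``, and saturating toward 0/1 at the extremes — resolution is spent
    where the binary classifier is genuinely uncertain.
    """
    p_arr = np.asarray(p, dtype=float)
    if ((p_arr < 0) | (p_arr > 1)).any():
        raise ValueError("p must lie in [0, 1]")
    out = 1.0 / (1.0 + np.exp(-(np.abs(p_arr - np.asarray(label, dtype=float)) - 0.5) * 10.0))
    return float(out) if np.isscalar(p) or p_arr.ndim == 0 else out


def revised_thresholds(counts: BitLabelCounts, eps: float = _EPS) -> np.ndarray:
    """Per-bit hardening thresholds equal to the training positive fraction.

    ``threshold_j = N+_j / (N+_j + N-_j)``, clamped into ``(eps, 1 - eps)``
    when a bit is one-sided (all-positive or all-negative in training).
    One-sided bits are reported via a ``UserWarning``.
    """
    total = counts.n_pos + counts.n_neg
    if (total == 0).any():
        raise ValueError("every bit needs at least one training sample")
    thr = counts.n_pos / total
    one_sided = (thr <= 0) | (thr >= 1)
    if one_sided.any():
        import warnings

        warnings.warn(
            f"{int(one_sided.sum())} bit(s) are one-sided in training; "
            "thresholds clamped",
            stacklevel=2,
        )
    return np.clip(thr, eps, 1 - eps)


def harden_outputs(outputs: Sequence[float], thresholds: float | Sequence[float]) -> np.ndarray:
    """Binarize probabilities: bit j is 1 iff ``p_j >= threshold_j``.

    A probability exactly at its threshold hardens to 1 (fixed convention).
    """
    p = _check_probs(outputs)
    thr = np.broadcast_to(np.asarray(thresholds, dtype=float), p.shape)
    if np.asarray(thresholds).ndim == 1 and np.asarray(thresholds).size != p.size:
        raise ValueError("threshold vector length must match outputs")
    return (p >= thr).astype(np.uint8)


def vector_distance(
    outputs: Sequence[float],
    codeword: Sequence[int],
    metric: str,
    thresholds: float | Sequence[float] = 0.5,
    active: Sequence[bool] | None = None,
) -> float:
    """Distance between a probability vector and a 0/1 codeword.

    ``hamming_on_hardened`` counts disagreements after hardening at
    ``thresholds``; ``euclidean`` is the L2 distance on raw probabilities;
    ``sigmoid_sum`` sums :func:`sigmoid_bit_distance` per bit.  Only the
    ``active`` bit positions contribute (all bits by default).
    """
    p = _check_probs(outputs)
    c = np.asarray(codeword, dtype=float)
    if p.shape != c.shape:
        raise ValueError("outputs and codeword must have equal length")
    mask = np.ones(p.size, dtype=bool) if active is None else np.asarray(active, dtype=bool)
    if metric == "hamming_on_hardened":
        hard = harden_outputs(p, thresholds)
        return float(np.count_nonzero(hard[mask] != c[mask]))
    if metric == "euclidean":
        return float(np.sqrt(((p[mask] - c[mask]) ** 2).sum()))
    if metric == "sigmoid_sum":
        return float(np.sum(sigmoid_bit_distance(p[mask], c[mask])))
    raise ValueError(f"unknown metric: {metric!r}")


_METRIC_FOR_METHOD = {
    "hard_hamming": "hamming_on_hardened",
    "hard_revised": "hamming_on_hardened",
    "soft_euclidean": "euclidean",
    "soft_sigmoid": "sigmoid_sum",
}


def decode_rank(
    outputs: Sequence[float],
    codebook: CodeBook,
    method: str,
    counts: BitLabelCounts | None = None,
) -> DecodeResult:
    """Rank all codebook classes by ascending distance to the bit outputs.

    ``counts`` is required only for ``hard_revised`` (it supplies the revised
    thresholds).  Equidistant classes rank in ascending class-index order.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    p = _check_probs(outputs)
    if p.size != codebook.n:
        raise ValueError(f"outputs have length {p.size}, codebook n = {codebook.n}")
    if method == "hard_revised":
        if counts is None:
            raise ValueError("hard_revised decoding requires BitLabelCounts")
        import warnings

        # one-sided *inactive* bits are expected (they are constant by
        # construction) and never contribute to the distance; only warn when
        # an active bit is one-sided
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            thresholds = revised_thresholds(counts)
        frac = counts.n_pos / (counts.n_pos + counts.n_neg)
        one_sided_active = ((frac <= 0) | (frac >= 1)) & codebook.active_bits
        if one_sided_active.any():
            warnings.warn(
                f"{int(one_sided_active.sum())} active bit(s) are one-sided "
                "in training; thresholds clamped",
                stacklevel=2,
            )
    else:
        thresholds = 0.5

    metric = _METRIC_FOR_METHOD[method]
    distances = np.array(
        [
            vector_distance(p, cw, metric, thresholds, active=codebook.active_bits)
            for cw in codebook.codewords
        ]
    )
    order = np.lexsort((np.arange(codebook.n_classes), distances))
    return DecodeResult(
        ranked_classes=[codebook.classes[i] for i in order],
        distances=distances[order],
        method=method,
    )
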