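"""Statistical analysis, per-bit diagnostics and the model-comparison report.

Feature-label association uses the Pearson correlation coefficient with its
t-test, ``t = r * sqrt((n - 2) / (1 - r^2))``; a binary gender coded 0/1
inside Pearson's r is the point-biserial correlation, which is the
appropriate treatment for a dichotomous feature.  The 99%-confidence
threshold is taken from the t distribution at the actual degrees of freedom.

Classification is scored by top-k (default top-3) accuracy: surgeons are
normally offered about three adjacent candidate sizes before the operation,
so a prediction whose true size ranks among the best three is clinically
usable.

Per-bit accuracies diagnose the binary sub-tasks of the ECOC decomposition
and drive the code-length advisor: doubling a Hadamard code from n to 2n
bits raises the error-correcting capability by n/4, which only pays off if
the extra binary classifiers err on fewer than n/4 bits — i.e. if every
per-bit accuracy clears 75%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .codes import CodeBook, positive_ratio_per_bit
from .decoder import METHODS, METHOD_LABELS, BitLabelCounts, decode_rank, harden_outputs

__all__ = [
    "CorrelationResult",
    "EvaluationReport",
    "pearson_r",
    "t_statistic",
    "significance_threshold",
    "correlation_table",
    "top_k_accuracy",
    "per_bit_accuracy",
    "code_length_advisor",
    "CodeLengthAdvice",
    "compare_methods",
]


@dataclass
class CorrelationResult:
    """Pearson r with its t statistic and sample count."""

    r: float
    t_value: float
    n: int


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient (point-biserial for a 0/1 input)."""
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.size != y_arr.size or x_arr.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 samples")
    if np.var(x_arr) == 0 or np.var(y_arr) == 0:
        raise ValueError("correlation is undefined for a zero-variance input")
    return float(stats.pearsonr(x_arr, y_arr).statistic)


def t_statistic(r: float, n: int) -> float:
    """t statistic of a Pearson correlation: ``r * sqrt((n-2)/(1-r^2))``."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1 for a finite t statistic")
    return float(r * np.sqrt((n - 2) / (1.0 - r * r)))


def significance_threshold(n: int, confidence: float = 0.99) -> float:
    """Two-sided critical t value at the given confidence for df = n - 2."""
    return float(stats.t.ppf(1 - (1 - confidence) / 2, df=n - 2))


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r plus its t statistic for one feature-label pair."""
    r = pearson_r(x, y)
    n = len(np.asarray(x))
    return CorrelationResult(r=r, t_value=t_statistic(r, n), n=n)


def correlation_table(cohort) -> dict[str, dict[str, CorrelationResult]]:
    """Feature-label correlation grid for a cohort table.

    Rows: femoral / tibial size; columns: gender (0/1 coded), height, weight.
    """
    from .synthetic import gender_numeric

    features = {
        "gender": gender_numeric(cohort["gender"]),
        "height": cohort["height_cm"].to_numpy(float),
        "weight": cohort["weight_kg"].to_numpy(float),
    }
    out: dict[str, dict[str, CorrelationResult]] = {}
    for comp, col in (("femoral", "femoral_size"), ("tibial", "tibial_size")):
        y = cohort[col].to_numpy(float)
        out[comp] = {name: correlate(x, y) for name, x in features.items()}
    return out


# ---------------------------------------------------------------------------
# Classification metrics
# ---------------------------------------------------------------------------

def top_k_accuracy(rankings: Sequence[Sequence], truths: Sequence, k: int = 3) -> float:
    """Fraction of samples whose true class is among the first k ranked."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rankings = list(rankings)
    truths = list(truths)
    if not rankings or len(rankings) != len(truths):
        raise ValueError("need matching, non-empty rankings and truths")
    hits = sum(t in list(r)[:k] for r, t in zip(rankings, truths))
    return hits / len(truths)


def per_bit_accuracy(
    outputs: np.ndarray,
    codebook: CodeBook,
    truths: Sequence,
    thresholds: float | Sequence[float] = 0.5,
) -> np.ndarray:
    """Accuracy of each active binary classifier after hardening.

    ``outputs`` is (n_samples, n) probabilities; bit j is scored against the
    true class's codeword bit j.  Returns one accuracy per *active* bit.
    """
    out = np.atleast_2d(np.asarray(outputs, dtype=float))
    truths = list(truths)
    if out.shape[0] != len(truths) or out.shape[1] != codebook.n:
        raise ValueError("outputs must be (n_samples, codebook.n)")
    true_bits = np.array([codebook.codeword_for(t) for t in truths])
    hard = np.array([harden_outputs(row, thresholds) for row in out])
    acc = (hard == true_bits).mean(axis=0)
    return acc[codebook.active_bits]


@dataclass
class CodeLengthAdvice:
    """Outcome of the 75% per-bit accuracy doubling heuristic."""

    n_bits: int
    fraction_above: float
    all_above: bool
    capability_gain_bits: float  #: extra correctable errors if n doubles (n/4)
    recommendation: str


def code_length_advisor(per_bit_acc: Sequence[float], threshold: float = 0.75) -> CodeLengthAdvice:
    """Advise on doubling the code length from the per-bit accuracies.

    Doubling n adds n/4 bits of error-correcting capability but also n new
    binary classifiers; the gain is real only when every per-bit accuracy
    exceeds the 75% threshold, otherwise the current length is kept.
    """
    acc = np.asarray(per_bit_acc, dtype=float)
    if acc.size == 0:
        raise ValueError("need at least one per-bit accuracy")
    above = acc > threshold
    all_above = bool(above.all())
    return CodeLengthAdvice(
        n_bits=acc.size,
        fraction_above=float(above.mean()),
        all_above=all_above,
        capability_gain_bits=acc.size / 4.0,
        recommendation=(
            "doubling may help: every binary classifier clears the 75% bar"
            if all_above
            else "retain current length: sub-75% binary classifiers would "
            "outweigh the n/4 capability gain"
        ),
    )


# ---------------------------------------------------------------------------
# Model comparison report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-decision-rule top-k accuracies plus per-bit diagnostics."""

    method_top_k: dict  #: {"I".."IV": {component: accuracy}}
    per_bit: dict  #: {component: [accuracy per active bit]}
    positive_ratios: dict  #: {component: [training positive ratio per active bit]}
    k: int
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method_top_k": self.method_top_k,
            "per_bit_accuracy": self.per_bit,
            "positive_ratios": self.positive_ratios,
            "k": self.k,
            "seed": self.seed,
            "config": self.config,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def compare_methods(
    outputs: dict[str, np.ndarray],
    codebooks: dict[str, CodeBook],
    counts: dict[str, BitLabelCounts],
    truths: dict[str, Sequence],
    train_freqs: dict[str, Sequence[float]] | None = None,
    k: int = 3,
    seed: int | None = None,
    config: dict | None = None,
) -> EvaluationReport:
    """Score all four decision rules on every component.

    ``outputs``, ``codebooks``, ``counts`` and ``truths`` are keyed by
    component name (e.g. ``femoral``, ``tibial``).  Returns the report with
    one top-k accuracy per method per component, per-bit accuracies and, when
    ``train_freqs`` is given, the training positive-sample ratio per bit.
    """
    components = list(outputs)
    if set(codebooks) != set(components) or set(truths) != set(components):
        raise ValueError("outputs, codebooks and truths must share components")
    method_top_k: dict[str, dict[str, float]] = {METHOD_LABELS[m]: {} for m in METHODS}
    per_bit: dict[str, list[float]] = {}
    ratios: dict[str, list[float]] = {}
    for comp in components:
        out = np.atleast_2d(np.asarray(outputs[comp], dtype=float))
        cb = codebooks[comp]
        for method in METHODS:
            rankings = [
                decode_rank(row, cb, method, counts=counts.get(comp)).ranked_classes
                for row in out
            ]
            method_top_k[METHOD_LABELS[method]][comp] = top_k_accuracy(
                rankings, truths[comp], k
            )
        per_bit[comp] = [float(a) for a in per_bit_accuracy(out, cb, truths[comp])]
        if train_freqs is not None:
            full = positive_ratio_per_bit(cb, train_freqs[comp])
            ratios[comp] = [float(r) for r in full[cb.active_bits]]
    return EvaluationReport(
        method_top_k=method_top_k,
        per_bit=per_bit,
        positive_ratios=ratios,
        k=k,
        seed=seed,
        config=config or {},
    )
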