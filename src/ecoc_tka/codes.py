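"""Binary block codes for error-correcting output classification.

ECOC reduces a K-class problem to ``n`` binary tasks: each class is assigned
a binary codeword of length ``n``, each bit position defines one binary
classifier, and decoding maps the classifier outputs to the nearest codeword.
The code's minimum pairwise Hamming distance ``d_min`` gives the ensemble an
error-correcting margin: any pattern of ``t = floor((d_min - 1) / 2)`` bit
errors is still decoded to the right class.

Two code families are provided:

* **Hadamard codes** — rows of the 0/1 Sylvester-type matrix built by the
  doubling recursion ``M_2n = [[M_n, M_n], [M_n, ~M_n]]``.  Row 0 is all
  zeros, every other row has weight ``n/2``, and any two distinct rows are
  at Hamming distance exactly ``n/2``.
* **Hamming codes** — the ``(2^m - 1, 2^m - 1 - m)`` single-error-correcting
  linear codes, together with a greedy selection procedure that picks ``N``
  class codewords from the full code while keeping the pairwise minimum
  distance as large as the weight schedule allows.

Class-to-codeword assignment for the Hadamard scheme minimizes the imbalance
of the induced binary tasks: for each bit, the fraction of training mass on
the positive side should sit near 0.5.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "WEIGHT_SCHEDULE",
    "CodeBook",
    "build_hadamard_matrix",
    "hamming_parity_check",
    "hamming_generator",
    "enumerate_hamming_codewords",
    "hamming_distance",
    "codebook_min_distance",
    "error_correcting_capability",
    "select_hamming_codewords",
    "assign_hadamard_codewords",
    "positive_ratio_per_bit",
]

#: Weight schedule for the greedy codeword selection: the distinct Hamming
#: weights occurring in the (15, 11) Hamming code, in ascending order.
WEIGHT_SCHEDULE: tuple[int, ...] = (0, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 15)

#: Candidate-count budget above which assignment search falls back to a
#: seeded greedy local search instead of exhaustive enumeration.
_EXHAUSTIVE_BUDGET = 1_000_000


def _as_bits(word: Sequence[int] | np.ndarray) -> np.ndarray:
    """Validate and coerce a codeword-like sequence to a uint8 0/1 vector."""
    arr = np.asarray(word)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("a codeword must be a non-empty 1-D sequence of bits")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("codeword symbols must be 0 or 1")
    return arr.astype(np.uint8)


# ---------------------------------------------------------------------------
# Hadamard construction
# ---------------------------------------------------------------------------

def build_hadamard_matrix(order: int) -> np.ndarray:
    """Build the 0/1 Hadamard matrix of a power-of-two ``order``.

    Starts from the 2x2 base ``[[0, 0], [0, 1]]`` and doubles via
    ``M_2n = [[M, M], [M, 1 - M]]``.

    Returns an ``(order, order)`` uint8 array whose rows are the Hadamard
    codewords: row 0 all zeros, every other row of weight ``order / 2``,
    pairwise row distances all equal to ``order / 2``.
    """
    if order < 2 or order & (order - 1) != 0:
        raise ValueError(f"Hadamard order must be a power of two >= 2, got {order}")
    m = np.array([[0, 0], [0, 1]], dtype=np.uint8)
    while m.shape[0] < order:
        m = np.block([[m, m], [m, 1 - m]]).astype(np.uint8)
    return m


# ---------------------------------------------------------------------------
# Hamming code construction
# ---------------------------------------------------------------------------

def hamming_parity_check(m: int) -> np.ndarray:
    """Parity-check matrix of the ``(2^m - 1, 2^m - 1 - m)`` Hamming code.

    Columns are all nonzero m-bit vectors: the ``2^m - 1 - m`` vectors of
    weight >= 2 first, in increasing binary value, then the identity block.
    Shape ``(m, 2^m - 1)``, dtype uint8.
    """
    if m < 3:
        raise ValueError(f"Hamming codes require m >= 3, got {m}")
    vecs = [[(v >> (m - 1 - j)) & 1 for j in range(m)] for v in range(1, 2 ** m)]
    heavy = [v for v in vecs if sum(v) >= 2]
    identity = np.eye(m, dtype=np.uint8)
    return np.column_stack([np.array(heavy, dtype=np.uint8).T, identity])


def hamming_generator(m: int) -> np.ndarray:
    """Systematic generator matrix ``G = [I_k | A^T]`` of the Hamming code.

    ``A`` is the non-identity block of :func:`hamming_parity_check`, so
    ``G @ H.T = 0 (mod 2)``.  Shape ``(k, n)`` with ``k = 2^m - 1 - m``.
    """
    h = hamming_parity_check(m)
    n = h.shape[1]
    k = n - m
    a = h[:, :k]  # m x k
    return np.column_stack([np.eye(k, dtype=np.uint8), a.T])


def enumerate_hamming_codewords(m: int) -> np.ndarray:
    """Enumerate all ``2^(n - m)`` codewords of the ``(2^m - 1, k)`` Hamming code.

    Returns a ``(2^k, n)`` uint8 array.  The set is linear (closed under
    XOR) and contains the all-zeros word.  Memory grows as ``2^(2^m - 1 - m)``
    rows; ``m = 4`` (2048 words of length 15) is the scale this package uses.
    """
    g = hamming_generator(m)
    k = g.shape[0]
    messages = ((np.arange(2 ** k)[:, None] >> np.arange(k - 1, -1, -1)) & 1).astype(np.uint8)
    return (messages @ g) % 2


# ---------------------------------------------------------------------------
# Distance metrics
# ---------------------------------------------------------------------------

def hamming_distance(u: Sequence[int], v: Sequence[int]) -> int:
    """Number of positions where two equal-length codewords differ."""
    a, b = _as_bits(u), _as_bits(v)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    return int(np.count_nonzero(a != b))


def codebook_min_distance(codewords: Iterable[Sequence[int]] | np.ndarray) -> int:
    """Minimum pairwise Hamming distance over a set of >= 2 codewords.

    Brute force over all pairs; this is the reference definition, not an
    optimized routine.
    """
    arr = np.atleast_2d(np.asarray(list(codewords) if not isinstance(codewords, np.ndarray) else codewords))
    if arr.shape[0] < 2:
        raise ValueError("minimum distance is undefined for fewer than 2 codewords")
    arr = arr.astype(np.uint8)
    # pairwise distances via broadcasting; fine at the <=2048-word scale
    best = arr.shape[1] + 1
    for i in range(arr.shape[0] - 1):
        d = np.count_nonzero(arr[i + 1:] != arr[i], axis=1).min()
        best = min(best, int(d))
    return best


def error_correcting_capability(d_min: int) -> int:
    """Number of bit errors ``t`` a code of minimum distance ``d_min`` corrects.

    ``t`` is the largest integer with ``2t + 1 <= d_min``, i.e.
    ``floor((d_min - 1) / 2)``.
    """
    if d_min < 1:
        raise ValueError(f"d_min must be >= 1, got {d_min}")
    return (d_min - 1) // 2


# ---------------------------------------------------------------------------
# Greedy codeword selection from the (15, 11) Hamming code
# ---------------------------------------------------------------------------

def _candidate_order(codewords: np.ndarray) -> list[int]:
    """Fixed candidate ordering: ascending (Hamming weight, MSB-first value)."""
    n = codewords.shape[1]
    pows = 1 << np.arange(n - 1, -1, -1, dtype=np.int64)
    values = codewords.astype(np.int64) @ pows
    weights = codewords.sum(axis=1).astype(np.int64)
    idx = np.lexsort((values, weights))
    return [int(values[i]) for i in idx if values[i] != 0]


def select_hamming_codewords(n_codewords: int, m: int = 4) -> tuple[np.ndarray, int]:
    """Greedily select ``N`` codewords of the Hamming code, maximizing spread.

    Walks a fixed weight schedule from the top: with the current minimum
    distance requirement ``dist_min``, start from the all-zeros word, repeatedly
    drop every candidate closer than ``dist_min`` to the last selected word and
    take the first survivor; when candidates run out before ``N`` words are
    selected, decrement the schedule index and restart.  The candidate list is
    ordered ascending by (weight, binary value read MSB first), which makes the
    output deterministic.

    Returns ``(codewords, dist_min)``: an ``(N, n)`` uint8 array whose first
    row is all zeros, with pairwise distances >= ``dist_min``.  For ``N = 1``
    the distance requirement is vacuous and the top-of-schedule value is
    returned unchanged.
    """
    full = enumerate_hamming_codewords(m)
    n_bits = full.shape[1]
    if n_codewords < 1:
        raise ValueError(f"need at least one codeword, got {n_codewords}")
    if n_codewords > full.shape[0]:
        raise ValueError(
            f"cannot select {n_codewords} codewords from a code of size {full.shape[0]}"
        )
    candidates = _candidate_order(full)

    i = len(WEIGHT_SCHEDULE) - 1
    while True:
        dist_min = WEIGHT_SCHEDULE[i]
        selected = [0]
        pool = list(candidates)
        while len(selected) < n_codewords:
            last = selected[-1]
            pool = [c for c in pool if (c ^ last).bit_count() >= dist_min]
            if not pool:
                break
            selected.append(pool.pop(0))
        if len(selected) >= n_codewords or i == 0:
            selected = selected[:n_codewords]
            break
        i -= 1

    out = np.array(
        [[(c >> (n_bits - 1 - j)) & 1 for j in range(n_bits)] for c in selected],
        dtype=np.uint8,
    )
    return out, WEIGHT_SCHEDULE[i]


# ---------------------------------------------------------------------------
# CodeBook and Hadamard assignment
# ---------------------------------------------------------------------------

@dataclass
class CodeBook:
    """A class -> codeword map with scheme metadata.

    Attributes
    ----------
    scheme : {"hadamard", "hamming"}
    n : codeword length.
    classes : ordered class identifiers (one per codeword row).
    codewords : ``(K, n)`` uint8 array, one row per class.
    active_bits : boolean mask of non-degenerate bit positions.  A bit that is
        constant across all class codewords carries no class information and is
        excluded from training and decoding.
    d_min : minimum pairwise Hamming distance (``None`` for a single class).
    """

    scheme: str
    n: int
    classes: list
    codewords: np.ndarray
    active_bits: np.ndarray = field(default=None)  # type: ignore[assignment]
    d_min: int | None = None

    def __post_init__(self):
        self.codewords = np.atleast_2d(np.asarray(self.codewords, dtype=np.uint8))
        if self.codewords.shape != (len(self.classes), self.n):
            raise ValueError("codewords must be a (n_classes, n) array")
        seen = {tuple(row) for row in self.codewords}
        if len(seen) != len(self.classes):
            raise ValueError("class -> codeword map must be injective")
        if self.active_bits is None:
            self.active_bits = ~np.all(self.codewords == self.codewords[0], axis=0)
        self.active_bits = np.asarray(self.active_bits, dtype=bool)
        if self.d_min is None and len(self.classes) >= 2:
            self.d_min = codebook_min_distance(self.codewords)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def codeword_for(self, cls) -> np.ndarray:
        return self.codewords[self.classes.index(cls)]

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "n": self.n,
            "classes": list(self.classes),
            "codewords": ["".join(str(b) for b in row) for row in self.codewords],
            "active_bits": [int(b) for b in self.active_bits],
            "d_min": self.d_min,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CodeBook":
        codewords = np.array([[int(ch) for ch in row] for row in d["codewords"]], dtype=np.uint8)
        return cls(
            scheme=d["scheme"],
            n=d["n"],
            classes=list(d["classes"]),
            codewords=codewords,
            active_bits=np.array(d["active_bits"], dtype=bool),
            d_min=d["d_min"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "CodeBook":
        return cls.from_dict(json.loads(Path(path).read_text()))


def positive_ratio_per_bit(codebook: CodeBook, class_freqs: Sequence[float]) -> np.ndarray:
    """Fraction of the class mass on the positive side of each bit.

    ``ratio[j] = sum of class_freqs[i] over classes whose codeword bit j is 1``.
    Ratios near 0.5 mean the induced binary task is balanced.  Returned for
    every bit position (degenerate bits included; mask with
    ``codebook.active_bits`` when needed).
    """
    freqs = np.asarray(class_freqs, dtype=float)
    if freqs.size != codebook.n_classes:
        raise ValueError(
            f"got {freqs.size} frequencies for {codebook.n_classes} classes"
        )
    if not math.isclose(freqs.sum(), 1.0, rel_tol=0, abs_tol=1e-8):
        raise ValueError("class frequencies must sum to 1")
    return freqs @ codebook.codewords


def _balance_objective(rows: np.ndarray, freqs: np.ndarray) -> float:
    """Sum of |positive ratio - 0.5| over the non-degenerate bits of ``rows``."""
    ratios = freqs @ rows
    active = ~np.all(rows == rows[0], axis=0)
    return float(np.abs(ratios[active] - 0.5).sum())


def assign_hadamard_codewords(
    class_freqs: Sequence[float],
    order: int,
    classes: Sequence | None = None,
    seed: int = 0,
    n_restarts: int = 16,
) -> CodeBook:
    """Pick Hadamard rows for each class so the induced bits are balanced.

    Selects ``K`` rows of the order-``n`` Hadamard matrix and an assignment of
    classes to rows minimizing ``sum_j |positive_ratio(j) - 0.5|`` over the
    active (non-degenerate) bits.  The search is exhaustive when the candidate
    count allows (always when the frequencies are uniform, where the
    assignment permutation is irrelevant and only the row subset matters);
    otherwise a seeded greedy local search with random restarts is used.

    Degenerate bits — constant across the selected rows, including the always-
    zero first Hadamard column — are flagged off in ``active_bits``.
    """
    freqs = np.asarray(class_freqs, dtype=float)
    k = freqs.size
    if classes is None:
        classes = list(range(1, k + 1))
    classes = list(classes)
    if len(classes) != k:
        raise ValueError("classes and class_freqs must have equal length")
    if not math.isclose(freqs.sum(), 1.0, rel_tol=0, abs_tol=1e-8):
        raise ValueError("class frequencies must sum to 1")
    matrix = build_hadamard_matrix(order)
    if k > order:
        raise ValueError(f"cannot assign {k} classes to {order} Hadamard rows")
    if k == 1:
        warnings.warn("single-class codebook: every bit is degenerate", stacklevel=2)
        return CodeBook("hadamard", order, classes, matrix[:1].copy())

    uniform = np.allclose(freqs, freqs[0])
    n_subsets = math.comb(order, k)
    n_full = n_subsets * math.factorial(k)

    best_rows: np.ndarray | None = None
    best_obj = np.inf
    if uniform and n_subsets <= _EXHAUSTIVE_BUDGET:
        for subset in itertools.combinations(range(order), k):
            rows = matrix[list(subset)]
            obj = _balance_objective(rows, freqs)
            if obj < best_obj - 1e-12:
                best_obj, best_rows = obj, rows
    elif n_full <= _EXHAUSTIVE_BUDGET:
        for subset in itertools.combinations(range(order), k):
            for perm in itertools.permutations(subset):
                rows = matrix[list(perm)]
                obj = _balance_objective(rows, freqs)
                if obj < best_obj - 1e-12:
                    best_obj, best_rows = obj, rows
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            rows_idx = list(rng.choice(order, size=k, replace=False))
            obj = _balance_objective(matrix[rows_idx], freqs)
            improved = True
            while improved:
                improved = False
                # swap a used row for an unused one
                unused = [r for r in range(order) if r not in rows_idx]
                for pos in range(k):
                    for cand in unused:
                        trial = list(rows_idx)
                        trial[pos] = cand
                        t_obj = _balance_objective(matrix[trial], freqs)
                        if t_obj < obj - 1e-12:
                            rows_idx, obj, improved = trial, t_obj, True
                            unused = [r for r in range(order) if r not in rows_idx]
                # swap the rows of two classes
                for a in range(k - 1):
                    for b in range(a + 1, k):
                        trial = list(rows_idx)
                        trial[a], trial[b] = trial[b], trial[a]
                        t_obj = _balance_objective(matrix[trial], freqs)
                        if t_obj < obj - 1e-12:
                            rows_idx, obj, improved = trial, t_obj, True
            if obj < best_obj - 1e-12:
                best_obj, best_rows = obj, matrix[rows_idx]

    assert best_rows is not None
    return CodeBook("hadamard", order, classes, best_rows.copy())
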