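"""Block-code construction, metrics, selection and assignment."""

import functools
import itertools

import numpy as np
import pytest

from ecoc_tka import codes
from ecoc_tka.codes import (
    CodeBook,
    WEIGHT_SCHEDULE,
    assign_hadamard_codewords,
    build_hadamard_matrix,
    codebook_min_distance,
    enumerate_hamming_codewords,
    error_correcting_capability,
    hamming_distance,
    hamming_parity_check,
    positive_ratio_per_bit,
    select_hamming_codewords,
)

# ---------------------------------------------------------------------------
# Hadamard matrices
# ---------------------------------------------------------------------------


def test_hadamard_base_case():
    assert build_hadamard_matrix(2).tolist() == [[0, 0], [0, 1]]


def test_hadamard_order_4_from_one_doubling():
    rows = {tuple(r) for r in build_hadamard_matrix(4)}
    assert rows == {(0, 0, 0, 0), (0, 1, 0, 1), (0, 0, 1, 1), (0, 1, 1, 0)}


@pytest.mark.parametrize("order", [2, 4, 8, 16, 32, 64])
def test_hadamard_invariants(order):
    """Row 0 all zeros; other rows weight n/2; pairwise distances all n/2."""
    m = build_hadamard_matrix(order)
    assert m.shape == (order, order)
    assert not m[0].any()
    assert (m[1:].sum(axis=1) == order // 2).all()
    for i, j in itertools.combinations(range(order), 2):
        assert hamming_distance(m[i], m[j]) == order // 2


@pytest.mark.parametrize("order", [0, 1, 3, 6, 12])
def test_hadamard_rejects_bad_order(order):
    with pytest.raises(ValueError):
        build_hadamard_matrix(order)


# ---------------------------------------------------------------------------
# Hamming codes
# ---------------------------------------------------------------------------


def test_hamming_m3_size_and_length():
    cw = enumerate_hamming_codewords(3)
    assert cw.shape == (16, 7)


def test_hamming_m4_code_facts():
    """2^11 codewords of length 15; weight set matches the selection schedule."""
    cw = enumerate_hamming_codewords(4)
    assert cw.shape == (2048, 15)
    assert sorted(set(cw.sum(axis=1).tolist())) == list(WEIGHT_SCHEDULE)
    assert not cw[0].any() or (cw.sum(axis=1) == 0).any()  # all-zeros present


@pytest.mark.parametrize("m", [3, 4])
def test_hamming_linearity_and_min_distance(m, rng):
    cw = enumerate_hamming_codewords(m)
    assert codebook_min_distance(cw) == 3
    codeset = {tuple(r) for r in cw}
    picks = rng.integers(0, len(cw), size=(200, 2))
    for i, j in picks:
        assert tuple((cw[i] ^ cw[j])) in codeset


def test_hamming_m5_min_distance_via_parity_check(rng):
    """For m=5, no weight-1/2 word exists (H columns distinct, nonzero) and a
    weight-3 word exists (two columns summing to a third), so d_min = 3;
    sampled codeword pairs respect the bound."""
    h = hamming_parity_check(5)
    cols = [tuple(c) for c in h.T]
    assert len(set(cols)) == h.shape[1]  # distinct -> no weight-2 codeword
    assert all(any(c) for c in cols)  # nonzero -> no weight-1 codeword
    g = codes.hamming_generator(5)
    # explicit weight-3 codeword: columns 0 + 1 of H sum to some column k
    target = tuple((h[:, 0] ^ h[:, 1]))
    k = cols.index(target)
    word = np.zeros(h.shape[1], dtype=np.uint8)
    word[[0, 1, k]] = 1
    assert not ((h @ word) % 2).any() and word.sum() == 3
    # sampled pairs: distances always >= 3
    msgs = rng.integers(0, 2, size=(300, g.shape[0])).astype(np.uint8)
    sampled = (msgs @ g) % 2
    for i in range(0, 298, 2):
        if (sampled[i] != sampled[i + 1]).any():
            assert hamming_distance(sampled[i], sampled[i + 1]) >= 3


def test_hamming_rejects_small_m():
    with pytest.raises(ValueError):
        enumerate_hamming_codewords(2)


# ---------------------------------------------------------------------------
# Distance metrics
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "u, v, d",
    [
        ((0, 0, 0, 0, 0), (0, 0, 0, 0, 0), 0),
        ((1, 0, 1, 0, 1), (0, 1, 0, 1, 0), 5),
        ((0, 1, 1), (0, 1, 0), 1),
    ],
)
def test_hamming_distance_examples(u, v, d):
    assert hamming_distance(u, v) == d
    assert hamming_distance(v, u) == d


def test_hamming_distance_rejects_length_mismatch():
    with pytest.raises(ValueError):
        hamming_distance((0, 1), (0, 1, 0))


def test_min_distance_matches_brute_force(rng):
    words = rng.integers(0, 2, size=(12, 10)).astype(np.uint8)
    words = np.unique(words, axis=0)
    expected = min(
        hamming_distance(a, b) for a, b in itertools.combinations(words, 2)
    )
    assert codebook_min_distance(words) == expected


def test_min_distance_single_codeword_errors():
    with pytest.raises(ValueError):
        codebook_min_distance(np.array([[0, 0]], dtype=np.uint8))


@pytest.mark.parametrize("d_min, t", [(1, 0), (3, 1), (8, 3)])
def test_error_correcting_capability_examples(d_min, t):
    assert error_correcting_capability(d_min) == t


def test_error_correcting_capability_closed_form():
    for d in range(1, 41):
        t = error_correcting_capability(d)
        assert 2 * t + 1 <= d  # the defining bound
        assert 2 * (t + 1) + 1 > d  # t is maximal
        assert t == (d - 1) // 2


def test_error_correcting_capability_rejects_zero():
    with pytest.raises(ValueError):
        error_correcting_capability(0)


# ---------------------------------------------------------------------------
# Greedy selection (independent brute-force oracle)
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=1)
def _oracle_code():
    """The (15, 11) Hamming code by exhaustive syndrome test over all 2^15
    length-15 words — independent of the package's generator construction."""
    h = hamming_parity_check(4)
    words = []
    for v in range(2 ** 15):
        w = np.array([(v >> (14 - j)) & 1 for j in range(15)], dtype=np.uint8)
        if not ((h @ w) % 2).any():
            words.append(tuple(int(b) for b in w))
    return words


def oracle_selection(n_needed: int):
    """Literal step-by-step re-implementation of the selection procedure."""
    words = _oracle_code()
    weights = [0, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 15]
    ordered = sorted(
        (w for w in words if any(w)),
        key=lambda w: (sum(w), int("".join(map(str, w)), 2)),
    )
    i = 11
    while True:
        dist_min = weights[i]
        selected = [tuple([0] * 15)]
        pool = list(ordered)
        done = False
        while len(selected) < n_needed:
            last = selected[-1]
            pool = [
                w for w in pool
                if sum(a != b for a, b in zip(w, last)) >= dist_min
            ]
            if not pool:
                break
            selected.append(pool.pop(0))
        if len(selected) >= n_needed or i == 0:
            return [list(w) for w in selected[:n_needed]], weights[i]
        i -= 1


@pytest.mark.parametrize("n", [1, 2, 8, 9])
def test_selection_matches_independent_oracle(n):
    got, d_got = select_hamming_codewords(n)
    want, d_want = oracle_selection(n)
    assert got.tolist() == want
    assert d_got == d_want


def test_selection_n1_is_all_zeros():
    words, _ = select_hamming_codewords(1)
    assert words.tolist() == [[0] * 15]


def test_selection_n2_is_zeros_and_ones_at_distance_15():
    words, d = select_hamming_codewords(2)
    assert words.tolist() == [[0] * 15, [1] * 15]
    assert d == 15
    assert hamming_distance(words[0], words[1]) == 15


@pytest.mark.parametrize("n", [3, 8, 9, 16])
def test_selection_min_distance_guarantee_and_reproducibility(n):
    words, d = select_hamming_codewords(n)
    assert words.shape[0] == n
    assert not words[0].any()  # all-zeros first
    assert codebook_min_distance(words) >= d
    again, d2 = select_hamming_codewords(n)
    assert (words == again).all() and d == d2


def test_selection_rejects_out_of_range():
    with pytest.raises(ValueError):
        select_hamming_codewords(0)
    with pytest.raises(ValueError):
        select_hamming_codewords(2049)


# ---------------------------------------------------------------------------
# Hadamard assignment and positive ratios
# ---------------------------------------------------------------------------


def test_assignment_k8_uniform_matches_exhaustive_subset_search():
    """With uniform frequencies the permutation is irrelevant; the balance
    objective of the returned codebook must equal the exhaustive minimum
    over all 16-choose-8 row subsets."""
    freqs = np.full(8, 1 / 8)
    cb = assign_hadamard_codewords(freqs, 16)
    matrix = build_hadamard_matrix(16)

    def objective(rows):
        ratios = freqs @ rows
        active = ~np.all(rows == rows[0], axis=0)
        return np.abs(ratios[active] - 0.5).sum()

    best = min(
        objective(matrix[list(sub)])
        for sub in itertools.combinations(range(16), 8)
    )
    assert objective(cb.codewords) == pytest.approx(best)


def test_assignment_single_class_warns_all_degenerate():
    with pytest.warns(UserWarning):
        cb = assign_hadamard_codewords([1.0], 16)
    assert cb.n_classes == 1
    assert not cb.active_bits.any()


def test_assignment_all_rows_excludes_constant_first_column():
    cb = assign_hadamard_codewords(np.full(16, 1 / 16), 16)
    assert cb.n_classes == 16
    # the first Hadamard column is all zeros -> degenerate
    col0 = cb.codewords[:, 0]
    assert not col0.any()
    assert not cb.active_bits[0]
    assert cb.active_bits[1:].all()


def test_assignment_rejects_too_many_classes():
    with pytest.raises(ValueError):
        assign_hadamard_codewords(np.full(17, 1 / 17), 16)


def test_assignment_nonuniform_greedy_is_seeded_and_reproducible():
    freqs = np.array([0.02, 0.08, 0.15, 0.25, 0.25, 0.15, 0.08, 0.02])
    a = assign_hadamard_codewords(freqs, 16, seed=7, n_restarts=4)
    b = assign_hadamard_codewords(freqs, 16, seed=7, n_restarts=4)
    assert (a.codewords == b.codewords).all()
    assert a.d_min == 8  # Hadamard rows keep their pairwise n/2 distance


@pytest.mark.parametrize(
    "codewords, freqs, expected",
    [
        ([[0, 0], [1, 1]], [0.5, 0.5], [0.5, 0.5]),
        ([[0], [1]], [0.9, 0.1], [0.1]),
    ],
)
def test_positive_ratio_examples(codewords, freqs, expected):
    cb = CodeBook("hadamard", len(codewords[0]), list(range(len(codewords))), np.array(codewords))
    assert positive_ratio_per_bit(cb, freqs).tolist() == pytest.approx(expected)


def test_positive_ratio_of_balanced_assignment_strictly_interior():
    from ecoc_tka.synthetic import _bell_probs

    freqs = _bell_probs(8, 2.0)
    cb = assign_hadamard_codewords(freqs, 16, seed=0)
    ratios = positive_ratio_per_bit(cb, freqs)[cb.active_bits]
    assert ((ratios > 0) & (ratios < 1)).all()


def test_positive_ratio_rejects_mismatched_freqs(hadamard16_codebook):
    with pytest.raises(ValueError):
        positive_ratio_per_bit(hadamard16_codebook, [0.5, 0.5])


def test_codebook_json_round_trip(tmp_path, hadamard16_codebook):
    path = tmp_path / "cb.json"
    hadamard16_codebook.save(path)
    back = CodeBook.load(path)
    assert (back.codewords == hadamard16_codebook.codewords).all()
    assert back.d_min == hadamard16_codebook.d_min
    assert (back.active_bits == hadamard16_codebook.active_bits).all()
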