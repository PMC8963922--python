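"""Correlation statistics, classification metrics and the comparison report."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecoc_tka.codes import CodeBook, assign_hadamard_codewords
from ecoc_tka.decoder import BitLabelCounts
from ecoc_tka.evaluation import (
    code_length_advisor,
    compare_methods,
    correlation_table,
    pearson_r,
    per_bit_accuracy,
    significance_threshold,
    t_statistic,
    top_k_accuracy,
)
from ecoc_tka.synthetic import CohortConfig, generate_cohort


def test_pearson_perfect_linear_relations(rng):
    x = rng.normal(size=50)
    assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
    assert pearson_r(x, -x) == pytest.approx(-1.0)


def test_pearson_affine_invariance(rng):
    x, y = rng.normal(size=40), rng.normal(size=40)
    assert pearson_r(3 * x - 7, y) == pytest.approx(pearson_r(x, y))


def test_pearson_rejects_zero_variance():
    with pytest.raises(ValueError):
        pearson_r([1, 1, 1], [1, 2, 3])


@pytest.mark.parametrize(
    "r, printed, decimals",
    [
        (0.6151, 13.65, 2),
        (0.6345, 14.36, 2),
        (0.4134, 7.943, 3),
        (0.6314, 14.24, 2),
        (0.6452, 14.77, 2),
        (0.4300, 8.331, 3),
    ],
)
def test_t_statistic_round_trips_reference_grid(r, printed, decimals):
    """Each reference t value is recovered from its correlation at n=308 to
    within 1.5 units of the last printed digit (the published t values were
    computed from unrounded correlations, so sub-ulp agreement from the
    rounded r is not attainable for every cell)."""
    assert abs(t_statistic(r, 308) - printed) <= 1.5 * 10 ** (-decimals)


def test_t_statistic_basics():
    assert t_statistic(0.0, 100) == 0.0
    assert t_statistic(-0.5, 50) == -t_statistic(0.5, 50)
    assert t_statistic(0.6, 300) > t_statistic(0.5, 300) > t_statistic(0.5, 100)
    with pytest.raises(ValueError):
        t_statistic(1.0, 100)


def test_significance_threshold_matches_t_distribution():
    # large-sample two-sided 99% threshold approaches the normal 2.576
    assert significance_threshold(308) == pytest.approx(2.5924, abs=1e-3)


def test_correlation_table_shape_and_significance():
    cohort = generate_cohort(CohortConfig(n_patients=1000, seed=8))
    table = correlation_table(cohort)
    assert set(table) == {"femoral", "tibial"}
    for row in table.values():
        assert set(row) == {"gender", "height", "weight"}
        for res in row.values():
            assert res.t_value > significance_threshold(res.n)
            assert res.t_value == pytest.approx(t_statistic(res.r, res.n))


# ---------------------------------------------------------------------------
# top-k accuracy
# ---------------------------------------------------------------------------


def test_top_k_examples():
    rankings = [[1, 2, 3], [2, 1, 3], [3, 2, 1]]
    truths = [1, 1, 1]
    assert top_k_accuracy(rankings, truths, k=3) == 1.0
    assert top_k_accuracy(rankings, truths, k=1) == pytest.approx(1 / 3)


@settings(derandomize=True, max_examples=30)
@given(st.integers(1, 8), st.integers(1, 8))
def test_top_k_nondecreasing_in_k(k1, k2):
    rng = np.random.default_rng(99)
    rankings = [list(rng.permutation(8) + 1) for _ in range(40)]
    truths = list(rng.integers(1, 9, size=40))
    lo, hi = sorted((k1, k2))
    assert top_k_accuracy(rankings, truths, lo) <= top_k_accuracy(rankings, truths, hi)


def test_top_k_saturates_at_class_count():
    rankings = [[2, 1], [1, 2]]
    assert top_k_accuracy(rankings, [1, 2], k=5) == 1.0


def test_top_k_rejects_empty():
    with pytest.raises(ValueError):
        top_k_accuracy([], [], 3)


# ---------------------------------------------------------------------------
# per-bit diagnostics and the code-length advisor
# ---------------------------------------------------------------------------


def test_per_bit_accuracy_perfect_outputs(hadamard16_codebook):
    truths = list(range(16))
    outputs = hadamard16_codebook.codewords.astype(float)
    acc = per_bit_accuracy(outputs, hadamard16_codebook, truths)
    assert acc.shape == (int(hadamard16_codebook.active_bits.sum()),)
    assert (acc == 1.0).all()


def test_per_bit_accuracy_constant_half_output():
    cb = CodeBook("hadamard", 2, [0, 1], np.array([[0, 0], [1, 1]]))
    outputs = np.full((10, 2), 0.5)  # hardens to 1 everywhere
    truths = [0] * 5 + [1] * 5
    acc = per_bit_accuracy(outputs, cb, truths)
    assert acc.tolist() == [0.5, 0.5]


def test_code_length_advisor_thresholds():
    up = code_length_advisor([0.9] * 14)
    assert up.all_above and "doubling" in up.recommendation
    assert up.capability_gain_bits == pytest.approx(3.5)
    down = code_length_advisor([0.9, 0.7, 0.6, 0.74])
    assert not down.all_above and "retain" in down.recommendation
    assert down.fraction_above == pytest.approx(0.25)
    with pytest.raises(ValueError):
        code_length_advisor([])


# ---------------------------------------------------------------------------
# compare_methods
# ---------------------------------------------------------------------------


@pytest.fixture()
def two_component_setup(rng):
    books = {
        "femoral": assign_hadamard_codewords(np.full(8, 1 / 8), 16, seed=0),
        "tibial": assign_hadamard_codewords(np.full(9, 1 / 9), 16, seed=0),
    }
    # every class appears at least once so no training bit is one-sided
    truths = {
        "femoral": list(range(1, 9)) + list(rng.integers(1, 9, size=22)),
        "tibial": list(range(1, 10)) + list(rng.integers(1, 10, size=21)),
    }
    counts = {c: BitLabelCounts.from_labels(truths[c], books[c]) for c in books}
    outputs = {
        c: np.array([books[c].codeword_for(t) for t in truths[c]], dtype=float)
        for c in books
    }
    return outputs, books, counts, truths


def test_compare_methods_perfect_outputs_all_one(two_component_setup):
    outputs, books, counts, truths = two_component_setup
    report = compare_methods(outputs, books, counts, truths, k=3, seed=1)
    assert set(report.method_top_k) == {"I", "II", "III", "IV"}
    for accs in report.method_top_k.values():
        assert set(accs) == {"femoral", "tibial"}
        assert all(a == 1.0 for a in accs.values())
    assert all((np.array(v) == 1.0).all() for v in report.per_bit.values())


def test_compare_methods_hard_rule_absorbs_within_capability_flips(
    two_component_setup, rng
):
    outputs, books, counts, truths = two_component_setup
    t = 3  # Hadamard-16 capability
    noisy = {}
    for comp, probs in outputs.items():
        active_idx = np.flatnonzero(books[comp].active_bits)
        probs = probs.copy()
        for row in probs:
            flips = rng.choice(active_idx, size=rng.integers(0, t + 1), replace=False)
            row[flips] = 1 - row[flips]
        noisy[comp] = probs
    report = compare_methods(noisy, books, counts, truths, k=1)
    assert report.method_top_k["I"]["femoral"] == 1.0
    assert report.method_top_k["I"]["tibial"] == 1.0


def test_soft_rules_not_below_hard_on_graded_outputs(two_component_setup, rng):
    """Blur the perfect outputs toward 0.5 without crossing it: hard decisions
    are unchanged while soft distances retain the ordering, so Methods III/IV
    cannot fall below Method I."""
    outputs, books, counts, truths = two_component_setup
    graded = {
        c: np.abs(p - rng.uniform(0.05, 0.45, size=p.shape))
        for c, p in outputs.items()
    }
    report = compare_methods(graded, books, counts, truths, k=3)
    for comp in ("femoral", "tibial"):
        assert report.method_top_k["III"][comp] >= report.method_top_k["I"][comp]
        assert report.method_top_k["IV"][comp] >= report.method_top_k["I"][comp]


def test_compare_methods_requires_matching_components(two_component_setup):
    outputs, books, counts, truths = two_component_setup
    with pytest.raises(ValueError):
        compare_methods(outputs, {"femoral": books["femoral"]}, counts, truths)


def test_report_json_round_trip(two_component_setup, tmp_path):
    import json

    outputs, books, counts, truths = two_component_setup
    report = compare_methods(outputs, books, counts, truths, k=3, seed=42)
    path = tmp_path / "report.json"
    report.save(path)
    data = json.loads(path.read_text())
    assert data["seed"] == 42
    assert set(data["method_top_k"]) == {"I", "II", "III", "IV"}
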