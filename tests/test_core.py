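"""Fitness-score primitives: entropy, per-row scores, module scores."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ibbig import (
    AssociationMatrix,
    GAParams,
    InvalidModuleError,
    ParameterError,
    WeightMatrix,
    association_probability,
    entropy,
    geneset_score,
    module_score,
    weighted_module_score,
)
from ibbig.core import module_scores_batch


class TestEntropy:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (0.5, 1.0),
            (0.0, 0.0),
            (1.0, 0.0),
            (0.25, 0.8112781244591329),  # closed-form Shannon value
            (2 / 3, 0.9182958340544895),
        ],
    )
    def test_closed_forms(self, p, expected):
        assert entropy(p) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_bounded(self, p):
        h = entropy(p)
        assert 0.0 <= h <= 1.0
        assert h == pytest.approx(entropy(1.0 - p), abs=1e-12)

    def test_maximum_exactly_at_half(self):
        grid = np.linspace(0, 1, 201)
        h = entropy(grid)
        assert grid[np.argmax(h)] == pytest.approx(0.5)
        assert h.max() == pytest.approx(1.0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            entropy(1.2)
        with pytest.raises(ValueError):
            entropy(-0.1)

    def test_vectorized(self):
        h = entropy(np.array([0.0, 0.5, 1.0]))
        assert np.allclose(h, [0.0, 1.0, 0.0])


class TestAssociationProbability:
    def test_all_associated(self):
        assert association_probability([1, 1, 1, 0], [0, 1, 2]) == 1.0

    def test_partial(self):
        assert association_probability([1, 1, 0, 0], [0, 1, 2]) == pytest.approx(2 / 3)

    def test_none(self):
        assert association_probability([0, 0, 0, 0], [0, 1]) == 0.0

    def test_invalid_module(self):
        with pytest.raises(InvalidModuleError):
            association_probability([1, 0, 1], [0])
        with pytest.raises(InvalidModuleError):
            association_probability([1, 0, 1], [0, 5])
        with pytest.raises(InvalidModuleError):
            association_probability([1, 0, 1], [0, 0])


class TestGenesetScore:
    # frozen closed-form evaluations of k^a * (1-H)^(1-a) * count
    def test_fully_associated_row(self):
        s = geneset_score([1, 1, 1, 0], [0, 1, 2], alpha=0.3)
        assert s == pytest.approx(4.171167510947728, rel=1e-12)  # 3^1.3

    def test_gradient_row(self):
        s = geneset_score([1, 1, 0, 0], [0, 1, 2], alpha=0.3)
        assert s == pytest.approx(0.4816563749608137, rel=1e-12)

    def test_gate_at_half(self):
        for alpha in (0.1, 0.3, 0.9):
            assert geneset_score([1, 0, 0, 0], [0, 1, 2], alpha) == 0.0
        # exactly p = 0.5 is still gated
        assert geneset_score([1, 1, 0, 0], [0, 1, 2, 3], 0.3) == 0.0

    def test_gate_for_random_rows(self, rng):
        for _ in range(50):
            row = (rng.random(10) < 0.5).astype(float)
            cols = rng.choice(10, size=4, replace=False)
            p = association_probability(row, cols)
            s = geneset_score(row, cols, 0.3)
            assert (s == 0.0) == (p <= 0.5)

    def test_strictly_increasing_in_p(self):
        k = 20
        scores = []
        for p in np.arange(0.55, 1.0001, 0.05):
            row = np.zeros(k)
            row[: int(round(p * k))] = 1
            scores.append(geneset_score(row, list(range(k)), 0.3))
        assert np.all(np.diff(scores) > 0)

    def test_increasing_in_k_at_fixed_p(self):
        # p = 0.75 at k = 4, 8, 16
        vals = []
        for k in (4, 8, 16):
            row = np.zeros(k)
            row[: (3 * k) // 4] = 1
            vals.append(geneset_score(row, list(range(k)), 0.3))
        assert vals[0] < vals[1] < vals[2]

    def test_increasing_in_alpha_for_heterogeneous_rows(self):
        # alpha shifts credit toward wide, imperfect rows: both the k^a
        # reward and the weakened homogeneity penalty grow with alpha
        row = [1, 1, 1, 0]
        a, b = (
            geneset_score(row, [0, 1, 2, 3], 0.3),
            geneset_score(row, [0, 1, 2, 3], 0.5),
        )
        assert b > a

    def test_alpha_out_of_domain(self):
        with pytest.raises(ParameterError):
            geneset_score([1, 1], [0, 1], alpha=0.0)


class TestModuleScore:
    def test_three_row_example(self, tiny_matrix):
        S, per_row = module_score(tiny_matrix.to_weights(), [0, 1, 2], 0.3)
        assert per_row[0] == pytest.approx(4.171167510947728, rel=1e-12)
        assert per_row[1] == pytest.approx(0.4816563749608137, rel=1e-12)
        assert per_row[2] == 0.0
        assert S == pytest.approx(4.652823885908542, rel=1e-12)

    def test_zero_matrix(self):
        S, per_row = module_score(np.zeros((5, 6)), [0, 1, 2], 0.3)
        assert S == 0.0 and not per_row.any()

    def test_all_ones_matrix(self):
        # every p_i = 1: S = n * k^(1+alpha)
        n, k = 7, 4
        S, _ = module_score(np.ones((n, 6)), list(range(k)), 0.3)
        assert S == pytest.approx(n * k**1.3, rel=1e-12)

    def test_additive_over_rows(self, rng):
        W = (rng.random((20, 8)) < 0.4).astype(float)
        cols = [1, 3, 5]
        S, _ = module_score(W, cols, 0.3)
        perm = rng.permutation(20)
        S_perm, _ = module_score(W[perm], cols, 0.3)
        S_a, _ = module_score(W[:11], cols, 0.3)
        S_b, _ = module_score(W[11:], cols, 0.3)
        assert S == pytest.approx(S_perm, rel=1e-12)
        assert S == pytest.approx(S_a + S_b, rel=1e-12)

    def test_batch_matches_scalar(self, rng):
        W = (rng.random((15, 10)) < 0.4).astype(float)
        members = (rng.random((8, 10)) < 0.4).astype(np.uint8)
        fits = module_scores_batch(W, members, 0.3)
        for i in range(8):
            cols = np.flatnonzero(members[i])
            expected = 0.0 if cols.size < 2 else module_score(W, cols, 0.3)[0]
            assert fits[i] == pytest.approx(expected, rel=1e-9, abs=1e-12)


class TestWeightedScore:
    def test_log_identity(self):
        # (k/m) * S = 1 maps to 0
        assert weighted_module_score(4 / 3, 3, 4) == pytest.approx(0.0, abs=1e-12)

    def test_module_example(self):
        assert weighted_module_score(4.652823885908542, 3, 4) == pytest.approx(
            1.2497922501153373, rel=1e-12
        )

    def test_zero_score_sentinel(self):
        assert weighted_module_score(0.0, 3, 4) == float("-inf")

    def test_invalid_k(self):
        with pytest.raises(InvalidModuleError):
            weighted_module_score(1.0, 5, 4)
        with pytest.raises(InvalidModuleError):
            weighted_module_score(1.0, 1, 4)


class TestContainers:
    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="binary"):
            AssociationMatrix(np.array([[0.7, 1], [0, 1]]))

    def test_rejects_single_column(self):
        with pytest.raises(ValueError):
            AssociationMatrix(np.array([[1], [0]]))

    def test_rejects_duplicate_labels(self):
        with pytest.raises(ValueError, match="unique"):
            AssociationMatrix(np.eye(2, dtype=int), row_ids=["x", "x"], col_ids=["p", "q"])

    def test_weights_equal_matrix_on_first_iteration(self, tiny_matrix):
        w = tiny_matrix.to_weights()
        assert np.array_equal(w.values, tiny_matrix.values)
        assert w.row_ids == tiny_matrix.row_ids

    def test_weight_matrix_range_check(self):
        with pytest.raises(ValueError):
            WeightMatrix(np.array([[0.5, 1.5]]), ["a"], ["p", "q"])

    def test_dataframe_roundtrip(self, tiny_matrix):
        df = tiny_matrix.to_dataframe()
        again = AssociationMatrix.from_dataframe(df)
        assert np.array_equal(again.values, tiny_matrix.values)
        assert again.col_ids == tiny_matrix.col_ids


class TestGAParams:
    def test_defaults(self):
        p = GAParams()
        assert (p.alpha, p.pop_size, p.mutation_rate) == (0.3, 100, 0.08)
        assert (p.success_ratio, p.selection_pressure, p.stagnation) == (0.6, 1.2, 50)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 1.0},
            {"alpha": 0.0},
            {"selection_pressure": 2.5},
            {"mutation_rate": -0.1},
            {"pop_size": 1},
            {"stagnation": 0},
            {"n_modules": 0},
            {"success_ratio": 0.0},
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ParameterError):
            GAParams(**kwargs)
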