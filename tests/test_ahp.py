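"""AHP: matrix construction, weight derivation, consistency, aggregation."""

import numpy as np
import pytest

from postfire_mca.ahp import (
    SAATY_RANDOM_INDEX,
    ComparisonMatrix,
    WeightVector,
    aggregate_weights,
    build_comparison_matrix,
    consistency_ratio,
    derive_weights,
    principal_eigenvalue,
    rank_alternatives,
    read_judgments_csv,
    read_weights_csv,
    write_judgments_csv,
    write_weights_csv,
)
from postfire_mca.errors import (
    CriteriaOrderError,
    IncompleteJudgmentsError,
    JudgmentDomainError,
    UnsupportedMatrixSizeError,
)


def power_iteration_lambda(a: np.ndarray, iters: int = 5000) -> float:
    """Independent dominant-eigenvalue oracle (power method)."""
    v = np.ones(a.shape[0]) / a.shape[0]
    for _ in range(iters):
        w = a @ v
        v = w / np.linalg.norm(w)
    return float(v @ a @ v / (v @ v))


def consistent_matrix(w, names=None) -> ComparisonMatrix:
    w = np.asarray(w, dtype=float)
    names = names or tuple(f"c{i}" for i in range(len(w)))
    return ComparisonMatrix(names, w[:, None] / w[None, :])


def random_reciprocal(rng, n) -> ComparisonMatrix:
    scale = [1 / k for k in range(9, 1, -1)] + list(range(1, 10))
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = rng.choice(scale)
            m[j, i] = 1 / m[i, j]
    return ComparisonMatrix(tuple(f"c{i}" for i in range(n)), m)


class TestBuildComparisonMatrix:
    def test_missing_pair_rejected(self):
        with pytest.raises(IncompleteJudgmentsError):
            build_comparison_matrix(["a", "b"], {})

    def test_reciprocal_fill(self):
        m = build_comparison_matrix(["a", "b"], {(0, 1): 3})
        np.testing.assert_allclose(m.entries, [[1, 3], [1 / 3, 1]])

    def test_transitive_judgments_give_consistent_matrix(self):
        m = build_comparison_matrix(
            ["a", "b", "c"], {(0, 1): 2, (0, 2): 6, (1, 2): 3}
        )
        a = m.entries
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    assert a[i, k] == pytest.approx(a[i, j] * a[j, k])

    def test_nonpositive_value_rejected(self):
        with pytest.raises(JudgmentDomainError):
            build_comparison_matrix(["a", "b"], {(0, 1): -2})

    def test_strict_scale_flag(self):
        with pytest.raises(JudgmentDomainError):
            build_comparison_matrix(["a", "b"], {(0, 1): 2.7}, strict_scale=True)
        build_comparison_matrix(["a", "b"], {(0, 1): 1 / 7}, strict_scale=True)

    def test_invariants_enforced_on_direct_construction(self):
        with pytest.raises(ValueError):
            ComparisonMatrix(("a", "b"), np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError):
            ComparisonMatrix(("a",), np.array([[1.0]]))


class TestDeriveWeights:
    def test_all_ones_gives_uniform(self):
        m = ComparisonMatrix(("a", "b", "c"), np.ones((3, 3)))
        np.testing.assert_allclose(derive_weights(m).weights, 1 / 3, atol=1e-12)

    def test_consistent_matrix_recovers_weights(self):
        w = np.array([0.6, 0.3, 0.1])
        got = derive_weights(consistent_matrix(w)).weights
        np.testing.assert_allclose(got, w, atol=1e-9)

    def test_close_to_principal_eigenvector(self):
        m = ComparisonMatrix(
            ("a", "b", "c"),
            np.array([[1, 2, 4], [0.5, 1, 3], [0.25, 1 / 3, 1]]),
        )
        vals, vecs = np.linalg.eig(m.entries)
        v = vecs[:, np.argmax(vals.real)].real
        oracle = v / v.sum()
        np.testing.assert_allclose(derive_weights(m).weights, oracle, atol=0.02)

    def test_weights_sum_to_one_randomized(self):
        rng = np.random.default_rng(42)
        for n in range(3, 8):
            for _ in range(5):
                w = derive_weights(random_reciprocal(rng, n)).weights
                assert abs(w.sum() - 1.0) < 1e-9
                assert np.all(w > 0)


class TestConsistencyRatio:
    def test_consistent_matrix_has_zero_cr(self):
        rep = consistency_ratio(consistent_matrix([0.5, 0.3, 0.15, 0.05]))
        assert rep.lambda_max == pytest.approx(4.0, abs=1e-9)
        assert rep.ci == pytest.approx(0.0, abs=1e-9)
        assert rep.cr == pytest.approx(0.0, abs=1e-9)
        assert rep.acceptable

    def test_mildly_inconsistent_matrix(self):
        m = ComparisonMatrix(
            ("a", "b", "c"),
            np.array([[1, 2, 4], [0.5, 1, 3], [0.25, 1 / 3, 1]]),
        )
        rep = consistency_ratio(m)
        lam_oracle = max(np.linalg.eigvals(m.entries).real)
        assert rep.lambda_max == pytest.approx(lam_oracle, abs=1e-9)
        assert rep.cr == pytest.approx((lam_oracle - 3) / 2 / 0.58, abs=1e-9)
        assert rep.cr < 0.1 and rep.acceptable

    def test_intransitive_matrix_rejected(self):
        m = ComparisonMatrix(
            ("a", "b", "c"),
            np.array([[1, 9, 1 / 9], [1 / 9, 1, 9], [9, 1 / 9, 1]]),
        )
        rep = consistency_ratio(m)
        assert rep.cr >= 0.1
        assert not rep.acceptable

    def test_two_criteria_always_acceptable(self):
        m = build_comparison_matrix(["a", "b"], {(0, 1): 9})
        rep = consistency_ratio(m)
        assert rep.cr == 0.0 and rep.acceptable

    def test_unsupported_size_errors(self):
        n = 11
        w = np.linspace(1, 2, n)
        m = ComparisonMatrix(tuple(f"c{i}" for i in range(n)), w[:, None] / w[None, :])
        with pytest.raises(UnsupportedMatrixSizeError):
            consistency_ratio(m)
        # a longer RI table makes the same matrix scoreable
        rep = consistency_ratio(m, random_index=SAATY_RANDOM_INDEX + (1.51,))
        assert rep.acceptable

    def test_lambda_max_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(3)
        for n in (3, 4, 5):
            for _ in range(10):
                m = random_reciprocal(rng, n)
                lam = principal_eigenvalue(m)
                assert lam == pytest.approx(power_iteration_lambda(m.entries), abs=1e-6)
                assert lam >= n - 1e-9

    def test_lambda_max_at_least_n(self):
        rng = np.random.default_rng(11)
        for n in range(3, 8):
            for _ in range(10):
                assert principal_eigenvalue(random_reciprocal(rng, n)) >= n - 1e-9


class TestPermutationEquivariance:
    def test_permuting_criteria_permutes_weights_and_preserves_cr(self):
        rng = np.random.default_rng(5)
        m = random_reciprocal(rng, 5)
        perm = rng.permutation(5)
        pm = ComparisonMatrix(
            tuple(m.criteria_names[k] for k in perm),
            m.entries[np.ix_(perm, perm)],
        )
        np.testing.assert_allclose(
            derive_weights(pm).weights, derive_weights(m).weights[perm], atol=1e-9
        )
        assert consistency_ratio(pm).cr == pytest.approx(
            consistency_ratio(m).cr, abs=1e-9
        )


class TestAggregateWeights:
    def test_single_participant_identity(self):
        wv = WeightVector(("a", "b"), np.array([0.7, 0.3]))
        np.testing.assert_allclose(aggregate_weights([wv]).weights, wv.weights)

    def test_symmetric_pair_averages_to_half(self):
        a = WeightVector(("x", "y"), np.array([0.6, 0.4]))
        b = WeightVector(("x", "y"), np.array([0.4, 0.6]))
        np.testing.assert_allclose(aggregate_weights([a, b]).weights, [0.5, 0.5])

    def test_componentwise_mean(self):
        vs = [
            WeightVector(("a", "b", "c"), np.array(w))
            for w in ([0.7, 0.2, 0.1], [0.5, 0.3, 0.2], [0.6, 0.2, 0.2])
        ]
        np.testing.assert_allclose(
            aggregate_weights(vs).weights, [0.6, 0.7 / 3, 0.5 / 3], atol=1e-12
        )

    def test_mismatched_criteria_rejected(self):
        a = WeightVector(("a", "b"), np.array([0.5, 0.5]))
        b = WeightVector(("b", "a"), np.array([0.5, 0.5]))
        with pytest.raises(CriteriaOrderError):
            aggregate_weights([a, b])


class TestRankAlternatives:
    def test_one_hot_projects_row(self):
        w = WeightVector(("a", "b"), np.array([1.0, 0.0]))
        x = np.array([[1.0, 2.0, 3.0], [9.0, 9.0, 9.0]])
        np.testing.assert_allclose(rank_alternatives(w, x), [1, 2, 3])

    def test_identical_columns_tie(self):
        w = WeightVector(("a", "b"), np.array([0.3, 0.7]))
        x = np.array([[2.0, 2.0], [5.0, 5.0]])
        out = rank_alternatives(w, x)
        assert out[0] == pytest.approx(out[1])

    def test_hand_example(self):
        w = WeightVector(("a", "b"), np.array([0.5, 0.5]))
        x = np.array([[1.0, 2.0], [3.0, 0.0]])
        np.testing.assert_allclose(rank_alternatives(w, x), [2.0, 1.0])

    def test_dimension_mismatch(self):
        w = WeightVector(("a", "b"), np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            rank_alternatives(w, np.ones((3, 2)))


class TestCSVRoundtrip:
    def test_judgments_roundtrip(self, tmp_path):
        rng = np.random.default_rng(8)
        mats = {"p1": random_reciprocal(rng, 4), "p2": random_reciprocal(rng, 4)}
        path = write_judgments_csv(mats, tmp_path / "j.csv")
        back = read_judgments_csv(path)
        assert set(back) == {"p1", "p2"}
        for pid in mats:
            np.testing.assert_allclose(
                back[pid].entries, mats[pid].entries, rtol=1e-9
            )
            assert back[pid].criteria_names == mats[pid].criteria_names

    def test_weights_roundtrip(self, tmp_path):
        wv = {"p1": WeightVector(("a", "b", "c"), np.array([0.5, 0.3, 0.2]))}
        path = write_weights_csv(wv, tmp_path / "w.csv")
        back = read_weights_csv(path)
        np.testing.assert_allclose(back["p1"].weights, wv["p1"].weights, atol=1e-12)
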