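"""AHP-TOPSIS weighting and composite-value ranking."""

import numpy as np
import pytest

from herbiscreen.mcda import (
    CompositeRanking,
    CriterionCosines,
    PairwiseMatrix,
    ScoreMatrix,
    WeightVector,
    ahp_weights,
    best_worst_vectors,
    compound_weights,
    composite_value,
    normalize_scores,
    objective_weights,
    percent_vs_reference,
    relative_error_cosines,
)


def make_scores(values, tags, ids=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ScoreMatrix(
        compound_ids=ids or [f"C{i}" for i in range(n)],
        criterion_ids=[f"crit{j}" for j in range(m)],
        indicator_types=list(tags),
        values=values)


def power_iteration(a, iters=2000):
    """Independent principal-eigenvector oracle."""
    v = np.ones(a.shape[0])
    lam = 0.0
    for _ in range(iters):
        v2 = a @ v
        lam = np.linalg.norm(v2)
        v = v2 / lam
    return v / v.sum(), float((a @ v)[0] / v[0])


class TestAhpWeights:
    def test_identity_case(self):
        w, cr = ahp_weights(PairwiseMatrix(np.array([[1.0]])))
        assert w.weights == pytest.approx([1.0])
        assert cr == 0.0

    def test_consistent_ratio_matrix_recovers_ratios(self):
        ratios = np.array([2.0, 1.0, 1.0])
        a = np.outer(ratios, 1.0 / ratios)
        w, cr = ahp_weights(PairwiseMatrix(a))
        assert w.weights == pytest.approx([0.5, 0.25, 0.25], abs=1e-12)
        assert cr == pytest.approx(0.0, abs=1e-9)

    def test_inconsistent_matrix_matches_power_iteration(self):
        a = np.array([[1.0, 2.0, 4.0],
                      [0.5, 1.0, 3.0],
                      [0.25, 1 / 3.0, 1.0]])
        w, _ = ahp_weights(PairwiseMatrix(a))
        v, _ = power_iteration(a)
        assert w.weights == pytest.approx(v, abs=1e-8)

    def test_two_by_two_cr_is_zero(self):
        _, cr = ahp_weights(PairwiseMatrix(np.array([[1.0, 3.0], [1 / 3.0, 1.0]])))
        assert cr == 0.0

    def test_high_inconsistency_warns(self):
        a = np.array([[1.0, 9.0, 1 / 9.0],
                      [1 / 9.0, 1.0, 9.0],
                      [9.0, 1 / 9.0, 1.0]])
        with pytest.warns(UserWarning, match="consistency"):
            ahp_weights(PairwiseMatrix(a))

    @pytest.mark.parametrize("bad", [
        np.array([[1.0, 2.0], [2.0, 1.0]]),      # non-reciprocal
        np.array([[1.0, -2.0], [-0.5, 1.0]]),    # non-positive
        np.array([[2.0, 2.0], [0.5, 1.0]]),      # diagonal != 1
    ])
    def test_invalid_matrix_rejected(self, bad):
        with pytest.raises(ValueError):
            PairwiseMatrix(bad)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_consistent_matrix_exact_recovery(self, seed):
        rng = np.random.default_rng(seed)
        ratios = rng.uniform(0.5, 5.0, size=rng.integers(3, 7))
        a = np.outer(ratios, 1.0 / ratios)
        w, cr = ahp_weights(PairwiseMatrix(a))
        assert w.weights == pytest.approx(ratios / ratios.sum(), abs=1e-10)
        assert cr == pytest.approx(0.0, abs=1e-9)


class TestNormalizeScores:
    @pytest.mark.parametrize("col,tag,expected", [
        ([2, 4, 6], "positive", [0.0, 0.5, 1.0]),
        ([2, 4, 6], "negative", [1.0, 0.5, 0.0]),
        ([10, 12.5, 20], "positive", [0.0, 0.25, 1.0]),
    ])
    def test_single_column(self, col, tag, expected):
        sm = make_scores(np.array(col)[:, None], [tag])
        z = normalize_scores(sm)
        assert z.values[:, 0] == pytest.approx(expected)

    def test_constant_column_errors_with_name(self):
        sm = make_scores([[1, 2], [1, 3]], ["positive", "positive"])
        with pytest.raises(ValueError, match="crit0"):
            normalize_scores(sm)

    def test_idempotent_on_unit_interval_columns(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(size=8)
        col[0], col[1] = 0.0, 1.0  # min 0, max 1 attained
        sm = make_scores(col[:, None], ["positive"])
        z = normalize_scores(sm)
        assert z.values[:, 0] == pytest.approx(col, abs=1e-15)

    def test_every_column_attains_both_endpoints(self):
        rng = np.random.default_rng(1)
        sm = make_scores(rng.normal(size=(10, 3)) * 20 + 100,
                         ["positive", "negative", "positive"])
        z = normalize_scores(sm).values
        assert z.min(axis=0) == pytest.approx([0, 0, 0])
        assert z.max(axis=0) == pytest.approx([1, 1, 1])


class TestBestWorstVectors:
    def test_positive_column(self):
        bw = best_worst_vectors(make_scores([[2], [4], [6]], ["positive"]))
        assert (bw.best[0], bw.worst[0]) == (6, 2)

    def test_negative_column(self):
        bw = best_worst_vectors(make_scores([[1], [3]], ["negative"]))
        assert (bw.best[0], bw.worst[0]) == (1, 3)

    def test_mixed_matrix_matches_bruteforce_scan(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(12, 2)) * 10
        sm = make_scores(vals, ["positive", "negative"])
        bw = best_worst_vectors(sm)
        for j, tag in enumerate(sm.indicator_types):
            col = sorted(vals[:, j])
            if tag == "positive":
                assert (bw.best[j], bw.worst[j]) == (col[-1], col[0])
            else:
                assert (bw.best[j], bw.worst[j]) == (col[0], col[-1])


class TestRelativeErrorCosines:
    def test_two_point_column_is_orthogonal(self):
        sm = make_scores([[0], [1]], ["positive"])
        rel, cos = relative_error_cosines(sm)
        assert rel.positive[:, 0] == pytest.approx([-1, 0])
        assert rel.negative[:, 0] == pytest.approx([0, 1])
        assert cos.theta[0] == pytest.approx(0.0)

    def test_three_point_column_hand_value(self):
        # normalized values (0, 0.5, 1): dot −0.25, norms sqrt(1.25) each
        sm = make_scores([[0], [0.5], [1]], ["positive"])
        _, cos = relative_error_cosines(sm)
        assert cos.theta[0] == pytest.approx(-0.2)
        assert cos.theta_abs[0] == pytest.approx(0.2)

    def test_cosine_bounded_by_one(self):
        rng = np.random.default_rng(3)
        sm = make_scores(rng.normal(size=(15, 3)), ["positive", "negative", "positive"])
        _, cos = relative_error_cosines(sm)
        assert np.all(cos.theta_abs <= 1.0 + 1e-12)

    def test_relative_errors_bounded_by_one(self):
        rng = np.random.default_rng(4)
        sm = make_scores(rng.normal(size=(9, 2)), ["positive", "negative"])
        rel, _ = relative_error_cosines(sm)
        assert np.all(np.abs(rel.positive) <= 1 + 1e-12)
        assert np.all(np.abs(rel.negative) <= 1 + 1e-12)


class TestObjectiveWeights:
    @pytest.mark.parametrize("theta,expected", [
        ([0.2, 0.2, 0.6], [0.2, 0.2, 0.6]),
        ([1.0, 1.0, 1.0], [1 / 3, 1 / 3, 1 / 3]),
        ([0.2, 0.3], [0.4, 0.6]),
    ])
    def test_normalization(self, theta, expected):
        cos = CriterionCosines(theta=np.array(theta), theta_abs=np.abs(theta))
        w2 = objective_weights(cos)
        assert w2.weights == pytest.approx(expected)
        assert w2.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_cosines_error(self):
        cos = CriterionCosines(theta=np.zeros(3), theta_abs=np.zeros(3))
        with pytest.raises(ValueError, match="objective"):
            objective_weights(cos)

    def test_negative_cosines_use_magnitude(self):
        t = np.array([-0.4, 0.4])
        w2 = objective_weights(CriterionCosines(theta=t, theta_abs=np.abs(t)))
        assert w2.weights == pytest.approx([0.5, 0.5])


def entropy_objective(w, w1, w2):
    return float(np.sum(w * np.log(w / w1)) + np.sum(w * np.log(w / w2)))


def minimize_entropy_oracle(w1, w2):
    """Independent constrained minimizer of the fusion entropy on the simplex."""
    from scipy.optimize import minimize

    n = len(w1)
    res = minimize(
        entropy_objective, np.full(n, 1.0 / n), args=(w1, w2),
        method="SLSQP",
        bounds=[(1e-9, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"ftol": 1e-14, "maxiter": 500})
    assert res.success
    return res.x


class TestCompoundWeights:
    def test_entropy_sqrt_fixed_point_when_weights_agree(self):
        # sqrt(W*W) = W: agreeing subjective and objective weights pass through
        w = WeightVector("W1", np.array([0.5, 0.3, 0.2]))
        fused = compound_weights(w, WeightVector("W2", w.weights.copy()),
                                 "entropy-sqrt")
        assert fused.weights == pytest.approx(w.weights)

    def test_uniform_weights_fixed_in_both_modes(self):
        w = WeightVector("W1", np.full(3, 1 / 3))
        for mode in ("printed-product", "entropy-sqrt"):
            fused = compound_weights(w, WeightVector("W2", w.weights.copy()), mode)
            assert fused.weights == pytest.approx(w.weights)

    def test_printed_product_hand_value(self):
        w1 = WeightVector("W1", np.array([0.5, 0.3, 0.2]))
        w2 = WeightVector("W2", np.array([0.2, 0.3, 0.5]))
        fused = compound_weights(w1, w2, "printed-product")
        assert fused.weights == pytest.approx(
            np.array([0.10, 0.09, 0.10]) / 0.29, abs=1e-12)

    def test_entropy_sqrt_matches_numerical_minimizer(self):
        w1 = np.array([0.5, 0.3, 0.2])
        w2 = np.array([0.2, 0.3, 0.5])
        fused = compound_weights(
            WeightVector("W1", w1), WeightVector("W2", w2), "entropy-sqrt")
        oracle = minimize_entropy_oracle(w1, w2)
        assert fused.weights == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_entropy_sqrt_on_random_simplex_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        w1 = rng.dirichlet(np.ones(n) * 2)
        w2 = rng.dirichlet(np.ones(n) * 2)
        fused = compound_weights(
            WeightVector("W1", w1), WeightVector("W2", w2), "entropy-sqrt")
        oracle = minimize_entropy_oracle(w1, w2)
        assert fused.weights == pytest.approx(oracle, abs=1e-6)

    def test_length_mismatch_and_unknown_mode(self):
        w1 = WeightVector("W1", np.array([0.5, 0.5]))
        w2 = WeightVector("W2", np.array([0.4, 0.3, 0.3]))
        with pytest.raises(ValueError):
            compound_weights(w1, w2)
        with pytest.raises(ValueError, match="mode"):
            compound_weights(w1, WeightVector("W2", np.array([0.5, 0.5])),
                             "geometric")

    def test_weight_vector_validation(self):
        with pytest.raises(ValueError):
            WeightVector("w", np.array([0.5, 0.5, 0.0]))  # zero entry
        with pytest.raises(ValueError):
            WeightVector("w", np.array([0.6, 0.6]))       # sum != 1


class TestCompositeValue:
    def full_pipeline_cv(self, values, tags, mode="printed-product"):
        sm = make_scores(values, tags)
        z = normalize_scores(sm)
        _, cos = relative_error_cosines(sm)
        w2 = objective_weights(cos)
        w1 = WeightVector("W1", np.full(len(tags), 1.0 / len(tags)))
        w = compound_weights(w1, w2, mode)
        return composite_value(z, w, sm.compound_ids)

    def test_best_and_worst_rows_hit_endpoints(self):
        vals = np.array([[9, 9, 1.0], [5, 6, 4], [1, 2, 9]])
        rk = self.full_pipeline_cv(vals, ["positive", "positive", "negative"])
        assert rk.cv[0] == pytest.approx(1.0)
        assert rk.cv[2] == pytest.approx(0.0)
        assert list(rk.rank) == [1, 2, 3]

    def test_raw_dot_product(self):
        from herbiscreen.mcda import NormalizedMatrix
        z = NormalizedMatrix(values=np.array([[1.0, 0.0, 0.4], [0.0, 1.0, 0.0]]))
        w = WeightVector("w", np.array([0.5, 0.25, 0.25]))
        rk = composite_value(z, w, ["a", "b"], renormalize=False)
        assert rk.cv[0] == pytest.approx(0.6)

    def test_ties_resolved_by_input_order(self):
        from herbiscreen.mcda import NormalizedMatrix
        z = NormalizedMatrix(values=np.array([[0.5], [0.5], [1.0]]))
        rk = composite_value(z, WeightVector("w", np.array([1.0])),
                             ["a", "b", "c"], renormalize=False)
        assert list(rk.rank) == [2, 3, 1]

    @pytest.mark.parametrize("seed", range(8))
    def test_ranking_invariant_under_positive_affine_rescaling(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(10, 3)) * 15 + 100
        tags = ["positive", "positive", "negative"]
        base = self.full_pipeline_cv(vals, tags)
        scaled = vals.copy()
        j = int(rng.integers(3))
        scaled[:, j] = scaled[:, j] * float(rng.uniform(0.1, 10)) \
            + float(rng.uniform(-50, 50))
        again = self.full_pipeline_cv(scaled, tags)
        assert list(base.rank) == list(again.rank)
        assert base.cv == pytest.approx(again.cv, abs=1e-9)


class TestPercentVsReference:
    def test_reference_itself_is_zero(self):
        rk = CompositeRanking(["a", "b"], np.array([0.5, 0.85]), np.array([2, 1]))
        pct = percent_vs_reference(rk, "a")
        assert pct["a"] == pytest.approx(0.0)
        assert pct["b"] == pytest.approx(70.0)

    def test_double_is_hundred_percent(self):
        rk = CompositeRanking(["a", "b"], np.array([0.3, 0.6]), np.array([2, 1]))
        assert percent_vs_reference(rk, "a")["b"] == pytest.approx(100.0)

    def test_missing_or_zero_reference(self):
        rk = CompositeRanking(["a", "b"], np.array([0.0, 0.6]), np.array([2, 1]))
        with pytest.raises(ValueError, match="not found"):
            percent_vs_reference(rk, "zz")
        with pytest.raises(ValueError, match="zero"):
            percent_vs_reference(rk, "a")
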