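import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from pathweight import (
    WeightSpec,
    abs_t_weights,
    apply_weights,
    global_test_objective,
    qdiff_weights,
    rwm_search,
    rwv_search,
)
from pathweight.weighting import uniform_weights, write_weights_tsv

from conftest import brute_force_Q, random_instance


class TestAbsT:
    def test_hand_computed_pooled_t_example(self):
        # gene1: class0=[0,2], class1=[4,6]; gene2: class0=[0,2], class1=[2,4]
        X = np.array([[0.0, 0.0], [2.0, 2.0], [4.0, 2.0], [6.0, 4.0]])
        Y = np.array([0, 0, 1, 1])
        w = abs_t_weights(X, Y)
        # pooled t: sp^2 = 2 for both genes, se = sqrt(2*(1/2+1/2)) = sqrt(2)
        # => |T| = [4/sqrt(2), 2/sqrt(2)] = [2.828, 1.414]
        np.testing.assert_allclose(w.weights, [2 / 3, 1 / 3], atol=1e-12)

    def test_matches_scipy_pooled_t(self, rng):
        X, Y = random_instance(rng, n=10, m=5)
        w = abs_t_weights(X, Y)
        t = np.abs(stats.ttest_ind(X[Y == 1], X[Y == 0], equal_var=True).statistic)
        np.testing.assert_allclose(w.weights, t / t.sum(), atol=1e-12)

    def test_welch_flag_matches_scipy_welch(self, rng):
        # unbalanced groups and unequal variances: the two flavors differ
        X = rng.standard_normal((12, 4))
        Y = np.array([1] * 4 + [0] * 8)
        X[Y == 1] *= 3.0
        w = abs_t_weights(X, Y, welch=True)
        t = np.abs(stats.ttest_ind(X[Y == 1], X[Y == 0], equal_var=False).statistic)
        np.testing.assert_allclose(w.weights, t / t.sum(), atol=1e-12)
        assert not np.allclose(w.weights, abs_t_weights(X, Y).weights)

    def test_identical_columns_share_weight(self, rng):
        col = rng.standard_normal(8)
        X = np.column_stack([col, col])
        Y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        np.testing.assert_allclose(abs_t_weights(X, Y).weights, [0.5, 0.5])

    def test_single_gene_gets_weight_one(self, rng):
        X, Y = random_instance(rng, n=6, m=1)
        np.testing.assert_allclose(abs_t_weights(X, Y).weights, [1.0])

    def test_order_matches_abs_t_order(self, rng):
        X, Y = random_instance(rng, n=12, m=6)
        w = abs_t_weights(X, Y).weights
        t = np.abs(stats.ttest_ind(X[Y == 1], X[Y == 0], equal_var=True).statistic)
        np.testing.assert_array_equal(np.argsort(w), np.argsort(t))

    def test_all_zero_t_falls_back_to_uniform(self):
        X = np.tile([[1.0, 5.0]], (6, 1))  # constant columns: t undefined -> 0
        Y = np.array([1, 1, 1, 0, 0, 0])
        np.testing.assert_allclose(abs_t_weights(X, Y).weights, [0.5, 0.5])

    def test_zero_variance_gene_capped_not_infinite(self, rng):
        X, Y = random_instance(rng, n=8, m=3)
        X[:, 0] = np.where(Y == 1, 1.0, 0.0)  # zero within-class variance
        w = abs_t_weights(X, Y).weights
        assert np.isfinite(w).all() and w.sum() == pytest.approx(1.0)
        assert w[0] == w.max()  # capped at the largest finite |T|

    def test_needs_two_samples_per_class(self, rng):
        X = rng.standard_normal((3, 2))
        with pytest.raises(ValueError, match=">= 2 samples"):
            abs_t_weights(X, np.array([1, 0, 0]))

    def test_column_permutation_equivariance(self, rng):
        X, Y = random_instance(rng, n=10, m=5)
        perm = rng.permutation(5)
        np.testing.assert_allclose(abs_t_weights(X[:, perm], Y).weights,
                                   abs_t_weights(X, Y).weights[perm])


class TestQdiff:
    def test_single_gene_defined_fallback(self, rng):
        X, Y = random_instance(rng, n=6, m=1)
        np.testing.assert_allclose(qdiff_weights(X, Y).weights, [1.0])

    def test_identical_columns_share_weight(self, rng):
        col = rng.standard_normal(6)
        X = np.column_stack([col, col])
        Y = np.array([1, 1, 1, 0, 0, 0])
        np.testing.assert_allclose(qdiff_weights(X, Y).weights, [0.5, 0.5])

    def test_leave_one_out_oracle(self, rng):
        X, Y = random_instance(rng, n=6, m=3)
        w = qdiff_weights(X, Y).weights
        q = brute_force_Q(X, Y)
        diffs = np.array([abs(q - brute_force_Q(np.delete(X, j, axis=1), Y))
                          for j in range(3)])
        np.testing.assert_allclose(w, diffs / diffs.sum(), atol=1e-10)

    def test_all_zero_differences_fall_back_to_uniform(self):
        X = np.zeros((6, 3))
        Y = np.array([1, 1, 1, 0, 0, 0])
        np.testing.assert_allclose(qdiff_weights(X, Y).weights, [1 / 3] * 3)

    def test_column_permutation_equivariance(self, rng):
        X, Y = random_instance(rng, n=8, m=4)
        perm = rng.permutation(4)
        np.testing.assert_allclose(qdiff_weights(X[:, perm], Y).weights,
                                   qdiff_weights(X, Y).weights[perm],
                                   atol=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(X=arrays(np.float64, (8, 4), elements=st.floats(-50, 50)),
       scheme=st.sampled_from(["absT", "Qdiff"]))
def test_closed_form_weights_are_a_probability_vector(X, scheme):
    """absT/Qdiff weights are nonnegative and sum to 1 on any valid input."""
    Y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    fn = abs_t_weights if scheme == "absT" else qdiff_weights
    w = fn(X, Y).weights
    assert (w >= 0).all()
    assert w.sum() == pytest.approx(1.0)


class TestApplyWeights:
    def test_unit_vector_is_identity(self, rng):
        X = rng.standard_normal((4, 3))
        np.testing.assert_array_equal(apply_weights(X, uniform_weights(3)), X)

    def test_vector_zeroes_column(self, rng):
        X = rng.standard_normal((4, 2))
        out = apply_weights(X, WeightSpec("vector", [2.0, 0.0]))
        np.testing.assert_array_equal(out[:, 1], 0.0)
        np.testing.assert_array_equal(out[:, 0], 2.0 * X[:, 0])

    def test_unit_matrix_is_identity(self, rng):
        X = rng.standard_normal((4, 3))
        np.testing.assert_array_equal(
            apply_weights(X, WeightSpec("matrix", np.ones((4, 3)))), X)

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.standard_normal((4, 3))
        with pytest.raises(ValueError):
            apply_weights(X, WeightSpec("vector", [1.0, 1.0]))
        with pytest.raises(ValueError):
            apply_weights(X, WeightSpec("matrix", np.ones((3, 3))))

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            WeightSpec("vector", [-0.1, 1.0])


class TestRandomSearches:
    @pytest.fixture
    def instance(self, rng):
        return random_instance(rng, n=10, m=4)

    @pytest.fixture
    def objective(self, instance):
        _, Y = instance
        return global_test_objective(Y, n_perm=500, seed=99)

    @pytest.mark.parametrize("search", [rwv_search, rwm_search])
    def test_count_zero_returns_uniform(self, search, instance, objective):
        X, Y = instance
        res = search(X, Y, count=0, objective=objective, seed=1)
        assert res.best_objective == res.initial_objective
        assert res.iterations_run == 0
        np.testing.assert_array_equal(res.best_weights.weights,
                                      np.ones(res.best_weights.weights.shape))

    @pytest.mark.parametrize("search", [rwv_search, rwm_search])
    @pytest.mark.parametrize("count", [1, 10, 50])
    def test_best_never_exceeds_uniform(self, search, count, instance, objective):
        X, Y = instance
        res = search(X, Y, count=count, objective=objective, seed=2)
        assert res.best_objective <= res.initial_objective

    @pytest.mark.parametrize("search", [rwv_search, rwm_search])
    def test_deterministic_given_seed(self, search, instance, objective):
        X, Y = instance
        r1 = search(X, Y, count=30, objective=objective, seed=7, record_trace=True)
        r2 = search(X, Y, count=30, objective=objective, seed=7, record_trace=True)
        assert r1.best_objective == r2.best_objective
        np.testing.assert_array_equal(r1.best_weights.weights,
                                      r2.best_weights.weights)
        np.testing.assert_array_equal(r1.trace, r2.trace)

    @pytest.mark.parametrize("search", [rwv_search, rwm_search])
    def test_trace_is_prefix_argmin(self, search, instance, objective):
        # best objective is non-increasing in count for a fixed seed stream
        X, Y = instance
        res = search(X, Y, count=80, objective=objective, seed=3,
                     record_trace=True)
        assert (np.diff(res.trace) <= 0).all()
        assert res.trace[0] == res.initial_objective
        assert res.trace[-1] == res.best_objective

    def test_uniformly_scaled_candidate_scores_initial_objective(
            self, instance, objective):
        # only the relative pattern of a weight vector matters to the
        # global-test objective
        X, Y = instance
        base = objective(X)
        scaled = objective(apply_weights(X, WeightSpec("vector", 0.55 * np.ones(4))))
        assert scaled[0] == base[0]

    def test_invalid_range_rejected(self, instance, objective):
        X, Y = instance
        with pytest.raises(ValueError, match="range"):
            rwv_search(X, Y, count=5, range_lo=0.0, range_hi=1.0,
                       objective=objective, seed=1)
        with pytest.raises(ValueError, match="range"):
            rwm_search(X, Y, count=5, range_lo=0.5, range_hi=0.2,
                       objective=objective, seed=1)

    def test_candidate_weights_stay_in_range(self, instance, objective):
        X, Y = instance
        res = rwv_search(X, Y, count=40, range_lo=0.3, range_hi=0.6,
                         objective=objective, seed=5)
        w = res.best_weights.weights
        if res.best_objective < res.initial_objective:  # a candidate won
            assert ((w >= 0.3) & (w <= 0.6)).all()

    def test_simple_draw_changes_candidate_stream(self, instance, objective):
        X, Y = instance
        r_two_step = rwv_search(X, Y, count=15, objective=objective, seed=8)
        r_simple = rwv_search(X, Y, count=15, objective=objective, seed=8,
                              simple_draw=True)
        # same seed, different draw protocol: traces may differ but both
        # respect the uniform bound
        assert r_simple.best_objective <= r_simple.initial_objective
        assert r_two_step.best_objective <= r_two_step.initial_objective

    def test_rwm_beats_rwv_on_majority_of_paired_seeds(self, instance):
        # the per-cell search has n*m degrees of freedom vs m, so at equal
        # budget it should reach an objective at least as low, most seeds
        X, Y = instance
        wins = 0
        n_seeds = 10
        for s in range(n_seeds):
            obj = global_test_objective(Y, n_perm=500, seed=1000 + s)
            rv = rwv_search(X, Y, count=60, objective=obj, seed=s)
            rm = rwm_search(X, Y, count=60, objective=obj, seed=s)
            wins += rm.best_objective <= rv.best_objective
        assert wins > n_seeds // 2


def test_weight_tsv_serialization(tmp_path, rng):
    import pandas as pd
    w = WeightSpec("vector", [0.25, 0.75])
    path = tmp_path / "w.tsv"
    write_weights_tsv(w, path, gene_ids=["G1", "G2"])
    back = pd.read_csv(path, sep="\t", index_col=0)
    np.testing.assert_allclose(back["weight"].to_numpy(), [0.25, 0.75])
    wm = WeightSpec("matrix", rng.uniform(0.1, 1.0, (3, 2)))
    path2 = tmp_path / "wm.tsv"
    write_weights_tsv(wm, path2, gene_ids=["G1", "G2"], sample_ids=list("abc"))
    back2 = pd.read_csv(path2, sep="\t", index_col=0)
    np.testing.assert_allclose(back2.to_numpy(), wm.weights)
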