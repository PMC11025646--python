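"""Encoding pipeline: folds, least-squares mapping, cross-validated
predictivity, aggregation, normalization, and the layer sweep."""

import numpy as np
import pytest

from lmalign.encoding import (
    FoldSpec,
    combine_and_normalize,
    cross_validated_predictivity,
    fit_linear_map,
    layer_sweep,
    load_neural_benchmark,
    make_folds,
    participant_score,
    pearson_columns,
    predict_linear_map,
    save_neural_benchmark,
    score_benchmark,
    sentence_representation,
)
from lmalign.synthetic import (
    NeuralBenchmark,
    SyntheticNeuralSpec,
    generate_neural_benchmark,
)


class TestFolds:
    @pytest.mark.parametrize(
        "n, k, expected_sizes",
        [
            (243, 5, [48, 48, 49, 49, 49]),
            (10, 5, [2, 2, 2, 2, 2]),
            (7, 5, [1, 1, 1, 2, 2]),
        ],
    )
    def test_fold_sizes(self, n, k, expected_sizes):
        folds = make_folds(n, k)
        assert sorted(folds.sizes()) == sorted(expected_sizes)
        assert folds.sizes() == expected_sizes  # extras go to the last folds

    def test_contiguous_in_stimulus_order(self):
        folds = make_folds(12, 3)
        assert np.all(np.diff(folds.assignment) >= 0)

    def test_each_item_in_exactly_one_test_fold(self):
        folds = make_folds(23, 5)
        seen = np.concatenate([folds.test_indices(f) for f in range(5)])
        assert sorted(seen) == list(range(23))

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            make_folds(4, 5)


class TestLinearMap:
    def test_self_regression_identity(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        W = fit_linear_map(X, X)
        assert W[:4] == pytest.approx(np.eye(4), abs=1e-9)
        assert predict_linear_map(W, X) == pytest.approx(X, abs=1e-9)

    def test_orthonormal_design_recovers_weights(self):
        rng = np.random.default_rng(1)
        Q, _ = np.linalg.qr(rng.normal(size=(30, 5)))
        w = rng.normal(size=(5, 3))
        W = fit_linear_map(Q, Q @ w)
        assert W[:5] == pytest.approx(w, abs=1e-9)

    def test_underdetermined_matches_pseudoinverse_oracle(self):
        """More units than rows: the solution equals the SVD pseudoinverse's
        minimum-norm solution."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 12))
        Y = rng.normal(size=(6, 3))
        A = np.hstack([X, np.ones((6, 1))])
        expected = np.linalg.pinv(A) @ Y
        assert fit_linear_map(X, Y) == pytest.approx(expected, abs=1e-8)

    def test_nonfinite_rejected(self):
        X = np.ones((5, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_linear_map(X, np.ones((5, 1)))


class TestCrossValidation:
    def test_noiseless_linear_signal_r_one(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 5))
        Y = X @ rng.normal(size=(5, 8)) + rng.normal(size=8)
        r = cross_validated_predictivity(X, Y, make_folds(50, 5))
        assert r == pytest.approx(np.ones(8), abs=1e-6)

    def test_null_case_r_near_zero(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 5))
        Y = rng.normal(size=(100, 200))  # independent of X
        r = cross_validated_predictivity(X, Y, make_folds(100, 5))
        se = r.std(ddof=1) / np.sqrt(r.size)
        assert abs(r.mean()) < 2 * se + 0.02

    def test_small_fold_rejected(self):
        X = np.random.default_rng(0).normal(size=(8, 2))
        with pytest.raises(ValueError):
            cross_validated_predictivity(X, X, make_folds(8, 4))

    def test_affine_voxel_rescaling_invariance(self):
        """Pearson predictivity is invariant to affine rescaling of a voxel's
        responses and to common rescaling of activations."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 4))
        Y = X @ rng.normal(size=(4, 3)) + 0.3 * rng.normal(size=(40, 3))
        folds = make_folds(40, 5)
        base = cross_validated_predictivity(X, Y, folds)
        Y2 = Y.copy()
        Y2[:, 1] = 5.0 * Y2[:, 1] - 7.0
        assert cross_validated_predictivity(X, Y2, folds) == pytest.approx(base, abs=1e-9)
        assert cross_validated_predictivity(3.2 * X, Y, folds) == pytest.approx(
            base, abs=1e-9
        )


class TestAggregation:
    def test_participant_score_medians(self):
        assert participant_score(np.full(4, 0.3)) == pytest.approx(0.3)
        assert participant_score(np.array([0.1, 0.2, 0.3])) == pytest.approx(0.2)
        # even count: mean of the central pair
        assert participant_score(np.array([0.1, 0.2, 0.3, 0.4])) == pytest.approx(0.25)

    def test_participant_score_empty_group_rejected(self):
        with pytest.raises(ValueError):
            participant_score(np.array([0.1]), mask=np.array([False]))

    def test_combine_and_normalize(self):
        assert combine_and_normalize([0.12, 0.20], 0.32) == pytest.approx(0.5)
        assert combine_and_normalize([0.32], 0.32) == pytest.approx(1.0)
        assert combine_and_normalize([0.7], 1.0) == pytest.approx(0.7)  # identity
        with pytest.raises(ValueError):
            combine_and_normalize([0.1], 0.0)


class TestPipeline:
    def test_oracle_equivalence_straight_line_reimplementation(self):
        """Full pipeline on a 20-sentence, 10-voxel, 8-unit instance agrees
        with an explicit loop/pseudoinverse reimplementation to 1e-8."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 8))
        Y = X @ rng.normal(size=(8, 10)) + 0.5 * rng.normal(size=(20, 10))
        k = 5
        folds = make_folds(20, k)
        got = cross_validated_predictivity(X, Y, folds)

        # straight-line oracle: explicit folds, pinv fit, loop Pearson
        fold_rs = []
        for f in range(k):
            test = [i for i in range(20) if folds.assignment[i] == f]
            train = [i for i in range(20) if folds.assignment[i] != f]
            A = np.hstack([X[train], np.ones((len(train), 1))])
            W = np.linalg.pinv(A) @ Y[train]
            pred = np.hstack([X[test], np.ones((len(test), 1))]) @ W
            rs = []
            for v in range(10):
                a, b = pred[:, v], Y[test, v]
                a = a - a.mean()
                b = b - b.mean()
                rs.append((a @ b) / np.sqrt((a @ a) * (b @ b)))
            fold_rs.append(rs)
        expected = np.mean(fold_rs, axis=0)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_normalized_score_approaches_one_as_noise_vanishes(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 8))
        norm_scores = []
        for ns in (0.8, 0.2, 0.0):
            bench, truth = generate_neural_benchmark(
                SyntheticNeuralSpec(2, 10, 100, ns, seed=8), X
            )
            res = score_benchmark(X, bench)
            norm_scores.append(res.median_normalized)
            assert bench.ceiling == pytest.approx(
                float(np.median(truth.analytic_ceiling))
            )
        assert norm_scores[-1] == pytest.approx(1.0, abs=1e-6)
        assert norm_scores == sorted(norm_scores)

    def test_layer_sweep_single_layer(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 4))
        bench, _ = generate_neural_benchmark(SyntheticNeuralSpec(1, 5, 30, 0.1, seed=1), X)
        results, best = layer_sweep([X], bench)
        assert best == 0 and len(results) == 1

    def test_layer_sweep_scores_all_layers(self):
        rng = np.random.default_rng(10)
        layers = [rng.normal(size=(30, 4)) for _ in range(5)]
        bench, _ = generate_neural_benchmark(
            SyntheticNeuralSpec(1, 5, 30, 0.1, seed=2), layers[3]
        )
        results, best = layer_sweep(layers, bench)
        assert len(results) == 5
        assert results[best].median_normalized == max(r.median_normalized for r in results)


class TestSentenceRepresentation:
    def test_single_token_last_word_identity(self):
        acts = [[np.array([[9.0, 9.0], [1.0, 2.0]])]]  # one layer, 2 tokens
        out = sentence_representation(acts, [(1, 2)])
        assert out[0][0] == pytest.approx([1.0, 2.0])

    def test_multi_token_word_mean(self):
        acts = [[np.array([[0.0, 0.0], [1.0, 1.0], [3.0, 3.0]])]]
        out = sentence_representation(acts, [(1, 3)])
        assert out[0][0] == pytest.approx([2.0, 2.0])

    def test_token_order_invariance(self):
        a = np.array([[1.0, 5.0], [3.0, 7.0]])
        fwd = sentence_representation([[a]], [(0, 2)])
        rev = sentence_representation([[a[::-1]]], [(0, 2)])
        assert fwd[0] == pytest.approx(rev[0])

    def test_empty_word_span_rejected(self):
        with pytest.raises(ValueError):
            sentence_representation([[np.zeros((2, 2))]], [(1, 1)])


class TestIO:
    def test_benchmark_hdf5_roundtrip(self, tmp_path):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 3))
        bench, _ = generate_neural_benchmark(SyntheticNeuralSpec(2, 4, 20, 0.2, seed=3), X)
        path = tmp_path / "bench.h5"
        save_neural_benchmark(path, bench)
        loaded = load_neural_benchmark(path)
        assert loaded.ceiling == pytest.approx(bench.ceiling)
        assert np.array_equal(loaded.experiments, bench.experiments)
        for a, b in zip(loaded.responses, bench.responses):
            assert np.array_equal(a, b)
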