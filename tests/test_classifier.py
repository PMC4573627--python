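"""SVM training, calibration and ROC evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirtss.classifier import (
    SvmConfig,
    evaluate_windows,
    load_model,
    predict_scores,
    roc_auc,
    save_model,
    split_half,
    train_svm,
)
from mirtss.profiles import Anchor, ProfileMatrix


def _matrix(X, y=None):
    X = np.asarray(X, dtype=float)
    anchors = [Anchor(f"a{i}", "chr1", 100 * i, "+") for i in range(len(X))]
    k = X.shape[1] // 2
    return ProfileMatrix(anchors=anchors, marks=["m"], k=k, X=X, y=y)


def _blobs(n_per_class=40, sep=6.0, seed=0, d=4):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per_class, d)) + sep
    b = rng.normal(0.0, 1.0, size=(n_per_class, d))
    X = np.abs(np.vstack([a, b]))
    y = np.array([1] * n_per_class + [-1] * n_per_class)
    return _matrix(X, y)


class TestSplitHalf:
    def test_split_is_stratified_fifty_fifty(self):
        mat = _matrix(np.zeros((140, 4)), np.array([1] * 100 + [-1] * 40))
        train, test = split_half(mat, seed=0)
        assert (train.y == 1).sum() == 50 and (train.y == -1).sum() == 20
        assert train.n + test.n == 140
        ids = {a.id for a in train.anchors} | {a.id for a in test.anchors}
        assert len(ids) == 140  # disjoint partition

    def test_same_seed_same_split(self):
        mat = _blobs()
        t1, _ = split_half(mat, seed=5)
        t2, _ = split_half(mat, seed=5)
        assert [a.id for a in t1.anchors] == [a.id for a in t2.anchors]

    def test_odd_class_floors_training_side(self):
        mat = _matrix(np.zeros((15, 2)), np.array([1] * 11 + [-1] * 4))
        train, test = split_half(mat, seed=0)
        assert (train.y == 1).sum() == 5 and (test.y == 1).sum() == 6

    def test_tiny_class_errors(self):
        mat = _matrix(np.zeros((3, 2)), np.array([1, 1, -1]))
        with pytest.raises(ValueError):
            split_half(mat, seed=0)


class TestTrainSvm:
    def test_separable_clusters_are_fit_perfectly(self):
        mat = _blobs(sep=8.0)
        model = train_svm(mat, SvmConfig(cv_folds=3))
        scores, probs = predict_scores(model, mat)
        assert np.all(np.sign(scores) == mat.y)
        assert np.all((probs > 0.5) == (mat.y == 1))

    def test_grid_of_one_selects_that_point(self):
        model = train_svm(
            _blobs(), SvmConfig(C_grid=(3.0,), gamma_grid=(0.05,), cv_folds=3)
        )
        assert (model.C, model.gamma) == (3.0, 0.05)

    def test_single_class_and_nonfinite_inputs_error(self):
        with pytest.raises(ValueError):
            train_svm(_matrix(np.zeros((10, 2)), np.ones(10, dtype=int)))
        X = np.zeros((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_svm(_matrix(X, np.array([1] * 5 + [-1] * 5)))

    def test_conflicting_duplicate_rows_report_chance_cv(self):
        X = np.ones((20, 2))
        y = np.array([1, -1] * 10)
        model = train_svm(_matrix(X, y), SvmConfig(cv_folds=2))
        assert model.cv_accuracy <= 0.5 + 1e-9


class TestPredictScores:
    def test_deterministic_and_order_invariant(self):
        mat = _blobs()
        model = train_svm(mat, SvmConfig(cv_folds=3))
        s1, _ = predict_scores(model, mat)
        s2, _ = predict_scores(model, mat)
        np.testing.assert_array_equal(s1, s2)
        rev, _ = predict_scores(model, mat.X[::-1])
        np.testing.assert_allclose(rev, s1[::-1], rtol=1e-12)

    def test_width_mismatch_errors(self):
        model = train_svm(_blobs(), SvmConfig(cv_folds=3))
        with pytest.raises(ValueError, match="width"):
            predict_scores(model, np.zeros((3, 7)))

    def test_probability_is_strictly_monotone_in_score(self):
        model = train_svm(_blobs(), SvmConfig(cv_folds=3))
        grid = np.linspace(-3, 3, 50)
        probs = model.probability(grid)
        assert np.all(np.diff(probs) > 0)

    def test_model_round_trips_through_disk(self, tmp_path):
        mat = _blobs()
        model = train_svm(mat, SvmConfig(cv_folds=3))
        save_model(model, tmp_path / "m.joblib")
        back = load_model(tmp_path / "m.joblib")
        np.testing.assert_array_equal(
            predict_scores(back, mat)[0], predict_scores(model, mat)[0]
        )


def brute_force_auc(scores, labels):
    """Independent oracle: exhaustive concordant-pair count with half ties."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == -1]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([0.9, 0.8, 0.2, 0.1], [1, 1, -1, -1], 1.0),
            ([0.5, 0.5, 0.5, 0.5], [1, 1, -1, -1], 0.5),
            ([0.9, 0.3, 0.5, 0.1], [1, 1, -1, -1], 0.75),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert roc_auc(scores, labels).auc == pytest.approx(expected)

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            n = int(rng.integers(4, 80))
            labels = np.array([1] * (n // 2) + [-1] * (n - n // 2))
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # forces ties
            res = roc_auc(scores, labels)
            assert res.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(
        # half-precision values keep the affine map injective in float64
        st.lists(st.floats(-5, 5, width=16), min_size=4, max_size=40),
        st.floats(0.1, 3.0),
    )
    def test_monotone_transform_invariance_and_complement(self, raw, slope):
        n = len(raw)
        labels = np.array([1] * (n // 2) + [-1] * (n - n // 2))
        scores = np.asarray(raw)
        base = roc_auc(scores, labels).auc
        assert roc_auc(slope * scores + 1.0, labels).auc == pytest.approx(base)
        assert roc_auc(-scores, labels).auc == pytest.approx(1.0 - base)

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=60)
        labels = np.array([1, -1] * 30)
        res = roc_auc(scores, labels)
        assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)


def test_evaluate_windows_emits_one_row_per_subset_and_k(tiny_sim):
    from mirtss.annotation_io import tss_of

    pos = [
        Anchor(g.id, g.interval.chrom, tss_of(g), g.interval.strand)
        for g in tiny_sim.genes[:60]
    ]
    from mirtss.profiles import sample_random_anchors

    neg = sample_random_anchors(tiny_sim.genome, 60, seed=3)
    table = evaluate_windows(
        tiny_sim.tracks, pos, neg, [["H3K4me3"]], k_list=[5],
        seed=0, config=SvmConfig(C_grid=(10.0,), gamma_grid=(1e-2,), cv_folds=2),
    )
    assert len(table) == 1
    assert set(table.columns) >= {"marks", "k", "auc"}
    assert 0.5 < table.auc.iloc[0] <= 1.0
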