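import numpy as np
import pytest

from pirnakit.classifier import (
    EvalReport,
    LabeledDataset,
    ModelParams,
    TrainedModel,
    cross_validate,
    cv_report_tsv,
    evaluate,
    grid_search,
    roc,
    stratified_partition,
    train,
)
from pirnakit.synthetic_fixtures import make_labeled_features

SMALL_C = (1.0, 32.0)
SMALL_G = (2.0, 32.0)


def _blobs(n_per_class=30, sep=4.0, seed=0, dim=32):
    rng = np.random.default_rng(seed)
    Xp = rng.normal(0, 1, (n_per_class, dim)) + sep
    Xn = rng.normal(0, 1, (n_per_class, dim))
    X = np.vstack([Xp, Xn])
    y = np.concatenate([np.ones(n_per_class, int), -np.ones(n_per_class, int)])
    ids = [f"s{i}" for i in range(2 * n_per_class)]
    return LabeledDataset(X, y, ids)


class TestStratifiedPartition:
    def test_balanced_tiny_case(self):
        data = _blobs(10)
        scheme = stratified_partition(data, k=10, seed=1)
        for part in scheme.partitions:
            labels = data.labels[part]
            assert (labels == 1).sum() == 1
            assert (labels == -1).sum() == 1

    def test_partition_sizes_like_published_split(self):
        # 9,758 positives into 10 partitions -> test partition 975 or 976
        y = np.concatenate([np.ones(9758, int), -np.ones(9240, int)])
        X = np.zeros((len(y), 32))
        data = LabeledDataset(X, y, [str(i) for i in range(len(y))])
        scheme = stratified_partition(data, k=10, seed=0)
        for part in scheme.partitions:
            assert (data.labels[part] == 1).sum() in (975, 976)
            assert (data.labels[part] == -1).sum() == 924

    def test_partitions_disjoint_and_exhaustive(self):
        data = _blobs(27)
        scheme = stratified_partition(data, k=10, seed=3)
        union = np.concatenate(scheme.partitions)
        assert len(union) == len(data.labels)
        assert len(set(union.tolist())) == len(union)

    def test_reproducible_from_seed(self):
        data = _blobs(25)
        a = stratified_partition(data, k=10, seed=5)
        b = stratified_partition(data, k=10, seed=5)
        for pa, pb in zip(a.partitions, b.partitions):
            assert np.array_equal(pa, pb)

    def test_too_few_samples_error(self):
        data = _blobs(5)
        with pytest.raises(ValueError, match="fewer than"):
            stratified_partition(data, k=10, seed=0)

    def test_rotation_roles(self):
        data = _blobs(20)
        scheme = stratified_partition(data, k=10, seed=0)
        tr, val, te = scheme.rotation(4)
        assert len(tr) + len(val) + len(te) == len(data.labels)
        assert set(te.tolist()) == set(scheme.partitions[4].tolist())
        assert not set(tr.tolist()) & set(val.tolist())


class TestTrainPredict:
    def test_two_point_separable(self):
        data = LabeledDataset(
            np.array([[0.0] * 32, [5.0] * 32]), np.array([-1, 1]), ["a", "b"]
        )
        model = train(data, ModelParams(C=10.0, gamma=0.1))
        labels, scores = model.predict(data.vectors)
        assert list(labels) == [-1, 1]
        assert (scores > 0).tolist() == [False, True]

    def test_single_class_error(self):
        data = LabeledDataset(np.zeros((3, 32)), np.ones(3, int), ["a", "b", "c"])
        with pytest.raises(ValueError, match="both classes"):
            train(data, ModelParams(C=1.0, gamma=1.0))

    def test_duplicating_samples_leaves_predictions_unchanged(self):
        data = _blobs(20, seed=2)
        held = _blobs(10, seed=99)
        params = ModelParams(C=4.0, gamma=0.05)
        m1 = train(data, params)
        doubled = LabeledDataset(
            np.vstack([data.vectors, data.vectors]),
            np.concatenate([data.labels, data.labels]),
            data.ids + [i + "_copy" for i in data.ids],
        )
        m2 = train(doubled, params)
        l1, _ = m1.predict(held.vectors)
        l2, _ = m2.predict(held.vectors)
        assert np.array_equal(l1, l2)

    def test_decision_sign_across_blob_centers(self):
        data = _blobs(30, sep=6.0, seed=4)
        model = train(data, ModelParams(C=8.0, gamma=0.01))
        pos_center = np.full((1, 32), 6.0)
        neg_center = np.zeros((1, 32))
        assert model.decision_function(pos_center)[0] > 0
        assert model.decision_function(neg_center)[0] < 0

    def test_score_sign_equals_label(self):
        data = _blobs(20, seed=6)
        model = train(data, ModelParams(C=2.0, gamma=0.05))
        labels, scores = model.predict(data.vectors)
        assert np.array_equal(labels, np.where(scores > 0, 1, -1))

    def test_batch_equals_single(self):
        data = _blobs(15, seed=7)
        model = train(data, ModelParams(C=2.0, gamma=0.05))
        batch, _ = model.predict(data.vectors)
        singles = [model.predict(v.reshape(1, -1))[0][0] for v in data.vectors]
        assert batch.tolist() == singles

    def test_wrong_dimensionality_rejected(self):
        data = _blobs(10, seed=8)
        model = train(data, ModelParams(C=1.0, gamma=0.1))
        with pytest.raises(ValueError, match="features"):
            model.predict(np.zeros((2, 31)))

    def test_json_round_trip(self, tmp_path):
        data = _blobs(15, seed=9)
        model = train(data, ModelParams(C=2.0, gamma=0.5))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = TrainedModel.from_json(path)
        assert np.allclose(
            back.decision_function(data.vectors), model.decision_function(data.vectors)
        )
        assert back.params == model.params


class TestGridSearch:
    def test_single_candidate(self):
        data = _blobs(20, seed=10)
        scheme = stratified_partition(data, k=10, seed=0)
        tr, val, _ = scheme.rotation(0)
        params = grid_search(data, tr, val, (3.0,), (0.25,))
        assert params == ModelParams(C=3.0, gamma=0.25)

    def test_separable_reaches_full_validation_accuracy(self):
        data = _blobs(30, sep=8.0, seed=11)
        scheme = stratified_partition(data, k=10, seed=0)
        tr, val, _ = scheme.rotation(0)
        params = grid_search(data, tr, val, SMALL_C, SMALL_G + (0.01,))
        model = train(data.subset(tr), params)
        labels, _ = model.predict(data.vectors[val])
        assert np.mean(labels == data.labels[val]) == 1.0

    def test_matches_brute_force_cell_loop(self):
        data = make_labeled_features(40, 40, separation=3.0, seed=12)
        scheme = stratified_partition(data, k=10, seed=1)
        tr, val, _ = scheme.rotation(0)
        C_grid, g_grid = (0.5, 4.0, 32.0), (1.0, 8.0, 64.0)
        params = grid_search(data, tr, val, C_grid, g_grid)
        best = None
        for C in C_grid:
            for g in g_grid:
                model = train(data.subset(tr), ModelParams(C=C, gamma=g))
                labels, _ = model.predict(data.vectors[val])
                acc = float(np.mean(labels == data.labels[val]))
                key = (-acc, C, g)
                if best is None or key < best:
                    best = key
        assert (params.C, params.gamma) == (best[1], best[2])


class TestEvaluate:
    def test_cross_species_worked_example(self):
        truth = np.ones(7140, int)
        pred = np.concatenate([np.ones(6690, int), -np.ones(450, int)])
        rep = evaluate(truth, pred)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (6690, 450, 0, 0)
        assert round(rep.se, 1) == 93.7
        assert round(rep.acc, 1) == 93.7  # positives-only: ACC == Se
        assert rep.sp is None  # no negatives -> undefined

    def test_perfect_predictions(self):
        truth = np.array([1, 1, -1, -1])
        rep = evaluate(truth, truth)
        assert rep.se == rep.sp == rep.pre == rep.acc == 100.0

    def test_formula_oracle_random_counts(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = (int(x) for x in rng.integers(1, 50, size=4))
            truth = np.concatenate([np.ones(tp + fn, int), -np.ones(tn + fp, int)])
            pred = np.concatenate(
                [np.ones(tp, int), -np.ones(fn, int), -np.ones(tn, int), np.ones(fp, int)]
            )
            rep = evaluate(truth, pred)
            assert rep.se == pytest.approx(100 * tp / (tp + fn))
            assert rep.sp == pytest.approx(100 * tn / (tn + fp))
            assert rep.pre == pytest.approx(100 * tp / (tp + fp))
            assert rep.acc == pytest.approx(100 * (tp + tn) / (tp + tn + fp + fn))
            assert min(rep.se, rep.sp) <= rep.acc <= max(rep.se, rep.sp)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1, 1], [1])


class TestCrossValidate:
    def test_ten_reports_and_separable_perfect(self):
        data = _blobs(40, sep=8.0, seed=13)
        scheme = stratified_partition(data, k=10, seed=2)
        res = cross_validate(data, scheme, SMALL_C, (0.01,) + SMALL_G)
        assert len(res.reports) == 10
        assert res.mean["ACC"] == 100.0
        assert res.sd["ACC"] == 0.0

    def test_aggregates_match_reports(self):
        data = make_labeled_features(60, 60, separation=3.0, seed=14)
        scheme = stratified_partition(data, k=10, seed=2)
        res = cross_validate(data, scheme, (8.0,), (8.0,))
        accs = [r.acc for r in res.reports]
        assert res.mean["ACC"] == pytest.approx(np.mean(accs))
        assert res.sd["ACC"] == pytest.approx(np.std(accs))

    def test_report_tsv_layout(self):
        data = _blobs(20, seed=15)
        scheme = stratified_partition(data, k=10, seed=2)
        res = cross_validate(data, scheme, (2.0,), (0.5,))
        lines = cv_report_tsv(res).splitlines()
        assert lines[0].startswith("rotation\tC\tgamma")
        assert len(lines) == 1 + 10 + 2  # header, rotations, mean, sd


class TestRoc:
    def test_perfect_ranking(self):
        truth = np.array([1, 1, -1, -1])
        _, _, auc = roc(np.array([0.9, 0.8, 0.1, 0.2]), truth)
        assert auc == 1.0

    def test_all_equal_scores(self):
        truth = np.array([1, 1, -1, -1])
        _, _, auc = roc(np.zeros(4), truth)
        assert auc == 0.5

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_auc_equals_mann_whitney(self, rng):
        truth = np.concatenate([np.ones(30, int), -np.ones(40, int)])
        scores = rng.normal(size=70)
        scores[:30] += 0.8
        _, _, auc = roc(scores, truth)
        pos, neg = scores[:30], scores[30:]
        u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc == pytest.approx(u / (30 * 40))


def test_eval_report_dict():
    rep = EvalReport(tp=6, fp=1, tn=5, fn=2)
    d = rep.as_dict()
    assert d["TP"] == 6 and d["ACC"] == pytest.approx(100 * 11 / 14)
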