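from __future__ import annotations

import numpy as np
import pytest
from sklearn.neighbors import KNeighborsClassifier

from lattice123.classify import (
    PredictionVector,
    greedy_select,
    ihmv,
    knn_cv_predict,
    make_folds,
    nn1_cv_sweep,
    run_channel,
    run_overall,
)

from .reference import ref_mode_vote, ref_nn1_l1


def test_make_folds_stratified_and_deterministic():
    y = np.array(["a"] * 30 + ["b"] * 20)
    f1 = make_folds(y, 10, seed=4)
    f2 = make_folds(y, 10, seed=4)
    np.testing.assert_array_equal(f1, f2)
    assert set(f1.tolist()) == set(range(10))
    for k in range(10):
        fold_labels = set(y[f1 == k].tolist())
        assert fold_labels == {"a", "b"}


def test_make_folds_fallback_warns():
    y = np.array(["a"] * 17 + ["b"] * 3)
    with pytest.warns(UserWarning, match="non-stratified"):
        folds = make_folds(y, 10, seed=0)
    assert np.bincount(folds).min() >= 1


def test_knn_cv_predict_matches_sklearn_oracle(rng):
    n = 40
    x = rng.normal(size=(n, 6))
    y = np.array(["h"] * 25 + ["d"] * 15)
    fold_ids = make_folds(y, 5, seed=2)
    ours = knn_cv_predict(x, y, fold_ids=fold_ids).labels
    expected = np.empty(n, dtype=object)
    for k in range(5):
        test = fold_ids == k
        clf = KNeighborsClassifier(n_neighbors=1, metric="cityblock")
        clf.fit(x[~test], y[~test])
        expected[test] = clf.predict(x[test])
    np.testing.assert_array_equal(ours.astype(str), expected.astype(str))


def test_knn_cv_predict_matches_bruteforce(rng):
    n = 24
    x = rng.normal(size=(n, 4))
    y = np.array([0, 1] * 12)
    fold_ids = make_folds(y, 4, seed=0)
    ours = knn_cv_predict(x, y, fold_ids=fold_ids).labels
    expected = np.empty(n, dtype=int)
    for k in range(4):
        test = fold_ids == k
        expected[test] = ref_nn1_l1(x[~test], y[~test], x[test])
    np.testing.assert_array_equal(ours, expected)


def test_knn_cv_predict_validation(rng):
    with pytest.raises(ValueError, match="aligned"):
        knn_cv_predict(rng.normal(size=(5, 2)), [0, 1, 0])
    with pytest.raises(ValueError, match="2 classes"):
        knn_cv_predict(rng.normal(size=(4, 2)), [1, 1, 1, 1])


def test_nn1_cv_sweep_consistent_with_full_predictor(rng):
    n = 30
    x = rng.normal(size=(n, 12))
    y = np.array([0, 1] * 15)
    fold_ids = make_folds(y, 5, seed=1)
    accs, preds = nn1_cv_sweep(x, y, fold_ids, iv=3, fv=12)
    assert accs.shape == (10,)
    assert len(preds) == 10
    for v in (3, 7, 12):
        direct = knn_cv_predict(x[:, :v], y, fold_ids=fold_ids).labels
        np.testing.assert_array_equal(preds[v - 3], direct)
        assert accs[v - 3] == pytest.approx(np.mean(direct == y))


def test_ihmv_counts_and_mode_oracle(rng):
    n = 200
    y = rng.integers(0, 2, size=n)
    # nine vectors with distinct accuracies
    preds = []
    for i in range(9):
        p = y.copy()
        flip = rng.random(n) < 0.05 * (i + 1)
        p[flip] = 1 - p[flip]
        preds.append(p)
    voted = ihmv(preds, y, r_min=3)
    assert len(voted) == 7  # 9 vectors -> r = 3..9
    assert [v.member_count for v in voted] == list(range(3, 10))

    # independent oracle: recompute the accuracy order and per-epoch mode
    accs = np.array([np.mean(p == y) for p in preds])
    order = np.argsort(-accs, kind="stable")
    for v in voted:
        stack = np.stack([preds[i] for i in order[: v.member_count]])
        np.testing.assert_array_equal(v.labels, ref_mode_vote(stack))
        assert tuple(order[: v.member_count]) == v.member_indices


def test_ihmv_six_gives_four(rng):
    y = rng.integers(0, 2, size=50)
    preds = [rng.integers(0, 2, size=50) for _ in range(6)]
    voted = ihmv(preds, y)
    assert len(voted) == 4
    with pytest.raises(ValueError, match="at least 3"):
        ihmv(preds[:2], y)


def test_ihmv_tie_goes_to_most_accurate_member():
    y = np.array([0, 0, 0, 0])
    a = np.array([1, 0, 0, 0])  # acc .75 (most accurate)
    b = np.array([0, 1, 1, 1])  # acc .25
    c = np.array([1, 1, 1, 0])  # acc .25
    d = np.array([0, 1, 0, 1])  # acc .50
    voted = ihmv([a, b, c, d], y, r_min=4)[0]
    # epoch 0: votes 1,0,1,0 tied -> member a (most accurate) voted 1
    assert voted.labels[0] == 1
    # epoch 3: votes 0,1,0,1 tied -> a voted 0
    assert voted.labels[3] == 0


def test_greedy_select():
    y = np.array([0, 1, 0, 1])
    good = PredictionVector(labels=np.array([0, 1, 0, 1]))
    ok = PredictionVector(labels=np.array([0, 1, 0, 0]))
    also_good = PredictionVector(labels=np.array([0, 1, 0, 1]))
    best, idx, acc = greedy_select([ok, good, also_good], y)
    assert idx == 1  # earliest of the tied winners
    assert acc == 1.0
    with pytest.raises(ValueError, match="at least one"):
        greedy_select([], y)


def test_run_channel_structure(tiny_collection, tiny_config):
    cfg = tiny_config
    coll = tiny_collection
    cr = run_channel(
        coll.channel(0),
        coll.labels,
        channel_id=1,
        iv=cfg.iv,
        fv=cfg.fv,
        folds=cfg.folds,
        seed=cfg.seed,
    )
    assert cr.channel_id == 1
    assert len(cr.category_accuracies) == 6
    assert len(cr.selected_sizes) == 6
    assert all(cfg.iv <= s <= cfg.fv for s in cr.selected_sizes)
    # greedy dominance: the winner beats or ties every single category
    assert cr.best_accuracy >= max(cr.category_accuracies)
    assert cr.chosen_source.startswith(("category-", "voted-r"))
    assert cr.best_vector.labels.shape == coll.labels.shape


def test_run_channel_wraps_errors():
    with pytest.raises(RuntimeError, match="channel 7 failed"):
        run_channel(np.zeros((4, 30)), np.array([0, 1, 0, 1]), channel_id=7)


def test_run_overall_structure(tiny_collection, tiny_config):
    cfg = tiny_config
    coll = tiny_collection
    fold_ids = make_folds(coll.labels, cfg.folds, cfg.seed)
    crs = [
        run_channel(
            coll.channel(c),
            coll.labels,
            channel_id=c + 1,
            iv=cfg.iv,
            fv=cfg.fv,
            folds=cfg.folds,
            seed=cfg.seed,
            fold_ids=fold_ids,
        )
        for c in range(coll.n_channels)
    ]
    overall = run_overall(crs, coll.labels)
    nch = coll.n_channels
    assert overall.n_candidates == nch + (nch - 2)  # channels + voted r=3..nch
    assert overall.best_accuracy >= max(cr.best_accuracy for cr in crs)
    assert set(overall.contributing_channels) <= set(range(1, nch + 1))
    with pytest.raises(ValueError, match="at least 3"):
        run_overall(crs[:2], coll.labels)
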