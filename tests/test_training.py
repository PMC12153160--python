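"""Loss, metrics, optimisation behaviour and cross-validation."""

import math
import warnings

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from scatddi import (CLASSES, ScatClassifier, ScatConfig, ScatModel,
                     TrainConfig, cross_entropy_loss, evaluate_metrics,
                     kfold_cv)
from scatddi.training import AdamOptimizer, _nll_from_logits


TINY = dict(d_w=6, d_d=4, d_g=2, gru_hidden=4, gru_layers=1, head_dim=4,
            n_heads=2, dropout=0.0)


def planted_pairs(n, rng, labels=CLASSES, mu=4.0, T=4, d=12):
    """Directly planted class-conditional Gaussian sequence pairs."""
    axes = {c: rng.standard_normal(d) / math.sqrt(d) for c in labels}
    X, y = [], []
    for i in range(n):
        c = labels[i % len(labels)]
        X.append((mu * axes[c] + rng.standard_normal((T, d)),
                  mu * axes[c] + rng.standard_normal((T, d))))
        y.append(c)
    return X, np.array(y)


class TestCrossEntropyLoss:
    def test_perfect_predictions_give_zero(self):
        p = np.eye(5)[[0, 2, 4]]
        assert cross_entropy_loss(p, [0, 2, 4]) == 0.0

    def test_uniform_closed_form(self):
        M = 7
        p = np.full((M, 5), 0.2)
        assert abs(cross_entropy_loss(p, [0] * M) - M * math.log(5)) < 1e-12
        assert abs(cross_entropy_loss(p, [0] * M, reduction="mean")
                   - math.log(5)) < 1e-12

    def test_matches_per_item_loop(self, rng):
        p = rng.dirichlet(np.ones(5), size=20)
        labels = rng.integers(0, 5, size=20)
        want = sum(-math.log(p[i, labels[i]]) for i in range(20))
        assert abs(cross_entropy_loss(p, labels) - want) < 1e-9

    def test_zero_probability_clamped_with_warning(self):
        p = np.array([[1.0, 0.0, 0, 0, 0]])
        with pytest.warns(UserWarning):
            loss = cross_entropy_loss(p, [1])
        assert loss == pytest.approx(-math.log(1e-12))

    def test_stable_logit_loss_agrees_with_probability_form(self, rng):
        from scatddi.autodiff import Tensor
        logits = rng.standard_normal((6, 5))
        labels = rng.integers(0, 5, size=6)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        p = e / e.sum(axis=1, keepdims=True)
        want = cross_entropy_loss(p, labels, reduction="mean")
        got = float(_nll_from_logits(Tensor(logits), labels, None).data)
        assert abs(got - want) < 1e-9


class TestMetrics:
    def test_perfect_predictions(self):
        rep = evaluate_metrics(["effect", "int"], ["effect", "int"])
        assert rep.precision == rep.recall == rep.f1 == rep.accuracy == 1.0

    def test_all_one_class_on_balanced_set(self):
        rep = evaluate_metrics(["effect"] * 4,
                               ["effect", "effect", "int", "int"], scope="all")
        assert rep.accuracy == 0.5

    def test_hand_confusion_positive_scope(self):
        gold = ["effect", "effect", "mechanism", "negative", "negative"]
        pred = ["effect", "mechanism", "mechanism", "negative", "effect"]
        rep = evaluate_metrics(pred, gold, scope="positive")
        assert rep.precision == 0.5
        assert rep.recall == pytest.approx(2 / 3)
        assert rep.f1 == pytest.approx(4 / 7)

    def test_micro_identity_all_scope(self, rng):
        labels = [CLASSES[i] for i in rng.integers(0, 5, size=200)]
        preds = [CLASSES[i] for i in rng.integers(0, 5, size=200)]
        rep = evaluate_metrics(preds, labels, scope="all")
        assert rep.precision == rep.recall == rep.accuracy
        assert rep.f1 == pytest.approx(rep.accuracy)

    def test_agrees_with_sklearn_micro(self, rng):
        gold = [CLASSES[i] for i in rng.integers(0, 5, size=120)]
        pred = [CLASSES[i] for i in rng.integers(0, 5, size=120)]
        pos = [c for c in CLASSES if c != "negative"]
        P, R, F, _ = precision_recall_fscore_support(
            gold, pred, labels=pos, average="micro", zero_division=0)
        rep = evaluate_metrics(pred, gold, scope="positive")
        assert rep.precision == pytest.approx(P)
        assert rep.recall == pytest.approx(R)
        assert rep.f1 == pytest.approx(F)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate_metrics([], [])


class TestOptimisation:
    def test_zero_learning_rate_leaves_parameters_unchanged(self, rng):
        model = ScatModel(ScatConfig(**TINY, seed=0))
        before = {k: p.data.copy() for k, p in model.params.items()}
        opt = AdamOptimizer(model.params, lr=0.0)
        X, y = planted_pairs(6, rng)
        idx = {c: i for i, c in enumerate(sorted(set(y)))}
        out = model.forward_batch([a for a, _ in X], [b for _, b in X], train=True)
        loss = _nll_from_logits(out["logits"], np.array([idx[c] for c in y]), None)
        model.zero_grad()
        loss.backward()
        opt.step()
        for k, p in model.params.items():
            np.testing.assert_array_equal(p.data, before[k])

    def test_same_seed_reproduces_identical_parameters(self, rng):
        X, y = planted_pairs(30, rng)
        cfg = ScatConfig(**TINY, seed=5)
        tcfg = TrainConfig(max_iterations=40, mini_batch=10, seed=5)
        runs = []
        for _ in range(2):
            clf = ScatClassifier(config=cfg, train_config=tcfg).fit(X, y)
            runs.append({k: p.data.copy() for k, p in clf.model_.params.items()})
        for k in runs[0]:
            np.testing.assert_array_equal(runs[0][k], runs[1][k])

    def test_single_class_warns_but_trains(self, rng):
        X, y = planted_pairs(12, rng, labels=("effect",))
        cfg = ScatConfig(**TINY, seed=1)
        tcfg = TrainConfig(max_iterations=5, mini_batch=6, seed=1)
        with pytest.warns(UserWarning, match="single-class"):
            clf = ScatClassifier(config=cfg, train_config=tcfg).fit(X, y)
        assert clf.n_iter_ == 5

    def test_overfits_small_planted_set(self, rng):
        """50 planted-signal instances are memorised within 500 steps, and
        the window-smoothed loss trace decreases."""
        X, y = planted_pairs(50, rng, mu=5.0)
        cfg = ScatConfig(**{**TINY, "dropout": 0.01}, seed=2)
        tcfg = TrainConfig(max_iterations=500, mini_batch=30, seed=2)
        clf = ScatClassifier(config=cfg, train_config=tcfg).fit(X, y)
        acc = float(np.mean(clf.predict(X) == y))
        assert acc >= 0.99
        trace = np.array(clf.loss_trace_)
        windows = trace[:len(trace) // 50 * 50].reshape(-1, 50).mean(axis=1)
        assert (np.diff(windows) <= 1e-3).all()
        assert windows[-1] < 0.1 * windows[0]

    def test_inverse_frequency_weighting_lifts_minority_recall(self):
        """95:5 imbalance: median minority recall over 5 seeds is strictly
        higher with inverse-frequency class weighting."""
        recalls = {"off": [], "inverse-frequency": []}
        for seed in range(5):
            r = np.random.Generator(np.random.PCG64(100 + seed))
            axes = {c: r.standard_normal(12) / math.sqrt(12)
                    for c in ("negative", "effect")}

            def make(n_neg, n_pos):
                labels = np.array(["negative"] * n_neg + ["effect"] * n_pos)
                X = [(0.5 * axes[c] + r.standard_normal((4, 12)),
                      0.5 * axes[c] + r.standard_normal((4, 12)))
                     for c in labels]
                return X, labels

            Xtr, ytr = make(95, 5)
            Xte, yte = make(95, 105)
            for mode in recalls:
                cfg = ScatConfig(**TINY, seed=seed)
                tcfg = TrainConfig(max_iterations=60, mini_batch=20,
                                   class_weighting=mode, seed=seed)
                clf = ScatClassifier(config=cfg, train_config=tcfg).fit(Xtr, ytr)
                rep = evaluate_metrics(list(clf.predict(Xte)), list(yte),
                                       scope="positive")
                recalls[mode].append(rep.recall)
        assert (np.median(recalls["inverse-frequency"])
                > np.median(recalls["off"]))


class TestKFold:
    def test_partition_stratification_and_pooled_f1(self, rng):
        X, y = planted_pairs(100, rng, mu=5.0)
        cfg = ScatConfig(**TINY, seed=4)
        tcfg = TrainConfig(max_iterations=60, mini_batch=20, seed=4)
        reports, summary = kfold_cv(X, y, k=5, config=cfg, train_config=tcfg,
                                    scope="all")
        assert len(reports) == 5
        assert sum(r.n for r in reports) == 100
        # stratification: each fold holds 20 instances, 4 per class
        global_frac = {c: np.mean(y == c) for c in set(y)}
        for r in reports:
            for c, (tp, fp, tn, fn) in r.counts.items():
                fold_count = tp + fn
                expected = global_frac[c] * r.n
                assert abs(fold_count - expected) <= 1.0
        # pooled report equals metrics on pooled out-of-fold predictions
        pooled = summary["pooled"]
        assert pooled.n == 100
        assert 0.0 <= pooled.f1 <= 1.0
        assert summary["mean"]["f1"] == pytest.approx(
            np.mean([r.f1 for r in reports]))

    def test_rare_class_merged_with_warning(self, rng):
        X, y = planted_pairs(40, rng, labels=("negative", "effect"))
        y[:3] = "int"  # 3 < k members
        with pytest.warns(UserWarning, match="fewer than"):
            reports, _ = kfold_cv(
                X, list(y), k=5, config=ScatConfig(**TINY, seed=0),
                train_config=TrainConfig(max_iterations=5, mini_batch=10, seed=0))
        assert sum(r.n for r in reports) == 40

    def test_k_larger_than_dataset_rejected(self, rng):
        X, y = planted_pairs(3, rng)
        with pytest.raises(ValueError):
            kfold_cv(X, y, k=5)
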