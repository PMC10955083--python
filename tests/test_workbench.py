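"""Training engine, metrics, fold aggregation and experiment drivers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mpfusion import workbench as wb
from mpfusion.fusion_baselines import build_model
from mpfusion.synthdata import SynthConfig, generate_cohort
from mpfusion.workbench import (Dataset, TrainConfig, aggregate_folds,
                                cross_validate, evaluate, metrics_from_probs,
                                run_experiment, train, tsne_export)


def _tiny_splits(seed=0, n_per_class=6):
    cohort = generate_cohort(SynthConfig(n_patients_per_class=n_per_class,
                                         image_size=16, seed=seed,
                                         class_imbalance=0.5))
    data = Dataset.from_cohort(cohort)
    labels = dict(zip(data.patient_ids, data.y))
    split = {}
    for lab in (0, 1):
        pids = sorted(p for p in set(data.patient_ids) if labels[p] == lab)
        for i, p in enumerate(pids):
            split[p] = "test" if i == 0 else "val" if i == 1 else "train"
    roles = np.array([split[p] for p in data.patient_ids])
    return {r: data.subset(roles == r) for r in ("train", "val", "test")}


def _probs_from_confusion(tn, fp, fn, tp):
    """Build predictions realising a given 2x2 confusion table."""
    y = [0] * (tn + fp) + [1] * (fn + tp)
    score = ([0.1] * tn + [0.9] * fp + [0.1] * fn + [0.9] * tp)
    probs = np.stack([1 - np.asarray(score), np.asarray(score)], axis=1)
    return np.asarray(y), probs


class TestMetrics:
    def test_hand_confusion_table(self):
        """TN=5, FP=1, FN=1, TP=3 -> accuracy 0.8, F1 0.75."""
        y, probs = _probs_from_confusion(5, 1, 1, 3)
        rep = metrics_from_probs(y, probs)
        assert rep.accuracy == pytest.approx(0.8)
        assert rep.f1 == pytest.approx(0.75)
        assert rep.confusion == [[5, 1], [1, 3]]
        assert rep.n == 10

    def test_perfect_predictions(self):
        y, probs = _probs_from_confusion(4, 0, 0, 6)
        rep = metrics_from_probs(y, probs)
        assert (rep.accuracy, rep.f1, rep.auc) == (1.0, 1.0, 1.0)

    def test_constant_scores_give_auc_half(self):
        y = np.array([0, 1, 0, 1])
        probs = np.full((4, 2), 0.5)
        rep = metrics_from_probs(y, probs)
        assert rep.auc == pytest.approx(0.5)

    def test_single_class_eval_warns_and_omits_auc(self):
        y = np.ones(5, dtype=int)
        probs = np.tile([0.3, 0.7], (5, 1))
        with pytest.warns(UserWarning, match="AUC undefined"):
            rep = metrics_from_probs(y, probs)
        assert rep.auc is None

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30),
           st.integers(1, 30))
    @settings(max_examples=40, deadline=None)
    def test_matches_naive_definitions(self, tn, fp, fn, tp):
        """Accuracy and F1 agree with their textbook formulas over random
        contingency tables."""
        y, probs = _probs_from_confusion(tn, fp, fn, tp)
        rep = metrics_from_probs(y, probs)
        n = tn + fp + fn + tp
        assert rep.accuracy == pytest.approx((tn + tp) / n, abs=5e-5)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn)
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        assert rep.f1 == pytest.approx(f1, abs=5e-5)
        assert int(np.sum(rep.confusion)) == n


class TestAggregation:
    def test_reference_ten_fold_accuracies(self):
        """Mean/population-variance of the reference per-fold
        accuracies: 0.9375 / 0.0001 at 4 decimals."""
        folds = [0.9545, 0.9375, 0.9261, 0.9432, 0.9318,
                 0.9261, 0.9375, 0.9375, 0.9602, 0.9204]
        assert aggregate_folds(folds) == (0.9375, 0.0001)

    def test_population_not_sample_variance(self):
        folds = [0.9545, 0.9375, 0.9261, 0.9432, 0.9318,
                 0.9261, 0.9375, 0.9375, 0.9602, 0.9204]
        v = np.var(folds, ddof=1)          # sample variance rounds to 0.0002
        assert round(float(v), 4) != aggregate_folds(folds)[1]

    def test_identical_folds_have_zero_variance(self):
        assert aggregate_folds([0.9] * 7) == (0.9, 0.0)


class TestTraining:
    def test_loss_descends_and_history_is_deterministic(self):
        splits = _tiny_splits(seed=1)
        cfg = TrainConfig(epochs=6, seed=3)
        model = build_model("single_b", arch="compact-test", hidden=8)
        p1, h1 = train(model, splits, cfg)
        assert h1.train_loss.iloc[5] < h1.train_loss.iloc[0]
        model2 = build_model("single_b", arch="compact-test", hidden=8)
        p2, h2 = train(model2, splits, cfg)
        pd.testing.assert_frame_equal(h1, h2)
        np.testing.assert_array_equal(
            model.predict_proba(p1, splits["test"].x1, splits["test"].x2),
            model2.predict_proba(p2, splits["test"].x1, splits["test"].x2))

    def test_l1_penalty_raises_objective(self):
        splits = _tiny_splits(seed=1)
        model = build_model("single_a", arch="compact-test", hidden=8)
        params = model.init(0)
        from mpfusion import nn
        tr = splits["train"]
        ce = float(nn.cross_entropy(model.logits(params, tr.x1, tr.x2), tr.y))
        lam = 1e-4
        with_l1 = ce + lam * float(nn.l1_penalty(params))
        assert with_l1 > ce

    def test_empty_training_split_rejected(self):
        splits = _tiny_splits(seed=1)
        empty = splits["train"].subset(np.zeros(len(splits["train"]), bool))
        with pytest.raises(ValueError, match="empty"):
            train(build_model("single_a", hidden=8), {"train": empty})

    def test_early_stopping_restores_best(self):
        splits = _tiny_splits(seed=2)
        cfg = TrainConfig(epochs=30, patience=2, seed=0,
                          learning_rate=0.05)
        model = build_model("single_a", arch="compact-test", hidden=8)
        params, hist = train(model, splits, cfg)
        # stopped early or ran out; either way best val loss was restored
        assert len(hist) <= 30
        best = hist.val_loss.min()
        va = splits["val"]
        from mpfusion import nn
        final = float(nn.cross_entropy(
            model.logits(params, va.x1, va.x2), va.y))
        l1 = cfg.l1_lambda * float(nn.l1_penalty(params))
        assert final + l1 == pytest.approx(best, abs=1e-9)


class TestCrossValidate:
    def test_patient_level_cv_aggregates(self):
        cohort = generate_cohort(SynthConfig(
            n_patients_per_class=8, image_size=16, seed=9,
            class_imbalance=0.5, effect_a=2.0, effect_b=2.0))
        data = Dataset.from_cohort(cohort)
        cfg = TrainConfig(epochs=3, seed=0)
        rep = cross_validate(
            lambda: build_model("single_b", arch="compact-test", hidden=8),
            data, k=4, cfg=cfg)
        assert len(rep.per_fold) == 4
        assert sum(r.n for r in rep.per_fold) == len(data)
        accs = [r.accuracy for r in rep.per_fold]
        assert rep.mean["accuracy"] == aggregate_folds(accs)[0]
        assert rep.var["accuracy"] == aggregate_folds(accs)[1]


class TestExperiment:
    def test_arms_run_and_are_deterministic(self):
        splits = _tiny_splits(seed=5)
        cfg = TrainConfig(epochs=3, seed=1)
        arms = ["single_a", {"strategy": "saff", "use_ma": False},
                {"strategy": "saff", "name": "saff_ma", "use_ma": True},
                "decision_level", "input_level", "feature_level"]
        kw = dict(arch="compact-test", hidden=8)
        t1, r1 = run_experiment(arms, splits, cfg, model_kwargs=kw)
        assert list(t1.arm) == ["single_a", "saff", "saff_ma",
                                "decision_level", "input_level",
                                "feature_level"]
        assert t1.accuracy.between(0, 1).all()
        t2, _ = run_experiment(arms, splits, cfg, model_kwargs=kw)
        pd.testing.assert_frame_equal(t1, t2)

    def test_unknown_arm_rejected(self):
        with pytest.raises(ValueError, match="unknown arm"):
            run_experiment(["gated_moe"], _tiny_splits(), TrainConfig(epochs=1))


class TestTSNE:
    def test_cardinality_seed_and_duplicates(self, rng, tmp_path):
        base = rng.normal(size=(20, 8))
        feats = np.vstack([base, base[:2]])      # two duplicated points
        labels = np.arange(22) % 2
        out = tmp_path / "emb.csv"
        df1 = tsne_export(feats, labels, path=out, seed=0)
        assert len(df1) == 22 and out.exists()
        df2 = tsne_export(feats, labels, seed=0)
        pd.testing.assert_frame_equal(df1, df2)
        # duplicated inputs stay nearby: their distance is far below the
        # embedding's typical spread
        emb = df1[["x", "y"]].to_numpy()
        spread = np.linalg.norm(emb.std(axis=0))
        for i in (0, 1):
            d = np.linalg.norm(emb[i] - emb[20 + i])
            assert d < 0.25 * spread

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            tsne_export(rng.normal(size=(3, 4)), [0, 1, 0], perplexity=30)
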