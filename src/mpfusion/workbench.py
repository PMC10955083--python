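"""Training/evaluation engine, metrics, cross-validation and experiments.

The training recipe mirrors the reference clinical protocol: SGD (learning rate 0.01),
50 epochs, batch size 8, cross-entropy loss with an L1 weight penalty, and
early stopping on the validation loss with best-weight restoration.  Every
run is seeded and single-threaded, so histories are bit-reproducible.

Fold aggregation reports the arithmetic mean and the *population* variance
(divide by k, not k-1) of each metric, rounded half-even to 4 decimals.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field

import numpy as onp
import pandas as pd
from autograd import grad as _grad
from sklearn.metrics import (accuracy_score, confusion_matrix, f1_score,
                             roc_auc_score)

from . import nn
from .fusion_baselines import build_model, decision_level_fuse, input_level_dataset
from .preprocess import kfold_split

__all__ = [
    "TrainConfig", "MetricsReport", "train", "evaluate", "cross_validate",
    "run_experiment", "tsne_export", "aggregate_folds", "Dataset",
]


@dataclass
class TrainConfig:
    """Optimisation recipe; the defaults are the reference clinical protocol."""

    learning_rate: float = 0.01
    epochs: int = 50
    batch_size: int = 8
    l1_lambda: float = 1e-5
    monitor: str = "val_loss"
    patience: int = 10
    seed: int = 0
    verbose: bool = False


@dataclass
class Dataset:
    """In-memory paired dataset: NHWC image arrays per modality, integer
    labels and patient ids."""

    x1: object
    x2: object
    y: object
    patient_ids: object

    @classmethod
    def from_cohort(cls, cohort, records=None):
        x1, x2, y, pids = cohort.arrays(records)
        return cls(x1, x2, y, pids)

    def subset(self, mask):
        return Dataset(self.x1[mask], self.x2[mask], self.y[mask],
                       self.patient_ids[mask])

    def split_by(self, manifest):
        """Split slices by a patient-level manifest -> dict of Datasets."""
        roles = onp.array([manifest.assignment[p] for p in self.patient_ids])
        return {role: self.subset(roles == role)
                for role in ("train", "val", "test")
                if onp.any(roles == role)}

    def __len__(self):
        return len(self.y)


@dataclass
class MetricsReport:
    """Evaluation metrics: accuracy, F1 and AUC in [0, 1] (positive class =
    high-grade), a [[TN, FP], [FN, TP]] confusion matrix, and — when
    produced by cross-validation — per-fold values with their mean and
    population variance."""

    accuracy: float
    f1: float
    auc: float | None
    confusion: list
    n: int
    per_fold: list = field(default_factory=list)
    mean: dict = field(default_factory=dict)
    var: dict = field(default_factory=dict)

    def to_dict(self):
        return {"accuracy": self.accuracy, "f1": self.f1, "auc": self.auc,
                "confusion": self.confusion, "n": self.n,
                "mean": self.mean, "var": self.var}


def _metrics(y_true, y_pred, scores):
    acc = accuracy_score(y_true, y_pred)
    f1 = f1_score(y_true, y_pred, pos_label=1, zero_division=0)
    if len(onp.unique(y_true)) < 2:
        warnings.warn("single-class evaluation set: AUC undefined")
        auc = None
    else:
        auc = float(roc_auc_score(y_true, scores))
    cm = confusion_matrix(y_true, y_pred, labels=[0, 1])
    return MetricsReport(accuracy=round(float(acc), 4),
                         f1=round(float(f1), 4),
                         auc=None if auc is None else round(auc, 4),
                         confusion=cm.tolist(), n=int(len(y_true)))


def metrics_from_probs(y_true, probs):
    probs = onp.asarray(probs)
    return _metrics(onp.asarray(y_true), probs.argmax(axis=1), probs[:, 1])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _batches(n, batch_size, rng):
    idx = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield idx[start:start + batch_size]


def train(model, data, cfg: TrainConfig | None = None, params=None):
    """Train a fusion model by mini-batch SGD.

    ``data`` maps 'train' (and optionally 'val') to :class:`Dataset`
    objects.  The objective is cross-entropy plus ``l1_lambda`` times the
    L1 norm of the weight kernels (biases and norm parameters excluded).
    With a validation split, training stops once the monitored loss has not
    improved for ``patience`` epochs and the best parameters are restored.

    Returns ``(params, history)`` with a per-epoch history DataFrame.
    """
    cfg = cfg or TrainConfig()
    tr = data["train"]
    if len(tr) == 0:
        raise ValueError("empty training split")
    va = data.get("val")
    if params is None:
        params = model.init(cfg.seed)
    rng = onp.random.default_rng(cfg.seed + 1)

    def loss_fn(p, xb1, xb2, yb):
        ce = nn.cross_entropy(model.logits(p, xb1, xb2), yb)
        if cfg.l1_lambda > 0:
            ce = ce + cfg.l1_lambda * nn.l1_penalty(p)
        return ce

    gfun = _grad(loss_fn)
    history, best, best_loss, stale = [], None, onp.inf, 0
    for epoch in range(cfg.epochs):
        losses = []
        for idx in _batches(len(tr), cfg.batch_size, rng):
            xb1 = tr.x1[idx] if tr.x1 is not None else None
            xb2 = tr.x2[idx] if tr.x2 is not None else None
            yb = tr.y[idx]
            lval = float(loss_fn(params, xb1, xb2, yb))
            if not onp.isfinite(lval):
                raise RuntimeError(
                    f"non-finite loss {lval} at epoch {epoch}; "
                    "try lowering the learning rate")
            g = gfun(params, xb1, xb2, yb)
            params = nn.sgd_step(params, g, cfg.learning_rate)
            losses.append(lval)
        row = {"epoch": epoch, "train_loss": float(onp.mean(losses))}
        if va is not None and len(va) > 0:
            vl = float(loss_fn(params, va.x1, va.x2, va.y))
            probs = model.predict_proba(params, va.x1, va.x2)
            row["val_loss"] = vl
            row["val_accuracy"] = float(
                accuracy_score(va.y, probs.argmax(axis=1)))
            monitored = row[cfg.monitor]
            if monitored < best_loss - 1e-12:
                best_loss, best, stale = monitored, copy.deepcopy(params), 0
            else:
                stale += 1
        history.append(row)
        if cfg.verbose:
            print(f"epoch {epoch}: {row}")
        if va is not None and stale > cfg.patience:
            break
    if best is not None:
        params = best
    return params, pd.DataFrame(history)


def evaluate(model, params, data: Dataset, patient_level=False):
    """Compute the metrics report on a labeled split.

    With ``patient_level=True``, slice probabilities are averaged per
    patient before thresholding (the default reports slice-level metrics).
    """
    probs = model.predict_proba(params, data.x1, data.x2)
    y = onp.asarray(data.y)
    if patient_level:
        df = pd.DataFrame({"pid": data.patient_ids, "p1": probs[:, 1],
                           "y": y})
        agg = df.groupby("pid").mean()
        probs = onp.stack([1 - agg.p1.values, agg.p1.values], axis=1)
        y = agg.y.values.astype(int)
    return metrics_from_probs(y, probs)


# ---------------------------------------------------------------------------
# cross-validation and experiments
# ---------------------------------------------------------------------------

def aggregate_folds(values):
    """Arithmetic mean and population variance (divide by k) of per-fold
    metric values, each rounded half-even to 4 decimals."""
    v = onp.asarray([x for x in values if x is not None], dtype=float)
    return (float(onp.round(onp.mean(v), 4)),
            float(onp.round(onp.var(v), 4)))


def cross_validate(model_builder, data: Dataset, k=10,
                   cfg: TrainConfig | None = None):
    """Patient-level k-fold cross-validation.

    ``model_builder()`` must return a fresh model; each fold trains from
    scratch on k-2 subsets, early-stops on one validation subset and is
    scored on its test subset, so every patient is tested exactly once.
    """
    cfg = cfg or TrainConfig()
    patients = pd.DataFrame({"patient_id": data.patient_ids,
                             "label": data.y}).drop_duplicates("patient_id")
    folds = kfold_split(patients, k=k, seed=cfg.seed)
    reports = []
    for manifest in folds:
        splits = data.split_by(manifest)
        if len(onp.unique(splits["test"].y)) < 2:
            raise ValueError(f"fold {manifest.fold} has a single-class test set")
        model = model_builder()
        params, _ = train(model, splits, cfg)
        reports.append(evaluate(model, params, splits["test"]))
    agg = MetricsReport(accuracy=0.0, f1=0.0, auc=None, confusion=[], n=sum(r.n for r in reports))
    agg.per_fold = reports
    for metric in ("accuracy", "f1", "auc"):
        vals = [getattr(r, metric) for r in reports]
        m, v = aggregate_folds(vals)
        agg.mean[metric], agg.var[metric] = m, v
        setattr(agg, metric, m)
    return agg


_KNOWN_ARMS = ("single_a", "single_b", "saff", "feature_level",
               "decision_level", "input_level")


def run_experiment(arms, data_splits, cfg: TrainConfig | None = None,
                   model_kwargs=None, out_json=None):
    """Train and evaluate a set of experiment arms on shared splits.

    ``arms`` is a list of strategy names (or dicts with a ``strategy`` key
    plus model overrides); all arms share the same seed, splits and recipe,
    so differences reflect the fusion strategy.  Returns a tidy DataFrame
    of test metrics, one row per arm.
    """
    cfg = cfg or TrainConfig()
    model_kwargs = dict(model_kwargs or {})
    rows, reports = [], {}
    for arm in arms:
        arm_cfg = {"strategy": arm} if isinstance(arm, str) else dict(arm)
        strategy = arm_cfg.pop("strategy")
        name = arm_cfg.pop("name", strategy)
        if strategy not in _KNOWN_ARMS:
            raise ValueError(f"unknown arm {strategy!r}")
        kw = {**model_kwargs, **arm_cfg}
        if strategy == "decision_level":
            report = _decision_level_arm(data_splits, cfg, kw)
        elif strategy == "input_level":
            report = _input_level_arm(data_splits, cfg, kw)
        else:
            model = build_model(strategy, **kw)
            params, _ = train(model, data_splits, cfg)
            report = evaluate(model, params, data_splits["test"])
        reports[name] = report
        rows.append({"arm": name, "accuracy": report.accuracy,
                     "f1": report.f1, "auc": report.auc, "n": report.n})
    table = pd.DataFrame(rows)
    if out_json:
        with open(out_json, "w") as fh:
            json.dump({k: r.to_dict() for k, r in reports.items()}, fh,
                      indent=2)
    return table, reports


def _decision_level_arm(splits, cfg, kw):
    """Two single-modality networks fused with validation-accuracy-
    proportional soft weights."""
    weights = []
    probs_test = []
    for modality in ("a", "b"):
        model = build_model(f"single_{modality}", **kw)
        params, _ = train(model, splits, cfg)
        va = splits.get("val")
        if va is not None and len(va) > 0:
            rep = evaluate(model, params, va)
            weights.append(rep.accuracy)
        else:
            weights.append(1.0)
        te = splits["test"]
        probs_test.append(model.predict_proba(params, te.x1, te.x2))
    fused = decision_level_fuse(probs_test[0], probs_test[1],
                                weights=weights)
    return metrics_from_probs(splits["test"].y, fused)


def _input_level_arm(splits, cfg, kw):
    """Sample pooling: one shared network on the pooled modality images;
    test samples are pooled the same way."""
    model = build_model("input_level", **kw)
    pooled = {}
    for role, ds in splits.items():
        x, y, pids = input_level_dataset(ds.x1, ds.x2, ds.y,
                                         ds.patient_ids)
        pooled[role] = Dataset(x, None, y, pids)
    params, _ = train(model, pooled, cfg)
    return evaluate(model, params, pooled["test"])


# ---------------------------------------------------------------------------
# synthetic fusion benchmark
# ---------------------------------------------------------------------------

def synthetic_fusion_benchmark(effect_a=1.0, effect_b=1.0, seeds=(0, 1, 2),
                               arms=("single_a", "single_b", "saff"),
                               n_train_patients_per_class=20,
                               n_test_patients_per_class=30,
                               image_size=32, epochs=15, patience=4,
                               use_ma=True, hidden=64):
    """Compact-backbone strategy comparison on generator data.

    For each seed, a training cohort is generated, split 9:1 into
    train/val at the patient level, and each arm is trained with the shared
    recipe; evaluation uses an independent test cohort from the same
    conditions (held-out patients, larger for tighter Monte-Carlo error).
    Returns a tidy DataFrame (one row per arm x seed) plus the Bayes-oracle
    accuracy/AUC bounds of the cue model for each arm's input.
    """
    from .preprocess import stratified_patient_split
    from .synthdata import SynthConfig, bayes_accuracy, bayes_auc, generate_cohort

    rows = []
    for seed in seeds:
        tr_cohort = generate_cohort(SynthConfig(
            n_patients_per_class=n_train_patients_per_class,
            image_size=image_size, effect_a=effect_a, effect_b=effect_b,
            seed=seed))
        te_cohort = generate_cohort(SynthConfig(
            n_patients_per_class=n_test_patients_per_class,
            image_size=image_size, effect_a=effect_a, effect_b=effect_b,
            seed=seed + 10_000))
        data = Dataset.from_cohort(tr_cohort)
        patients = pd.DataFrame({"patient_id": data.patient_ids,
                                 "label": data.y})
        manifest = stratified_patient_split(patients, ratios=(9, 1, 0),
                                            seed=seed)
        splits = data.split_by(manifest)
        splits["test"] = Dataset.from_cohort(te_cohort)
        cfg = TrainConfig(epochs=epochs, patience=patience, seed=seed)
        table, _ = run_experiment(list(arms), splits, cfg,
                                  model_kwargs=dict(arch="compact-test",
                                                    use_ma=use_ma,
                                                    hidden=hidden))
        table["seed"] = seed
        rows.append(table)
    result = pd.concat(rows, ignore_index=True)
    prior = SynthConfig().class_imbalance
    cue = SynthConfig().cue_noise
    arm_effects = {"single_a": [effect_a], "single_b": [effect_b]}
    bounds = {}
    for arm in result["arm"].unique():
        eff = arm_effects.get(arm, [effect_a, effect_b])
        bounds[arm] = {"bayes_accuracy": bayes_accuracy(eff, cue, prior),
                       "bayes_auc": bayes_auc(eff, cue)}
    return result, bounds


# ---------------------------------------------------------------------------
# t-SNE export
# ---------------------------------------------------------------------------

def tsne_export(features, labels, path=None, seed=0, perplexity=None):
    """2-D t-SNE embedding of a feature matrix for visual inspection.

    Returns a DataFrame with columns (x, y, label); written as CSV when
    ``path`` is given.  Utility only — no quantitative claims.
    """
    from sklearn.manifold import TSNE

    features = onp.asarray(features, dtype=float)
    n = features.shape[0]
    if perplexity is None:
        perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
    if n <= perplexity:
        raise ValueError(f"{n} samples too few for perplexity {perplexity}")
    emb = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
               init="pca").fit_transform(features)
    df = pd.DataFrame({"x": emb[:, 0], "y": emb[:, 1],
                       "label": onp.asarray(labels)})
    if path is not None:
        df.to_csv(path, index=False)
    return df
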