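"""Random-forest discrimination of MK vs NS with permutation importance.

A single stratified 70/30 split mirrors the study design.  Variable
importance is the mean decrease in held-out accuracy when one feature's
test column is permuted; the panel is the top five features by that score.
The reported AUC uses the Mann-Whitney identity (probability that a random
positive outscores a random negative, ties counted one half), with a
stratified percentile-bootstrap 95% confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve

from .tables import SampleMetadata

log = logging.getLogger("keloidomics.classifier")


def stratified_split(meta: SampleMetadata, train_frac: float = 0.7,
                     seed: int = 0) -> Tuple[List[str], List[str]]:
    """Per-group split with nearest rounding, at least one train and one
    test sample per group; disjoint, exhaustive, seed-deterministic."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for g in ("MK", "NS"):
        ids = np.array(meta.ids_in(g))
        if ids.size < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")
        n_train = int(round(train_frac * ids.size))
        n_train = min(max(n_train, 1), ids.size - 1)
        perm = rng.permutation(ids)
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return sorted(train), sorted(test)


def rf_importance(features: pd.DataFrame, meta: SampleMetadata,
                  train_ids: Sequence[str], test_ids: Sequence[str],
                  n_trees: int = 500, n_repeats: int = 10, seed: int = 0,
                  estimator: str = "oob"
                  ) -> Tuple[RandomForestClassifier, Dict[str, float]]:
    """Fit a random forest on the training samples and score each feature
    by mean decrease in accuracy (MDA).

    The default ``oob`` estimator is the classic randomForest one: for each
    tree, accuracy on its out-of-bag samples is compared with accuracy
    after permuting one feature's out-of-bag column, and the decreases are
    averaged over trees (and ``n_repeats`` permutations).  Its per-tree
    resolution separates correlated informative features that whole-forest
    permutation cannot (a redundant ensemble rarely flips a prediction when
    a single feature is permuted).  ``estimator="test"`` instead permutes
    columns of the held-out test set against the whole forest.
    """
    y_train = (meta.labels_for(train_ids) == "MK").astype(int)
    y_test = (meta.labels_for(test_ids) == "MK").astype(int)
    if len(set(y_train)) < 2:
        raise ValueError("training set contains a single class")
    x_train = features.loc[list(train_ids)].to_numpy(float)
    x_test = features.loc[list(test_ids)].to_numpy(float)
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    model.fit(x_train, y_train)
    rng = np.random.default_rng(seed)
    if estimator == "oob":
        drop = _oob_mda(model, x_train, y_train, n_repeats, rng)
    elif estimator == "test":
        drop = _whole_forest_mda(model, x_test, y_test, n_repeats, rng)
    else:
        raise ValueError(f"unknown importance estimator {estimator!r}")
    importance = dict(zip(features.columns, drop))
    return model, importance


def _perm_block(x: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Stack of copies of x, copy j with column j permuted by ``perm``."""
    n, j = x.shape
    block = np.repeat(x[None, :, :], j, axis=0)
    idx = np.arange(j)
    block[idx, :, idx] = x[perm][:, idx].T
    return block.reshape(j * n, j)


def _whole_forest_mda(model, x_eval, y_eval, n_repeats, rng) -> np.ndarray:
    n, j = x_eval.shape
    baseline = (model.predict(x_eval) == y_eval).mean()
    acc = np.empty((n_repeats, j))
    for rep in range(n_repeats):
        preds = model.predict(_perm_block(x_eval, rng.permutation(n))).reshape(j, n)
        acc[rep] = (preds == y_eval[None, :]).mean(axis=1)
    return baseline - acc.mean(axis=0)


def _oob_mda(model, x_train, y_train, n_repeats, rng) -> np.ndarray:
    from sklearn.ensemble._forest import (_generate_unsampled_indices,
                                          _get_n_samples_bootstrap)

    n, j = x_train.shape
    try:
        n_boot = _get_n_samples_bootstrap(n, model.max_samples)
    except TypeError:  # newer sklearn adds a sample_weight argument
        n_boot = _get_n_samples_bootstrap(n, model.max_samples, None)
    total = np.zeros(j)
    used = 0
    for tree in model.estimators_:
        try:
            oob_idx = _generate_unsampled_indices(tree.random_state, n, n_boot)
        except TypeError:
            oob_idx = _generate_unsampled_indices(tree.random_state, n, n_boot, None)
        if oob_idx.size < 2 or len(set(y_train[oob_idx])) < 1:
            continue
        xo, yo = x_train[oob_idx], y_train[oob_idx]
        base = (tree.predict(xo) == yo).mean()
        m = xo.shape[0]
        accs = np.empty((n_repeats, j))
        for rep in range(n_repeats):
            preds = tree.predict(_perm_block(xo, rng.permutation(m))).reshape(j, m)
            accs[rep] = (preds == yo[None, :]).mean(axis=1)
        total += base - accs.mean(axis=0)
        used += 1
    if used == 0:
        raise RuntimeError("no tree had out-of-bag samples")
    return total / used


def select_panel(importance: Dict[str, float], k: int = 5) -> List[str]:
    """Top-k features by importance, ties broken by feature id."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(importance):
        log.warning("k=%d exceeds %d scored features; returning all", k, len(importance))
    ranked = sorted(importance.items(), key=lambda kv: (-kv[1], kv[0]))
    return [f for f, _ in ranked[:k]]


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney probability that a positive outscores a
    negative, ties counted one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return float((gt + 0.5 * eq) / (pos.size * neg.size))


def roc_auc(scores: Sequence[float], labels: Sequence[int], n_boot: int = 2000,
            seed: int = 0) -> Tuple[List[Tuple[float, float]], float, Tuple[float, float]]:
    """ROC points, Mann-Whitney AUC, and a stratified percentile-bootstrap
    95% confidence interval over (score, label) pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    auc = auc_mann_whitney(scores, labels)
    fpr, tpr, _ = roc_curve(labels, scores)
    points = list(zip(fpr.tolist(), tpr.tolist()))
    rng = np.random.default_rng(seed)
    ipos = np.flatnonzero(labels == 1)
    ineg = np.flatnonzero(labels == 0)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        rp = rng.choice(ipos, size=ipos.size, replace=True)
        rn = rng.choice(ineg, size=ineg.size, replace=True)
        idx = np.concatenate([rp, rn])
        boots[b] = auc_mann_whitney(scores[idx], labels[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo, hi = min(lo, auc), max(hi, auc)
    return points, auc, (float(lo), float(hi))


@dataclass
class ClassifierReport:
    layer: str
    train_ids: List[str]
    test_ids: List[str]
    importance: Dict[str, float]
    panel: List[str]
    roc_points: List[Tuple[float, float]]
    auc: float
    auc_ci: Tuple[float, float]
    seed: int

    def to_dict(self) -> dict:
        return {
            "layer": self.layer, "train_ids": self.train_ids,
            "test_ids": self.test_ids,
            "importance": {k: float(v) for k, v in self.importance.items()},
            "panel": self.panel, "roc_points": self.roc_points,
            "auc": self.auc, "auc_ci": list(self.auc_ci), "seed": self.seed,
        }


def classify_layer(features: pd.DataFrame, meta: SampleMetadata,
                   layer: str = "taxa", train_frac: float = 0.7, top_k: int = 5,
                   n_trees: int = 500, n_repeats: int = 10, n_boot: int = 2000,
                   seed: int = 0, roc_on: str = "test",
                   importance_estimator: str = "oob") -> ClassifierReport:
    """Full discrimination workflow for one omics layer: split, fit, score
    importance, select the panel, and evaluate ROC/AUC on out-of-sample
    forest votes."""
    train_ids, test_ids = stratified_split(meta, train_frac, seed)
    model, importance = rf_importance(features, meta, train_ids, test_ids,
                                      n_trees, n_repeats, seed,
                                      estimator=importance_estimator)
    panel = select_panel(importance, top_k)
    eval_ids = test_ids if roc_on == "test" else list(features.index)
    scores = model.predict_proba(features.loc[eval_ids].to_numpy(float))[:, 1]
    labels = (meta.labels_for(eval_ids) == "MK").astype(int)
    points, auc, ci = roc_auc(scores, labels, n_boot=n_boot, seed=seed)
    log.info("layer %s: AUC %.3f [%.3f, %.3f], panel %s", layer, auc, *ci, panel)
    return ClassifierReport(layer, list(train_ids), list(test_ids), importance,
                            panel, points, auc, ci, int(seed))
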