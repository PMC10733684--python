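"""Workflow A: can each non-neotissue constituent be detected from the spectra?

Technical replicates are averaged to one preprocessed spectrum per sample,
then each of the nine algorithms is evaluated by seeded stratified 10-fold
cross-validation per constituent flag.  Out-of-fold predictions are pooled
over the folds into a single confusion matrix per (constituent, algorithm),
from which F1 and AUC are reported.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import algorithms as zoo
from .metrics import auc_score, confusion_from_predictions, f1_score
from .spectra import CONSTITUENTS, Inventory, average_replicates

__all__ = ["stratified_kfold_indices", "run_workflow_a", "sample_matrix"]

log = logging.getLogger(__name__)


def stratified_kfold_indices(labels, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Seeded stratified test folds: k disjoint index arrays covering all samples,
    each with class proportions within one sample of the global proportion."""
    labels = np.asarray(labels).astype(int)
    n = labels.size
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of samples ({n})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros((n, 1)), labels)]


def sample_matrix(inv: Inventory) -> tuple[np.ndarray, list[str]]:
    """Replicate-averaged intensity matrix (samples x channels) + sample ids."""
    X = np.stack([average_replicates(s).intensities for s in inv.samples])
    return X, inv.sample_ids


def run_workflow_a(
    inv: Inventory,
    constituents=CONSTITUENTS,
    algorithm_names=zoo.ALGORITHM_NAMES,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate every (constituent, algorithm) pair on a preprocessed inventory.

    Returns a table with one row per pair: pooled out-of-fold confusion counts,
    F1 and AUC.  Positive class = constituent present.  A constituent that is
    constant across the inventory is skipped with a warning.
    """
    X, _ = sample_matrix(inv)
    rows = []
    for ci, constituent in enumerate(constituents):
        y = np.array([s.flag(constituent) for s in inv.samples], dtype=int)
        if y.min() == y.max():
            log.warning("constituent %s is constant across the inventory; skipped",
                        constituent)
            continue
        folds = stratified_kfold_indices(y, k=k, seed=_fold_seed(seed, ci))
        for ai, name in enumerate(algorithm_names):
            spec = zoo.make_algorithm(name, seed=_fold_seed(seed, ci, ai + 1))
            pred = np.empty_like(y)
            scores = np.empty(y.size, dtype=float)
            for test_idx in folds:
                train_mask = np.ones(y.size, dtype=bool)
                train_mask[test_idx] = False
                model = zoo.fit(spec, X[train_mask], y[train_mask])
                pred[test_idx] = zoo.predict_labels(model, X[test_idx])
                scores[test_idx] = zoo.predict_scores(model, X[test_idx])
            cm = confusion_from_predictions(y == 1, pred == 1,
                                            positive_class_label=constituent)
            rows.append(
                {
                    "constituent": constituent,
                    "algorithm": name,
                    "AUC": auc_score(scores[y == 1], scores[y == 0]).value,
                    "F1": f1_score(cm).value,
                    "tp": cm.tp,
                    "fp": cm.fp,
                    "fn": cm.fn,
                    "tn": cm.tn,
                }
            )
    return pd.DataFrame(rows)


def _fold_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))
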