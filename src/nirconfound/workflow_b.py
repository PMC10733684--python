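"""Workflow B step 1: controlled vs uncontrolled maturity models.

For each constituent, nine uncontrolled models (trained on the deliberately
confounded arms) and nine controlled models (trained on the shared
propensity-matched set) predict construct maturity (Day-28 = positive) on
the same test set.  Training uses replicate-level spectra; test samples are
replicate-averaged.  Per constituent the paired per-algorithm F1/AUC
differences are summarised with the rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import algorithms as zoo
from .metrics import (
    TestResult,
    auc_score,
    confusion_from_predictions,
    f1_score,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from .partition import (
    PartitionSpec,
    build_partition,
    estimate_propensity,
    match_nearest_neighbor,
)
from .spectra import CONSTITUENTS, Inventory, average_replicates

__all__ = ["ComparisonResult", "run_step1", "build_all_partitions",
           "DEFAULT_N_PAIRS", "training_matrix", "test_matrix"]

#: Default cap on matched pairs retained in the controlled training set.
#: Mirrors the reference study's controlled-set size (10 pairs, 20 samples)
#: and keeps Day-28 samples available for the shared test sets.
DEFAULT_N_PAIRS = 10


@dataclass
class ComparisonResult:
    """Per-constituent metric tables and paired comparison statistics."""

    tables: dict[str, pd.DataFrame]
    f1_tests: dict[str, TestResult]
    auc_tests: dict[str, TestResult]
    partitions: dict[str, PartitionSpec]

    def mean_difference(self, constituent: str, metric: str = "F1") -> float:
        t = self.tables[constituent]
        return float((t[f"{metric}_controlled"] - t[f"{metric}_uncontrolled"]).mean())

    def to_frame(self) -> pd.DataFrame:
        """Long summary table mirroring the study's controlled/uncontrolled layout."""
        out = []
        for constituent, t in self.tables.items():
            t = t.copy()
            t.insert(0, "constituent", constituent)
            out.append(t)
        return pd.concat(out, ignore_index=True)


def training_matrix(inv: Inventory, ids) -> tuple[np.ndarray, np.ndarray]:
    """Replicate-level training data: one row per technical replicate."""
    rows, labels = [], []
    for sid in ids:
        s = inv.sample(sid)
        for spec in s.replicates:
            rows.append(spec.intensities)
            labels.append(1 if s.day == 28 else 0)
    return np.stack(rows), np.array(labels)


def test_matrix(inv: Inventory, ids) -> tuple[np.ndarray, np.ndarray]:
    """Replicate-averaged test data: one row per sample."""
    rows, labels = [], []
    for sid in ids:
        s = inv.sample(sid)
        rows.append(average_replicates(s).intensities)
        labels.append(1 if s.day == 28 else 0)
    return np.stack(rows), np.array(labels)


def _evaluate(model, X_test, y_test) -> tuple[float, float]:
    pred = zoo.predict_labels(model, X_test)
    scores = zoo.predict_scores(model, X_test)
    cm = confusion_from_predictions(y_test == 1, pred == 1, positive_class_label="Day-28")
    f1 = f1_score(cm).value if (cm.tp + cm.fp + cm.fn) else float("nan")
    auc = auc_score(scores[y_test == 1], scores[y_test == 0]).value
    return f1, auc

def build_all_partitions(
    inv: Inventory,
    constituents=CONSTITUENTS,
    n_pairs: int | None = DEFAULT_N_PAIRS,
) -> dict[str, PartitionSpec]:
    """Propensity matching plus the per-constituent Workflow B partitions,
    without fitting any model."""
    scores = estimate_propensity(inv)
    non_controls = [s for s in inv.samples if not s.is_control]
    treated = [s.sample_id for s in non_controls if s.day == 28]
    day7 = [s.sample_id for s in non_controls if s.day == 7]
    match = match_nearest_neighbor(scores, treated, day7)
    return {c: build_partition(inv, c, match, n_pairs=n_pairs) for c in constituents}


def run_step1(
    inv: Inventory,
    constituents=CONSTITUENTS,
    algorithm_names=zoo.ALGORITHM_NAMES,
    seed: int = 0,
    n_pairs: int | None = DEFAULT_N_PAIRS,
    paired_test: bool = False,
) -> ComparisonResult:
    """Train and compare controlled vs uncontrolled maturity models.

    The single propensity-matched controlled set (capped at ``n_pairs``
    best-distance pairs) is shared across all constituent comparisons; only
    the uncontrolled arms and hence the test sets vary.  ``paired_test``
    switches the per-constituent comparison to the signed-rank variant
    (sensitivity analysis; default is the rank-sum test).  The rank-sum
    comparison needs >= 2 algorithms; with fewer, the test entries are None.
    """
    partitions = build_all_partitions(inv, constituents, n_pairs=n_pairs)
    tables: dict[str, pd.DataFrame] = {}
    f1_tests: dict[str, TestResult | None] = {}
    auc_tests: dict[str, TestResult | None] = {}
    compare = wilcoxon_signed_rank if paired_test else wilcoxon_rank_sum

    for ci, constituent in enumerate(constituents):
        part = partitions[constituent]
        X_unc, y_unc = training_matrix(inv, part.uncontrolled_train_ids)
        X_con, y_con = training_matrix(inv, part.controlled_train_ids)
        X_test, y_test = test_matrix(inv, part.test_ids)
        rows = []
        for ai, name in enumerate(algorithm_names):
            algo_seed = _seed_for(seed, ci, ai)
            m_con = zoo.fit(zoo.make_algorithm(name, seed=algo_seed), X_con, y_con)
            m_unc = zoo.fit(zoo.make_algorithm(name, seed=algo_seed), X_unc, y_unc)
            f1_c, auc_c = _evaluate(m_con, X_test, y_test)
            f1_u, auc_u = _evaluate(m_unc, X_test, y_test)
            rows.append(
                {
                    "algorithm": name,
                    "F1_controlled": f1_c,
                    "F1_uncontrolled": f1_u,
                    "AUC_controlled": auc_c,
                    "AUC_uncontrolled": auc_u,
                }
            )
        table = pd.DataFrame(rows)
        tables[constituent] = table
        if len(algorithm_names) >= 2:
            f1_tests[constituent] = compare(
                table["F1_controlled"].to_numpy(), table["F1_uncontrolled"].to_numpy()
            )
            auc_tests[constituent] = compare(
                table["AUC_controlled"].to_numpy(), table["AUC_uncontrolled"].to_numpy()
            )
        else:
            f1_tests[constituent] = auc_tests[constituent] = None
    return ComparisonResult(tables=tables, f1_tests=f1_tests,
                            auc_tests=auc_tests, partitions=partitions)


def _seed_for(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))
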