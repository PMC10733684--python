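"""Confounded and controlled training-set construction (Workflow B, step 1).

The uncontrolled design deliberately aliases a constituent with maturity:
its Day-28 training arm is every Day-28 sample *with* the constituent and
its Day-7 arm every Day-7 sample *without* it.  The controlled design
removes that alias by propensity-score matching: a logistic regression of
Day-28 membership on the four constituent flags yields a score per sample,
and Day-28 samples are greedily matched to unused Day-7 samples by nearest
logit distance (without replacement).  Control samples are excluded from
all of Workflow B; all replicates of a sample always share one membership
(the replicate trap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from .spectra import CONSTITUENTS, Inventory, SampleRecord

__all__ = [
    "PropensityScores",
    "MatchResult",
    "PartitionSpec",
    "build_uncontrolled_training",
    "estimate_propensity",
    "match_nearest_neighbor",
    "build_controlled_training",
    "build_test_set",
    "build_partition",
]

log = logging.getLogger(__name__)


class PartitionError(ValueError):
    pass


@dataclass(frozen=True)
class PropensityScores:
    """Modeled P(Day-28 | constituent flags) per non-control sample."""

    scores: dict[str, float]

    def __post_init__(self) -> None:
        for sid, e in self.scores.items():
            if not (0.0 < e < 1.0):
                raise PartitionError(f"propensity score for {sid!r} outside (0, 1): {e}")

    def __getitem__(self, sample_id: str) -> float:
        return self.scores[sample_id]

    def logit(self, sample_id: str) -> float:
        e = self.scores[sample_id]
        return float(np.log(e / (1.0 - e)))


@dataclass
class MatchResult:
    pairs: list[tuple[str, str]]  # (day28_id, day7_id)
    unmatched: list[str]
    distances: list[float]

    def __post_init__(self) -> None:
        used = [sid for pair in self.pairs for sid in pair]
        if len(set(used)) != len(used):
            raise PartitionError("a sample appears in more than one matched pair")


@dataclass
class PartitionSpec:
    constituent: str
    uncontrolled_train_ids: list[str]
    controlled_train_ids: list[str]
    test_ids: list[str]

    def __post_init__(self) -> None:
        train = set(self.uncontrolled_train_ids) | set(self.controlled_train_ids)
        overlap = train & set(self.test_ids)
        if overlap:
            raise PartitionError(f"test set overlaps training sets: {sorted(overlap)}")


def _non_controls(inv: Inventory) -> list[SampleRecord]:
    return [s for s in inv.samples if not s.is_control]


def build_uncontrolled_training(inv: Inventory, constituent: str) -> tuple[list[str], list[str]]:
    """Day-28 arm = Day-28 samples with the constituent; Day-7 arm = Day-7
    samples without it.  Controls excluded."""
    samples = _non_controls(inv)
    day28_arm = [s.sample_id for s in samples if s.day == 28 and s.flag(constituent)]
    day7_arm = [s.sample_id for s in samples if s.day == 7 and not s.flag(constituent)]
    if not day28_arm:
        raise PartitionError(f"no Day-28 sample carries {constituent!r}: empty arm")
    if not day7_arm:
        raise PartitionError(f"every Day-7 sample carries {constituent!r}: empty arm")
    return day28_arm, day7_arm


def estimate_propensity(inv: Inventory) -> PropensityScores:
    """Logistic regression of Day-28 membership on the four constituent flags.

    Constant flag columns are dropped (they are absorbed by the intercept).
    On perfect separation or non-convergence the fit falls back to a
    ridge-penalised logistic regression, with a log notice.
    """
    samples = _non_controls(inv)
    days = {s.day for s in samples}
    if days != {7, 28}:
        raise PartitionError("propensity model needs non-control samples on both days")
    X = np.array([[float(s.flag(c)) for c in CONSTITUENTS] for s in samples])
    y = np.array([1.0 if s.day == 28 else 0.0 for s in samples])
    informative = np.ptp(X, axis=0) > 0
    Xi = X[:, informative]
    design = sm.add_constant(Xi, has_constant="add")
    fitted = None
    try:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # separation warnings handled below
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        if res.mle_retvals.get("converged", False) and np.all(np.isfinite(res.params)) \
                and np.max(np.abs(res.params)) < 15:
            fitted = np.asarray(res.predict(design))
    except Exception:  # separation, singular Hessian
        fitted = None
    if fitted is None:
        log.info("propensity logistic regression unstable; using ridge-penalised fit")
        lr = LogisticRegression(C=1.0, max_iter=1000)
        lr.fit(Xi if Xi.shape[1] else np.zeros((len(y), 1)), y.astype(int))
        fitted = lr.predict_proba(Xi if Xi.shape[1] else np.zeros((len(y), 1)))[:, 1]
    eps = 1e-12
    fitted = np.clip(fitted, eps, 1 - eps)
    return PropensityScores({s.sample_id: float(e) for s, e in zip(samples, fitted)})


def match_nearest_neighbor(
    scores: PropensityScores,
    treated_ids,
    control_ids,
    max_distance: float | None = None,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching on the propensity logit,
    without replacement.

    Treated (Day-28) samples are visited in descending propensity order
    (ties by sample id); each takes the unused Day-7 sample with the smallest
    absolute logit difference.  With ``max_distance`` set, a treated sample
    whose best available match exceeds it goes unmatched.
    """
    treated_ids = list(treated_ids)
    control_ids = list(control_ids)
    if not treated_ids or not control_ids:
        raise PartitionError("matching requires non-empty treated and control groups")
    order = sorted(treated_ids, key=lambda sid: (-scores[sid], sid))
    available = sorted(control_ids)
    pairs, distances, unmatched = [], [], []
    for t in order:
        lt = scores.logit(t)
        if not available:
            unmatched.append(t)
            continue
        best = min(available, key=lambda c: (abs(scores.logit(c) - lt), c))
        d = abs(scores.logit(best) - lt)
        if max_distance is not None and d > max_distance:
            unmatched.append(t)
            continue
        pairs.append((t, best))
        distances.append(d)
        available.remove(best)
    return MatchResult(pairs=pairs, unmatched=unmatched, distances=distances)


def build_controlled_training(match: MatchResult, n_pairs: int | None = None) -> list[str]:
    """Training ids from matched pairs: both members of every retained pair.

    ``n_pairs`` caps the controlled set at the best-matched (smallest
    distance) pairs, which keeps Day-28 samples available for the shared
    test sets; by default all pairs are retained.  The result is exactly
    day-balanced by construction.
    """
    if not match.pairs:
        raise PartitionError("no matched pairs: cannot build controlled training set")
    pairs = match.pairs
    if n_pairs is not None and n_pairs < len(pairs):
        ranked = sorted(range(len(pairs)), key=lambda i: (match.distances[i], pairs[i]))
        pairs = [pairs[i] for i in sorted(ranked[:n_pairs])]
    return [sid for pair in pairs for sid in pair]


def build_test_set(
    inv: Inventory, constituent: str, uncontrolled_ids, controlled_ids
) -> list[str]:
    """All non-control samples in neither training set (replicates averaged
    at evaluation time)."""
    used = set(uncontrolled_ids) | set(controlled_ids)
    test = [s.sample_id for s in _non_controls(inv) if s.sample_id not in used]
    if not test:
        raise PartitionError(f"empty test set for constituent {constituent!r}")
    return test


def build_partition(
    inv: Inventory,
    constituent: str,
    match: MatchResult,
    n_pairs: int | None = None,
) -> PartitionSpec:
    """Assemble the full Workflow B partition for one constituent."""
    day28_arm, day7_arm = build_uncontrolled_training(inv, constituent)
    uncontrolled = day28_arm + day7_arm
    controlled = build_controlled_training(match, n_pairs=n_pairs)
    test = build_test_set(inv, constituent, uncontrolled, controlled)
    return PartitionSpec(
        constituent=constituent,
        uncontrolled_train_ids=uncontrolled,
        controlled_train_ids=controlled,
        test_ids=test,
    )
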