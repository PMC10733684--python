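"""Propensity scores, matching, and the Workflow B partitions."""

import numpy as np
import pytest

import nirconfound as nc
from nirconfound.partition import (
    MatchResult,
    PartitionError,
    PropensityScores,
    build_controlled_training,
    build_partition,
    build_test_set,
    build_uncontrolled_training,
    estimate_propensity,
    match_nearest_neighbor,
)
from nirconfound.spectra import CONSTITUENTS, Inventory, SampleRecord, default_grid

GRID = default_grid(16)


def metadata_inventory(samples):
    return Inventory(samples, GRID)


def flagged(sid, day, **flags):
    return SampleRecord(sid, day, **flags)


def random_confounded_roster(seed, n=60):
    """Roster whose flags are genuinely associated with incubation day."""
    rng = np.random.default_rng(seed)
    p7 = {"mper": 0.2, "hav": 0.3, "bmp9": 0.35, "tgfb1": 0.15}
    p28 = {"mper": 0.7, "hav": 0.75, "bmp9": 0.65, "tgfb1": 0.55}
    samples = []
    for i in range(n):
        day = 28 if rng.random() < 0.4 else 7
        p = p28 if day == 28 else p7
        bmp9 = rng.random() < p["bmp9"]
        tgfb1 = (not bmp9) and (rng.random() < p["tgfb1"])
        samples.append(flagged(
            f"S{i:02d}", day,
            mper=bool(rng.random() < p["mper"]),
            hav=bool(rng.random() < p["hav"]),
            bmp9=bool(bmp9), tgfb1=bool(tgfb1),
        ))
    if len({s.day for s in samples}) != 2:
        return random_confounded_roster(seed + 1000, n)
    return metadata_inventory(samples)


def prevalence_gap(samples_by_id, ids_a, ids_b, flag):
    pa = np.mean([samples_by_id[i].flag(flag) for i in ids_a])
    pb = np.mean([samples_by_id[i].flag(flag) for i in ids_b])
    return abs(pa - pb)


class TestUncontrolledArms:
    def test_arm_sizes_on_default_roster(self, default_dataset):
        expected = {"mper": (10, 30), "bmp9": (12, 19), "tgfb1": (7, 27), "hav": (16, 17)}
        for constituent, (n28, n7) in expected.items():
            d28, d7 = build_uncontrolled_training(default_dataset, constituent)
            assert (len(d28), len(d7)) == (n28, n7)

    def test_arms_respect_flag_and_day(self, default_dataset):
        d28, d7 = build_uncontrolled_training(default_dataset, "mper")
        for sid in d28:
            s = default_dataset.sample(sid)
            assert s.day == 28 and s.mper and not s.is_control
        for sid in d7:
            s = default_dataset.sample(sid)
            assert s.day == 7 and not s.mper and not s.is_control

    def test_empty_arm_is_an_error(self):
        inv = metadata_inventory([
            flagged("A", 28), flagged("B", 28), flagged("C", 7), flagged("D", 7)])
        with pytest.raises(PartitionError, match="mper"):
            build_uncontrolled_training(inv, "mper")


class TestPropensity:
    def test_identical_flags_give_prevalence(self):
        samples = [flagged(f"S{i}", 28 if i < 3 else 7, mper=True) for i in range(10)]
        scores = estimate_propensity(metadata_inventory(samples))
        for sid in scores.scores:
            assert scores[sid] == pytest.approx(0.3, abs=1e-6)

    def test_saturated_single_covariate_matches_cell_proportions(self):
        # day28: 3 of 4 flagged; day7: 1 of 4 flagged
        samples = (
            [flagged(f"T{i}", 28, mper=True) for i in range(3)]
            + [flagged("T3", 28)]
            + [flagged("C0", 7, mper=True)]
            + [flagged(f"C{i}", 7) for i in range(1, 4)]
        )
        scores = estimate_propensity(metadata_inventory(samples))
        # P(day28 | mper) = 3/4, P(day28 | !mper) = 1/4
        assert scores["T0"] == pytest.approx(0.75, abs=1e-6)
        assert scores["C1"] == pytest.approx(0.25, abs=1e-6)

    def test_constant_flag_leaves_scores_unchanged(self):
        def roster(hav_all):
            return metadata_inventory([
                flagged(f"S{i}", 28 if i % 3 == 0 else 7,
                        mper=bool(i % 2), hav=hav_all)
                for i in range(12)
            ])
        a = estimate_propensity(roster(False))
        b = estimate_propensity(roster(True))
        for sid in a.scores:
            assert a[sid] == pytest.approx(b[sid], abs=1e-8)

    def test_scores_bounded_open_interval(self, default_dataset):
        scores = estimate_propensity(default_dataset)
        non_controls = [s for s in default_dataset.samples if not s.is_control]
        assert set(scores.scores) == {s.sample_id for s in non_controls}
        assert all(0.0 < e < 1.0 for e in scores.scores.values())


class TestMatching:
    @staticmethod
    def scores_of(mapping):
        return PropensityScores(dict(mapping))

    def test_identical_scores_all_matched_at_zero_distance(self):
        sc = self.scores_of({f"T{i}": 0.5 for i in range(3)} |
                            {f"C{i}": 0.5 for i in range(5)})
        m = match_nearest_neighbor(sc, [f"T{i}" for i in range(3)],
                                   [f"C{i}" for i in range(5)])
        assert len(m.pairs) == 3 and not m.unmatched
        assert all(d == 0.0 for d in m.distances)

    def test_greedy_descending_order_outcome(self):
        sc = self.scores_of({"T_hi": 0.8, "T_lo": 0.6,
                             "C_a": 0.75, "C_b": 0.5, "C_c": 0.2})
        m = match_nearest_neighbor(sc, ["T_lo", "T_hi"], ["C_a", "C_b", "C_c"])
        assert m.pairs == [("T_hi", "C_a"), ("T_lo", "C_b")]

    def test_surplus_treated_left_unmatched(self):
        sc = self.scores_of({f"T{i}": 0.4 + 0.01 * i for i in range(5)} |
                            {f"C{i}": 0.4 + 0.01 * i for i in range(3)})
        m = match_nearest_neighbor(sc, [f"T{i}" for i in range(5)],
                                   [f"C{i}" for i in range(3)])
        assert len(m.pairs) == 3 and len(m.unmatched) == 2

    def test_caliper_excludes_distant_pairs(self):
        sc = self.scores_of({"T0": 0.9, "T1": 0.5, "C0": 0.52, "C1": 0.1})
        m = match_nearest_neighbor(sc, ["T0", "T1"], ["C0", "C1"],
                                   max_distance=0.5)
        assert ("T1", "C0") in m.pairs and "T0" in m.unmatched

    def test_without_replacement_across_pairs(self):
        for seed in range(5):
            inv = random_confounded_roster(seed)
            sc = estimate_propensity(inv)
            treated = [s.sample_id for s in inv.samples if s.day == 28]
            ctrl = [s.sample_id for s in inv.samples if s.day == 7]
            m = match_nearest_neighbor(sc, treated, ctrl)
            used = [sid for pair in m.pairs for sid in pair]
            assert len(set(used)) == len(used)
            assert len(m.pairs) == min(len(treated), len(ctrl))
            assert set(t for t, _ in m.pairs) | set(m.unmatched) == set(treated)

    def test_matching_reduces_mean_covariate_imbalance(self):
        """Across 20 random confounded rosters, matching shrinks the mean
        Day-28 vs Day-7 prevalence gap of every constituent flag."""
        pre_gap = np.zeros(len(CONSTITUENTS))
        post_gap = np.zeros(len(CONSTITUENTS))
        for seed in range(20):
            inv = random_confounded_roster(seed)
            by_id = {s.sample_id: s for s in inv.samples}
            sc = estimate_propensity(inv)
            treated = [s.sample_id for s in inv.samples if s.day == 28]
            ctrl = [s.sample_id for s in inv.samples if s.day == 7]
            m = match_nearest_neighbor(sc, treated, ctrl)
            m28 = [t for t, _ in m.pairs]
            m7 = [c for _, c in m.pairs]
            for j, flag in enumerate(CONSTITUENTS):
                pre_gap[j] += prevalence_gap(by_id, treated, ctrl, flag)
                post_gap[j] += prevalence_gap(by_id, m28, m7, flag)
        assert np.all(post_gap < pre_gap)


class TestControlledAndTestSets:
    def make_match(self, n_pairs):
        pairs = [(f"T{i}", f"C{i}") for i in range(n_pairs)]
        return MatchResult(pairs=pairs, unmatched=[],
                           distances=[0.01 * i for i in range(n_pairs)])

    def test_ten_pairs_give_twenty_balanced_ids(self):
        ids = build_controlled_training(self.make_match(10))
        assert len(ids) == 20 and len(set(ids)) == 20
        assert sum(1 for i in ids if i.startswith("T")) == 10

    def test_single_pair(self):
        assert len(build_controlled_training(self.make_match(1))) == 2

    def test_cap_keeps_best_distance_pairs(self):
        m = self.make_match(5)
        ids = build_controlled_training(m, n_pairs=2)
        assert set(ids) == {"T0", "C0", "T1", "C1"}

    def test_zero_pairs_rejected(self):
        with pytest.raises(PartitionError, match="no matched pairs"):
            build_controlled_training(MatchResult([], [], []))

    def test_test_set_is_complement_of_union(self):
        samples = [flagged(f"S{i}", 7 if i < 6 else 28,
                           mper=bool(i % 2)) for i in range(10)]
        inv = metadata_inventory(samples)
        test = build_test_set(inv, "mper", ["S0", "S1", "S2"], ["S2", "S3", "S4", "S5"])
        assert sorted(test) == [f"S{i}" for i in range(6, 10)]

    def test_partitions_disjoint_on_default_roster(self, default_dataset):
        scores = estimate_propensity(default_dataset)
        non_controls = [s for s in default_dataset.samples if not s.is_control]
        treated = [s.sample_id for s in non_controls if s.day == 28]
        ctrl = [s.sample_id for s in non_controls if s.day == 7]
        match = match_nearest_neighbor(scores, treated, ctrl)
        control_ids = {s.sample_id for s in default_dataset.samples if s.is_control}
        for constituent in CONSTITUENTS:
            part = build_partition(default_dataset, constituent, match, n_pairs=10)
            train = set(part.uncontrolled_train_ids) | set(part.controlled_train_ids)
            assert not train & set(part.test_ids)
            assert not control_ids & (train | set(part.test_ids))
            # both maturity classes survive in the test set
            days = {default_dataset.sample(sid).day for sid in part.test_ids}
            assert days == {7, 28}
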