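"""Split plans, the metric suite (against brute-force oracles), scrambling."""

import numpy as np
import pytest

from pcmbench.datasets import ActivityRecord, PCMDataset, TargetEntry
from pcmbench.encoding import DescriptorSetSpec
from pcmbench.model import ModelConfig
from pcmbench.simulate import make_dipeptide_set, make_mutant_panel
from pcmbench.tables import load_descriptor_table
from pcmbench.validation import (confusion_and_mcc, make_70_30_plan,
                                 make_leave_fraction_targets_plan,
                                 make_loso_plan, q_squared_oob, r0_squared,
                                 rmse, run_protocol, y_scramble)
from conftest import grid_dataset


# ---------------------------------------------------------------------------
# brute-force metric oracles (independent of the implementation)


def oracle_rmse(y, p):
    return (sum((a - b) ** 2 for a, b in zip(y, p)) / len(y)) ** 0.5


def oracle_r0(y, p):
    k = sum(a * b for a, b in zip(y, p)) / sum(b * b for b in p)
    ybar = sum(y) / len(y)
    return 1 - sum((a - k * b) ** 2 for a, b in zip(y, p)) / \
        sum((a - ybar) ** 2 for a in y)


def oracle_q2(y, p):
    ybar = sum(y) / len(y)
    return 1 - sum((a - b) ** 2 for a, b in zip(y, p)) / \
        sum((a - ybar) ** 2 for a in y)


def oracle_mcc_sens(obs, pred):
    tp = sum(o == "active" and p == "active" for o, p in zip(obs, pred))
    tn = sum(o == "inactive" and p == "inactive" for o, p in zip(obs, pred))
    fp = sum(o == "inactive" and p == "active" for o, p in zip(obs, pred))
    fn = sum(o == "active" and p == "inactive" for o, p in zip(obs, pred))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom ** 0.5
    sens = tp / (tp + fn) if tp + fn else float("nan")
    return mcc, sens


class TestMetricOracles:
    def test_regression_metrics_match_oracles(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(3, 40))
            y = rng.normal(size=n)
            p = y + rng.normal(scale=rng.uniform(0.01, 2.0), size=n)
            assert rmse(y, p) == pytest.approx(oracle_rmse(y, p), abs=1e-12)
            assert r0_squared(y, p) == pytest.approx(oracle_r0(y, p), abs=1e-12)
            assert q_squared_oob(y, p) == pytest.approx(oracle_q2(y, p), abs=1e-12)

    def test_mcc_matches_oracle_and_sklearn(self):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(4, 60))
            obs = rng.choice(["active", "inactive"], size=n).tolist()
            pred = rng.choice(["active", "inactive"], size=n).tolist()
            got = confusion_and_mcc(obs, pred)
            mcc, sens = oracle_mcc_sens(obs, pred)
            assert got["mcc"] == pytest.approx(mcc, abs=1e-12)
            if len(set(obs)) == 2 and len(set(pred)) == 2:
                assert got["mcc"] == pytest.approx(
                    matthews_corrcoef(obs, pred), abs=1e-9)

    def test_hand_computed_cases(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse([0.0, 0.0], [1.0, -1.0]) == 1.0
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert r0_squared(y, y) == pytest.approx(1.0)
        assert q_squared_oob(y, y) == pytest.approx(1.0)
        assert q_squared_oob(y, np.full(4, y.mean())) == pytest.approx(0.0)
        assert q_squared_oob(y, y[::-1]) < 0  # worse than the null model

    def test_r0_punishes_offsets(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=50)
        p = y + 1.0  # perfectly ranked, constant offset
        pearson2 = np.corrcoef(y, p)[0, 1] ** 2
        assert pearson2 == pytest.approx(1.0)
        assert r0_squared(y, p) < pearson2 - 0.2

    def test_r0_orientation_flag(self):
        # a scaled-and-offset prediction separates the two orientations
        rng = np.random.default_rng(3)
        y = rng.normal(size=30)
        p = 0.5 * y + 2.0
        default = r0_squared(y, p)
        other = r0_squared(y, p, regress_predicted_on_observed=True)
        assert abs(default - other) > 1.0

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="constant"):
            r0_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="equal-length"):
            rmse([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="unknown class"):
            confusion_and_mcc(["active"], ["maybe"])

    def test_mcc_zero_convention_and_inversion(self):
        got = confusion_and_mcc(["active", "inactive"] * 5, ["active"] * 10)
        assert got["mcc"] == 0.0 and got["sensitivity"] == 1.0
        perfect = confusion_and_mcc(["active", "inactive"], ["active", "inactive"])
        assert perfect["mcc"] == 1.0 and perfect["sensitivity"] == 1.0
        inverted = confusion_and_mcc(["active", "inactive"], ["inactive", "active"])
        assert inverted["mcc"] == -1.0


class TestSplitPlans:
    def test_70_30_sizes_and_partition(self):
        ds = grid_dataset(10, 10, 100)
        plan = make_70_30_plan(ds, seed=0, n_repeats=10)
        assert len(plan.folds) == 10
        for train, test in plan.folds:
            assert len(test) == 30
            assert sorted(train + test) == list(range(100))

    def test_70_30_repeats_differ(self):
        ds = grid_dataset(10, 10, 100)
        plan = make_70_30_plan(ds, seed=1, n_repeats=10)
        tests = {frozenset(test) for _, test in plan.folds}
        assert len(tests) == 10

    def test_rounding_half_up(self):
        ds = grid_dataset(5, 3, 15)  # 30% of 15 = 4.5 -> 5
        plan = make_70_30_plan(ds, seed=0, n_repeats=1)
        assert len(plan.folds[0][1]) == 5

    def test_loso_one_fold_per_target(self):
        ds = make_mutant_panel(n_targets=14, n_compounds=12, sequence_length=20,
                               n_mutated_positions=8, max_mutations=4,
                               completeness=0.9, seed=0, n_fingerprint_bits=16)
        plan = make_loso_plan(ds)
        assert len(plan.folds) == 14
        tested = [i for _, test in plan.folds for i in test]
        assert sorted(tested) == list(range(len(ds.activities)))
        for (train, test) in plan.folds:
            test_targets = {ds.activities[i].target_id for i in test}
            train_targets = {ds.activities[i].target_id for i in train}
            assert len(test_targets) == 1
            assert not test_targets & train_targets

    def test_leave_fraction_partitions(self):
        ds = grid_dataset(2, 20, 40)
        plan = make_leave_fraction_targets_plan(ds, fraction=0.25, seed=0)
        assert len(plan.folds) == 4
        sizes = [len({ds.activities[i].target_id for i in test})
                 for _, test in plan.folds]
        assert sizes == [5, 5, 5, 5]

    def test_pi_scale_fold_sizes(self):
        ds = grid_dataset(1, 1060, 1060, residue_len=2)
        plan = make_leave_fraction_targets_plan(ds, fraction=0.1, seed=0)
        assert len(plan.folds) == 10
        group_sizes = [len({ds.activities[i].target_id for i in test})
                       for _, test in plan.folds]
        assert group_sizes == [106] * 10

    def test_plan_preconditions(self):
        ds = grid_dataset(2, 2, 4)
        with pytest.raises(ValueError, match="at least 10"):
            make_70_30_plan(ds)
        with pytest.raises(ValueError, match="fraction"):
            make_leave_fraction_targets_plan(grid_dataset(2, 20, 40), fraction=0.6)

    def test_random_configurations_never_leak(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_targets = int(rng.integers(4, 12))
            n_compounds = int(rng.integers(4, 12))
            n_records = int(rng.integers(max(10, n_targets),
                                         n_targets * n_compounds + 1))
            ds = grid_dataset(n_compounds, n_targets, n_records)
            by_target = {}
            for i, rec in enumerate(ds.activities):
                by_target.setdefault(rec.target_id, []).append(i)
            plans = [make_70_30_plan(ds, seed=int(rng.integers(1 << 30)),
                                     n_repeats=2)]
            if all(by_target.get(t.target_id) for t in ds.targets):
                plans.append(make_loso_plan(ds))
            if n_targets >= 4:
                plans.append(make_leave_fraction_targets_plan(
                    ds, fraction=0.25, seed=int(rng.integers(1 << 30))))
            for plan in plans:
                for train, test in plan.folds:
                    assert not set(train) & set(test)
                    assert set(train) | set(test) <= set(range(n_records))
                    if plan.protocol != "seventy_thirty":
                        test_targets = {ds.activities[i].target_id for i in test}
                        train_targets = {ds.activities[i].target_id for i in train}
                        assert not test_targets & train_targets
                if plan.protocol != "seventy_thirty":
                    tested = sorted(i for _, test in plan.folds for i in test)
                    assert tested == list(range(n_records))


class TestYScramble:
    def test_response_multiset_preserved(self):
        ds = make_dipeptide_set(n_peptides=30, seed=0)
        scrambled = y_scramble(ds, seed=1)
        before = sorted(r.value for r in ds.activities)
        after = sorted(r.value for r in scrambled.activities)
        assert before == after
        assert np.mean(before) == pytest.approx(np.mean(after))
        pairs_before = [(r.compound_id, r.target_id) for r in ds.activities]
        pairs_after = [(r.compound_id, r.target_id) for r in scrambled.activities]
        assert pairs_before == pairs_after
        assert any(a.value != b.value
                   for a, b in zip(ds.activities, scrambled.activities))


class TestRunProtocol:
    def test_report_shape_and_per_target_rows(self):
        ds = make_mutant_panel(n_targets=5, n_compounds=15, sequence_length=15,
                               n_mutated_positions=6, max_mutations=3,
                               completeness=0.9, seed=1, n_fingerprint_bits=16)
        spec = DescriptorSetSpec(base_tables=(load_descriptor_table("zscales3"),))
        config = ModelConfig.for_dataset(ds, seed=0, n_trees=40)
        plan = make_70_30_plan(ds, seed=0, n_repeats=3)
        report = run_protocol(ds, spec, None, config, plan)
        assert len(report.per_fold) == 3
        for fold in report.per_fold:
            assert {"rmse", "r0_squared", "q_squared"} <= set(fold)
        tested_targets = {ds.activities[i].target_id
                          for _, test in plan.folds for i in test}
        assert set(report.per_target) == tested_targets
        frame = report.to_frame()
        assert {"dataset", "descriptor", "protocol", "target"} <= set(frame.columns)

    def test_single_class_folds_counted_as_failed(self):
        targets = [TargetEntry("tA", "AC"), TargetEntry("tB", "CA")]
        compounds = [(f"c{i}", "bits:0101") for i in range(12)]
        activities = (
            [ActivityRecord(f"c{i}", "tA", class_label="active") for i in range(6)]
            + [ActivityRecord(f"c{i}", "tB", class_label="inactive")
               for i in range(6, 12)])
        ds = PCMDataset(name="degenerate", task="classification",
                        compounds=compounds, targets=targets,
                        activities=activities)
        spec = DescriptorSetSpec(base_tables=(load_descriptor_table("zscales3"),))
        config = ModelConfig.for_dataset(ds, seed=0, n_trees=10)
        plan = make_loso_plan(ds)
        with pytest.warns(UserWarning, match="excluded"):
            report = run_protocol(ds, spec, None, config, plan)
        assert report.failed_folds == 2
        assert report.per_fold == []
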