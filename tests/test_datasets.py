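"""Dataset model: binding sites, summary arithmetic, distances, bundle IO."""

import numpy as np
import pytest

from pcmbench.datasets import (ActivityRecord, PCMDataset, TargetEntry,
                               avg_euclidean_distance, avg_tanimoto_distance,
                               classify_activity, completeness,
                               extract_binding_site, read_dataset,
                               variable_positions, write_dataset)
from pcmbench.tables import load_descriptor_table
from conftest import grid_dataset, toy_table


class TestBindingSiteExtraction:
    def test_drop_any_gap_rule(self):
        aln = [("s1", "ACD"), ("s2", "A-D")]
        entries, dropped = extract_binding_site(aln, [1, 2, 3])
        assert dropped == [2]
        assert [e.residue_string for e in entries] == ["AD", "AD"]

    def test_gap_free_identity(self):
        aln = [("s1", "ACDEF"), ("s2", "GHIKL")]
        entries, dropped = extract_binding_site(aln, [2, 4])
        assert dropped == []
        assert [e.residue_string for e in entries] == ["CE", "HK"]

    def test_errors(self):
        with pytest.raises(ValueError, match="out of range"):
            extract_binding_site([("s1", "ACD")], [4])
        with pytest.raises(ValueError, match="gapped"):
            extract_binding_site([("s1", "A-D"), ("s2", "A-D")], [2])
        with pytest.raises(ValueError, match="ragged"):
            extract_binding_site([("s1", "ACD"), ("s2", "AC")], [1])

    def test_equal_output_lengths(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(5):
            seq = list("ACDEFGHIKL")
            for j in rng.integers(0, 10, size=2):
                seq[j] = "-"
            rows.append((f"s{i}", "".join(seq)))
        entries, dropped = extract_binding_site(rows, range(1, 11))
        lengths = {len(e.residue_string) for e in entries}
        assert len(lengths) == 1
        assert lengths.pop() == 10 - len(dropped)


class TestVariablePositions:
    def test_identical_sequences_empty(self):
        assert variable_positions(["ACD", "ACD"]) == []

    def test_brute_force_example(self):
        assert variable_positions(["ACD", "AFD", "ACE"]) == [2, 3]

    def test_ragged_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            variable_positions(["ACD", "AC"])


class TestCompleteness:
    def test_nnrti_shape(self):
        ds = grid_dataset(451, 14, 4024)
        result = completeness(ds)
        assert result["rounded_2dp"] == 0.64
        assert result["raw"] == pytest.approx(4024 / 6314)

    def test_pi_shape(self):
        ds = grid_dataset(9, 1060, 6995)
        assert completeness(ds)["percent"] == 73

    def test_gpcr_shape(self):
        ds = grid_dataset(3230, 32, 6046)
        assert completeness(ds)["rounded_2dp"] == 0.06

    def test_full_matrix(self):
        ds = grid_dataset(4, 3, 12)
        assert completeness(ds)["raw"] == 1.0


class TestTargetDistances:
    def test_identical_targets_zero(self):
        ts = [TargetEntry("a", "ACDE"), TargetEntry("b", "ACDE")]
        assert avg_tanimoto_distance(ts) == 0.0
        assert avg_euclidean_distance(ts, load_descriptor_table("zscales3")) == 0.0

    def test_disjoint_targets_one(self):
        ts = [TargetEntry("a", "ACDE"), TargetEntry("b", "GHIK")]
        assert avg_tanimoto_distance(ts) == pytest.approx(1.0)

    def test_tanimoto_matches_pairwise_oracle(self):
        seqs = ["ACDE", "ACDF", "GCDE"]

        def set_tanimoto_distance(s1, s2):
            a = {(i, c) for i, c in enumerate(s1)}
            b = {(i, c) for i, c in enumerate(s2)}
            return 1 - len(a & b) / len(a | b)

        expected = np.mean([set_tanimoto_distance(seqs[i], seqs[j])
                            for i in range(3) for j in range(i + 1, 3)])
        ts = [TargetEntry(f"t{i}", s) for i, s in enumerate(seqs)]
        assert avg_tanimoto_distance(ts) == pytest.approx(expected)

    def test_euclidean_hand_case_and_symmetry(self):
        table = toy_table({"A": 0.0, "C": 3.0}, fill=1.0)
        ts = [TargetEntry("a", "A"), TargetEntry("b", "C")]
        assert avg_euclidean_distance(ts, table) == pytest.approx(3.0)
        three = [TargetEntry("a", "AC"), TargetEntry("b", "CA"),
                 TargetEntry("c", "AA")]
        d1 = avg_euclidean_distance(three, table)
        d2 = avg_euclidean_distance(list(reversed(three)), table)
        assert d1 == pytest.approx(d2)

    def test_ragged_lengths_rejected(self):
        ts = [TargetEntry("a", "AC"), TargetEntry("b", "ACD")]
        with pytest.raises(ValueError, match="length"):
            avg_tanimoto_distance(ts)


class TestDatasetInvariants:
    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PCMDataset(name="x", task="regression",
                       compounds=[("c1", "CCO")],
                       targets=[TargetEntry("t1", "AC")],
                       activities=[ActivityRecord("c1", "t1", value=5.0),
                                   ActivityRecord("c1", "t1", value=6.0)])

    def test_median_merge_mode(self):
        ds = PCMDataset(name="x", task="regression",
                        compounds=[("c1", "CCO")],
                        targets=[TargetEntry("t1", "AC")],
                        activities=[ActivityRecord("c1", "t1", value=5.0)])
        ds.activities.append(ActivityRecord("c1", "t1", value=7.0))
        merged = ds.merge_duplicates()
        assert len(merged.activities) == 1
        assert merged.activities[0].value == 6.0

    def test_unknown_reference_rejected(self):
        with pytest.raises(ValueError, match="unknown target"):
            PCMDataset(name="x", task="regression",
                       compounds=[("c1", "CCO")],
                       targets=[TargetEntry("t1", "AC")],
                       activities=[ActivityRecord("c1", "t9", value=5.0)])

    def test_task_response_consistency(self):
        with pytest.raises(ValueError, match="class-labelled"):
            PCMDataset(name="x", task="regression",
                       compounds=[("c1", "CCO")],
                       targets=[TargetEntry("t1", "AC")],
                       activities=[ActivityRecord("c1", "t1",
                                                  class_label="active")])
        with pytest.raises(ValueError, match="exactly one"):
            ActivityRecord("c", "t", value=5.0, class_label="active")

    def test_ragged_target_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            PCMDataset(name="x", task="regression",
                       targets=[TargetEntry("t1", "AC"),
                                TargetEntry("t2", "ACD")])


def test_activity_classification_rule():
    assert classify_activity(7.1) == "active"
    assert classify_activity(7.0) == "inactive"  # pKi <= 7 is inactive
    assert classify_activity(8.0, threshold=8.5) == "inactive"


def test_bundle_round_trip(tmp_path):
    from pcmbench.simulate import make_mutant_panel

    ds = make_mutant_panel(n_targets=4, n_compounds=6, sequence_length=12,
                           n_mutated_positions=5, max_mutations=3,
                           completeness=0.9, seed=5, n_fingerprint_bits=16)
    write_dataset(ds, tmp_path / "bundle")
    back = read_dataset(tmp_path / "bundle")
    assert back.name == ds.name and back.task == ds.task
    assert [(t.target_id, t.residue_string) for t in back.targets] == \
        [(t.target_id, t.residue_string) for t in ds.targets]
    assert back.compounds == ds.compounds
    assert [(r.compound_id, r.target_id, r.value) for r in back.activities] == \
        [(r.compound_id, r.target_id, r.value) for r in ds.activities]


def test_classification_bundle_round_trip(tmp_path):
    from pcmbench.simulate import make_gpcr_classification_set

    ds = make_gpcr_classification_set(n_targets=3, n_families=3, n_actives=4,
                                      n_inactives=2, n_presumed_inactives=1,
                                      sequence_length=8, n_fingerprint_bits=16,
                                      seed=2)
    write_dataset(ds, tmp_path / "bundle")
    back = read_dataset(tmp_path / "bundle")
    assert [(r.compound_id, r.class_label) for r in back.activities] == \
        [(r.compound_id, r.class_label) for r in ds.activities]
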