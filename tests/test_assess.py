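"""Architecture comparison, conserved residues, misannotation
classification, identity matrices and snapshot diffs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecaudit.assess import (
    ResidueSpec,
    architecture_identity_matrix,
    canonical_architectures,
    classify,
    conserved_residues,
    identity_histogram,
    same_architecture,
    version_diff,
)
from ecaudit.records import AnnotationSnapshot, SequenceRecord
from ecaudit.simulate import mutate_to_identity, random_sequence

architectures = st.lists(
    st.sampled_from(["FMN_dh", "DAO", "Fer2_BFD", "CCG"]), max_size=4
).map(tuple)


class TestSameArchitecture:
    def test_equal_single_domain(self):
        assert same_architecture(("FMN_dh",), ("FMN_dh",))

    def test_order_disregarded(self):
        assert same_architecture(("DAO", "Fer2_BFD"), ("Fer2_BFD", "DAO"))

    def test_copy_number_respected(self):
        assert not same_architecture(("DAO",), ("DAO", "DAO"))

    @settings(derandomize=True, max_examples=60)
    @given(architectures, architectures, architectures)
    def test_equivalence_relation(self, a, b, c):
        assert same_architecture(a, a)
        assert same_architecture(a, b) == same_architecture(b, a)
        if same_architecture(a, b) and same_architecture(b, c):
            assert same_architecture(a, c)


class TestCanonicalArchitectures:
    def test_single_shared_architecture(self):
        records = [
            SequenceRecord(id=f"C{i}", sequence="MKVAL", characterised=True,
                           architecture=("FMN_dh",))
            for i in range(3)
        ]
        assert canonical_architectures(records) == [("FMN_dh",)]

    def test_distinct_architectures_both_kept(self):
        records = [
            SequenceRecord(id="A", sequence="MKVAL", architecture=("FMN_dh",)),
            SequenceRecord(id="B", sequence="MKVAM",
                           architecture=("FMN_dh", "Cyt_B5")),
        ]
        assert len(canonical_architectures(records)) == 2

    def test_no_known_architecture_is_an_error(self):
        records = [SequenceRecord(id="A", sequence="MKVAL")]
        with pytest.raises(ValueError, match="no canonical reference"):
            canonical_architectures(records)


class TestConservedResidues:
    REF = "MKVALWQENPDTSGHIRFCYMKVALWQENPDTSGHIRFCY"
    SPEC = ResidueSpec(reference_id="REF", positions=(3, 10, 25), expected=("V", "P", "L"))

    def test_reference_against_itself_fully_conserved(self):
        query = SequenceRecord(id="Q", sequence=self.REF)
        status, fraction = conserved_residues(query, self.SPEC, self.REF)
        assert fraction == 1.0 and all(status.values())

    def test_single_mutation_drops_one_position(self):
        mutated = self.REF[:9] + "G" + self.REF[10:]  # position 10: P -> G
        query = SequenceRecord(id="Q", sequence=mutated)
        status, fraction = conserved_residues(query, self.SPEC, self.REF)
        assert status == {3: True, 10: False, 25: True}
        assert fraction == pytest.approx(2 / 3)

    def test_deletion_spanning_position_scores_false(self):
        deleted = self.REF[:22] + self.REF[28:]  # removes positions 23-28
        query = SequenceRecord(id="Q", sequence=deleted)
        status, _ = conserved_residues(query, self.SPEC, self.REF)
        assert status[25] is False
        assert status[3] is True

    def test_spec_inconsistent_with_reference_rejected(self):
        bad = ResidueSpec(reference_id="REF", positions=(1,), expected=("W",))
        query = SequenceRecord(id="Q", sequence=self.REF)
        with pytest.raises(ValueError, match="spec expects"):
            conserved_residues(query, bad, self.REF)


class TestClassify:
    def test_planted_fractions_recovered(self, ec_class_42):
        """60 canonical + 40 outliers with distinct architectures and
        sub-30% roots: both headline fractions must equal 0.400 exactly."""
        snapshot, truth = ec_class_42
        records = snapshot.records
        characterised = {r.id for r in records if r.characterised}
        report = classify(records, characterised)
        summary = report.class_summary
        assert summary["fraction_non_canonical"] == pytest.approx(0.400)
        assert summary["fraction_below_threshold"] == pytest.approx(0.400)
        for acc, entry in report.per_record.items():
            assert entry["below_threshold"] == truth[acc]["is_misannotated"]

    def test_all_characterised_self_match(self):
        records = [
            SequenceRecord(
                id=f"C{i}",
                sequence=random_sequence(60, np.random.default_rng(i)),
                characterised=True,
                architecture=("FMN_dh",),
            )
            for i in range(4)
        ]
        report = classify(records, {r.id for r in records})
        assert report.class_summary["fraction_below_threshold"] == 0.0
        for entry in report.per_record.values():
            assert entry["max_identity_pct"] == 100.0

    def test_threshold_is_strict_less_than(self):
        # a record whose identity equals the threshold is NOT below it
        rng = np.random.default_rng(0)
        seq = random_sequence(100, rng)
        records = [
            SequenceRecord(id="C", sequence=seq, characterised=True,
                           architecture=("FMN_dh",)),
            SequenceRecord(id="Q", sequence=mutate_to_identity(seq, 0.25, 0.0, rng),
                           architecture=("FMN_dh",)),
        ]
        identity = classify(records, {"C"}).per_record["Q"]["max_identity_pct"]
        at_threshold = classify(records, {"C"}, threshold_pct=identity)
        assert at_threshold.per_record["Q"]["below_threshold"] is False
        above = classify(records, {"C"}, threshold_pct=identity + 0.01)
        assert above.per_record["Q"]["below_threshold"] is True

    def test_histogram_counts_sum_per_superkingdom(self, ec_class_42):
        snapshot, _ = ec_class_42
        records = snapshot.records
        report = classify(records, {r.id for r in records if r.characterised})
        histograms = report.class_summary["per_superkingdom_histograms"]
        for kingdom, bins in histograms.items():
            expected = sum(1 for r in records if r.superkingdom == kingdom)
            assert sum(bins) == expected

    def test_monotone_in_threshold(self, ec_class_42):
        snapshot, _ = ec_class_42
        records = snapshot.records[:30]
        characterised = {r.id for r in records if r.characterised}
        fractions = [
            classify(records, characterised, threshold_pct=t).class_summary[
                "fraction_below_threshold"
            ]
            for t in (10.0, 25.0, 60.0, 101.0)
        ]
        assert fractions == sorted(fractions)

    def test_histogram_bins(self):
        bins = identity_histogram([0.0, 0.5, 25.0, 99.9, 100.0])
        assert bins[0] == 2 and bins[25] == 1 and bins[99] == 1 and bins[100] == 1
        assert sum(bins) == 5


class TestArchitectureIdentityMatrix:
    def test_within_high_between_low(self):
        rng = np.random.default_rng(1)
        a = random_sequence(150, rng)
        b = random_sequence(150, rng)
        records = [
            SequenceRecord(id="A1", sequence=a),
            SequenceRecord(id="A2", sequence=a),
            SequenceRecord(id="B1", sequence=b),
            SequenceRecord(id="B2", sequence=b),
        ]
        matrix = architecture_identity_matrix(
            records, {"fam_a": ["A1", "A2"], "fam_b": ["B1", "B2"]}
        )
        assert matrix[("fam_a", "fam_a")] == pytest.approx(100.0)
        assert matrix[("fam_a", "fam_b")] < 25.0
        assert matrix[("fam_a", "fam_b")] == matrix[("fam_b", "fam_a")]

    def test_known_pairwise_value(self):
        from ecaudit.pairwise import align_identity

        rng = np.random.default_rng(2)
        a = random_sequence(120, rng)
        b = mutate_to_identity(a, 0.8, 0.0, rng)
        records = [SequenceRecord(id="A", sequence=a), SequenceRecord(id="B", sequence=b)]
        matrix = architecture_identity_matrix(records, {"g": ["A", "B"]})
        assert matrix[("g", "g")] == pytest.approx(align_identity(a, b))

    def test_singleton_group_within_mean_is_none(self):
        records = [SequenceRecord(id="A", sequence="MKVALMKVAL")]
        matrix = architecture_identity_matrix(records, {"g": ["A"]})
        assert matrix[("g", "g")] is None

    def test_unknown_member_rejected(self):
        records = [SequenceRecord(id="A", sequence="MKVALMKVAL")]
        with pytest.raises(ValueError, match="unknown ids"):
            architecture_identity_matrix(records, {"g": ["A", "ghost"]})


class TestVersionDiff:
    def snap(self, label, archs):
        records = [
            SequenceRecord(id=f"{label}{i}", sequence=f"MKVAL{'A' * i}",
                           architecture=arch)
            for i, arch in enumerate(archs)
        ]
        return AnnotationSnapshot(version_label=label, records=records)

    def test_identical_snapshots_have_zero_deltas(self):
        a = self.snap("a", [("FMN_dh",), ("DAO",)])
        b = self.snap("b", [("FMN_dh",), ("DAO",)])
        diff = version_diff(a, b)
        assert all(d == 0 for _, _, d in diff.counts.values())

    def test_added_records_counted_positive(self):
        a = self.snap("a", [("FMN_dh",)])
        b = self.snap("b", [("FMN_dh",)] + [("DAO",)] * 5)
        diff = version_diff(a, b)
        assert diff.counts["DAO"] == (0, 5, 5)

    def test_removed_record_counted_negative(self):
        a = self.snap("a", [("FMN_dh",), ("DAO",)])
        b = self.snap("b", [("FMN_dh",)])
        diff = version_diff(a, b)
        assert diff.counts["DAO"] == (1, 0, -1)

    def test_counts_sum_to_totals_and_unknown_label(self):
        a = self.snap("a", [("FMN_dh",), ()])
        b = self.snap("b", [("DAO", "Fer2_BFD"), ("Fer2_BFD", "DAO")])
        diff = version_diff(a, b)
        assert sum(c[0] for c in diff.counts.values()) == diff.totals[0]
        assert sum(c[1] for c in diff.counts.values()) == diff.totals[1]
        assert diff.counts["unknown"][0] == 1
        # order-free architecture key merges the two equal multisets
        assert diff.counts["DAO+Fer2_BFD"][1] == 2
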