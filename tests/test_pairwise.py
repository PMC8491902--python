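"""k-tuple profiles, NGD prefilter, global alignment and identity search."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecaudit.pairwise import (
    AlignParams,
    align_identity,
    closest_characterised,
    corpus_distinct,
    global_align,
    google_distance,
    kmer_profile,
    percent_identity,
    rank_agreement,
)
from ecaudit.records import SequenceRecord
from ecaudit.simulate import mutate_to_identity, random_sequence

from conftest import brute_force_align_score


class TestKmerProfile:
    def test_repeated_word_counted(self):
        p = kmer_profile("AAAA", 3)
        assert p.counts == {"AAA": 2} and p.distinct == 1

    def test_all_windows_enumerated(self):
        p = kmer_profile("ACDEF", 3)
        assert p.counts == {"ACD": 1, "CDE": 1, "DEF": 1}

    def test_windows_touching_x_skipped(self):
        # every length-3 window of ACXDE contains the X
        assert kmer_profile("ACXDE", 3).distinct == 0

    def test_total_count_invariant(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        p = kmer_profile(seq, 3)
        assert sum(p.counts.values()) == len(seq) - 3 + 1

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="shorter than word size"):
            kmer_profile("AC", 3)


class TestGoogleDistance:
    def test_identical_profiles_give_zero(self):
        p = kmer_profile("ACDEFG", 3)
        assert google_distance(p, p, 10) == 0.0

    def test_disjoint_word_sets_give_one(self):
        p = kmer_profile("AAAA", 3)
        q = kmer_profile("CCCC", 3)
        assert google_distance(p, q, 10) == 1.0

    def test_formula_value_clamped_to_one(self):
        # f(p)=2, f(q)=2, shared=1, N=3: (log2 - log1)/(log3 - log2) = 1.7095
        from ecaudit.pairwise import KmerProfile

        p = KmerProfile("p", 3, {"AAA": 1, "AAC": 1}, 2)
        q = KmerProfile("q", 3, {"AAA": 1, "CCC": 1}, 2)
        assert google_distance(p, q, 3) == 1.0

    def test_empty_profile_rejected(self):
        p = kmer_profile("ACXDE", 3)  # all windows masked
        q = kmer_profile("ACDEF", 3)
        with pytest.raises(ValueError, match="empty profile"):
            google_distance(p, q, 10)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.text(alphabet="ACDEFG", min_size=3, max_size=30),
        st.text(alphabet="ACDEFG", min_size=3, max_size=30),
    )
    def test_symmetric_and_bounded(self, a, b):
        p, q = kmer_profile(a, 3), kmer_profile(b, 3)
        n = corpus_distinct([p, q])
        d_pq = google_distance(p, q, n)
        d_qp = google_distance(q, p, n)
        assert d_pq == d_qp
        assert 0.0 <= d_pq <= 1.0
        if set(p.counts) == set(q.counts):
            assert d_pq == 0.0


class TestGlobalAlign:
    def test_identical_sequences_align_without_gaps(self):
        aa, ab, _ = global_align("ACD", "ACD")
        assert aa == ab == "ACD"
        assert percent_identity(aa, ab) == 100.0

    def test_deletion_gives_one_gap_column(self):
        aa, ab, score = global_align("ACD", "AD")
        assert len(aa) == len(ab) == 3
        assert ab.count("-") == 1
        assert score == brute_force_align_score("ACD", "AD")

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACD")

    def test_score_matches_exhaustive_enumeration(self):
        """Optimality oracle: every alignment of short 4-letter sequences
        is enumerated and the best score must equal the aligner's."""
        rng = np.random.default_rng(5)
        alphabet = "ACDE"
        for _ in range(60):
            a = "".join(rng.choice(list(alphabet), rng.integers(1, 7)))
            b = "".join(rng.choice(list(alphabet), rng.integers(1, 7)))
            _, _, score = global_align(a, b)
            assert score == pytest.approx(brute_force_align_score(a, b))

    def test_score_symmetric(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = "".join(rng.choice(list("ACDE"), rng.integers(1, 7)))
            b = "".join(rng.choice(list("ACDE"), rng.integers(1, 7)))
            assert global_align(a, b)[2] == pytest.approx(global_align(b, a)[2])

    def test_gap_params_validated(self):
        with pytest.raises(ValueError):
            AlignParams(gap_open=-0.5, gap_extend=-10.0)


class TestPercentIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACDEFGHIKL", "ACDEFGHIKL", 100.0),
            ("AC-D", "ACED", 75.0),
            ("AAAA", "CCCC", 0.0),
        ],
    )
    def test_column_counting(self, a, b, expected):
        assert percent_identity(a, b) == expected

    def test_gap_columns_count_in_denominator(self):
        # 2 matches over 4 columns even though only 3 columns are gapless
        assert percent_identity("AC-D", "ACE-") == 50.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            percent_identity("AC", "ACD")


class TestClosestCharacterised:
    def test_query_in_characterised_set_matches_itself(self):
        rec = SequenceRecord(id="Q", sequence="ACDEFGHIKLMNP")
        result = closest_characterised(rec, [rec])
        assert result.identity_pct == 100.0 and result.subject == "Q"

    def test_empty_characterised_set(self):
        rec = SequenceRecord(id="Q", sequence="ACDEFGHIKLMNP")
        result = closest_characterised(rec, [])
        assert result.identity_pct == 0.0 and result.subject is None

    def test_full_top_n_equals_exhaustive_maximum(self):
        """With top_n covering the whole characterised set, the result
        must equal the brute-force all-pairs maximum identity."""
        rng = np.random.default_rng(3)
        root = random_sequence(120, rng)
        characterised = [
            SequenceRecord(id=f"C{i}", sequence=mutate_to_identity(root, t, 0.0, rng))
            for i, t in enumerate(np.linspace(0.3, 0.9, 8))
        ]
        queries = [
            SequenceRecord(id=f"Q{i}", sequence=mutate_to_identity(root, t, 0.0, rng))
            for i, t in enumerate([0.5, 0.7, 0.85])
        ]
        for query in queries:
            result = closest_characterised(
                query, characterised, top_n=len(characterised)
            )
            exhaustive = max(
                align_identity(query.sequence, c.sequence) for c in characterised
            )
            assert result.identity_pct == pytest.approx(exhaustive)


class TestRankAgreement:
    def test_monotone_gradient_gives_perfect_rho(self):
        """Nested mutations at fresh positions with cumulative counts
        0/4/10/18: every unordered pair differs at a distinct number of
        sites and all pairs stay inside the NGD's sensitive range, so the
        two measures must rank all pairs identically."""
        rng = np.random.default_rng(2)
        root = random_sequence(300, rng)
        positions = rng.permutation(300)
        subs = {
            int(p): [a for a in "ACDEFGHIKLMNPQRSTVWY" if a != root[p]][
                rng.integers(19)
            ]
            for p in positions
        }
        records = [SequenceRecord(id="G0", sequence=root)]
        for i, n_mut in enumerate([4, 10, 18], start=1):
            seq_list = list(root)
            for pos in positions[:n_mut]:
                seq_list[pos] = subs[int(pos)]
            records.append(SequenceRecord(id=f"G{i}", sequence="".join(seq_list)))
        rho, n_pairs = rank_agreement(records)
        assert n_pairs == 6
        assert rho == pytest.approx(1.0)

    def test_two_records_rejected(self):
        records = [
            SequenceRecord(id="A", sequence="ACDEFGHIKL"),
            SequenceRecord(id="B", sequence="ACDEFGHIKM"),
        ]
        with pytest.raises(ValueError):
            rank_agreement(records)

    def test_all_tied_distances_give_none(self):
        records = [
            SequenceRecord(id=f"R{i}", sequence="ACDEFGHIKL") for i in range(3)
        ]
        rho, _ = rank_agreement(records)
        assert rho is None
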