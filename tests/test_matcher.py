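"""Alignment contract, identity/p-distance semantics and best-hit retrieval."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodeaudit import matcher
from barcodeaudit._align import AlphabetError, encode, overlap_align
from barcodeaudit.library_io import QuerySpecimen, ReferenceRecord
from barcodeaudit.taxonomy import TaxonLineage

from conftest import make_seq, mutate_at

L = TaxonLineage.from_names


def _ref(rid, seq, **names):
    return ReferenceRecord(
        record_id=rid, sequence=seq, lineage=L(**(names or {"family": "Tortricidae"})),
        year_added=2010,
    )


def _query(seq, qid="Q1"):
    return QuerySpecimen(specimen_id=qid, morph_lineage=L(family="Tortricidae"), sequence=seq)


class TestPairwiseIdentity:
    def test_identical_full_length(self):
        rng = np.random.default_rng(0)
        seq = make_seq(rng, 658)
        assert matcher.pairwise_identity(seq, seq) == (100.0, 658)

    def test_thirteen_mismatches_in_650_bp_is_exactly_98(self):
        """637/650 = 98.0 exactly: the strict >98 rule must exclude it."""
        rng = np.random.default_rng(1)
        a = make_seq(rng, 650)
        b = mutate_at(a, range(0, 650, 50))  # 13 evenly spaced substitutions
        ident, overlap = matcher.pairwise_identity(a, b)
        assert ident == 98.0
        assert overlap == 650
        m = matcher.top_hit(_query(a), [_ref("R1", b)], threshold_pct=98.0)
        assert m.hits_above_threshold == ()
        assert m.best_subthreshold == ("R1", 98.0)

    def test_exact_substring_has_free_terminal_gaps(self):
        rng = np.random.default_rng(2)
        a = make_seq(rng, 658)
        assert matcher.pairwise_identity(a, a[100:600]) == (100.0, 500)

    def test_ambiguity_codes_match_on_intersection(self):
        assert matcher.pairwise_identity("ARGT" * 100, "AAGT" * 100, min_overlap_bp=100) == (100.0, 400)
        # Y = C/T does not intersect A
        ident, _ = matcher.pairwise_identity("AYGT" * 100, "AAGT" * 100, min_overlap_bp=100)
        assert ident == 75.0

    def test_bad_alphabet_raises(self):
        with pytest.raises(AlphabetError):
            matcher.pairwise_identity("ACGTQ" * 100, "ACGTA" * 100)


class TestPDistance:
    def test_identical_is_zero(self):
        seq = make_seq(np.random.default_rng(3), 500)
        assert matcher.p_distance(seq, seq) == 0.0

    def test_thirteen_in_650_is_exactly_two_percent(self):
        rng = np.random.default_rng(4)
        a = make_seq(rng, 650)
        b = mutate_at(a, range(0, 650, 50))
        assert matcher.p_distance(a, b) == pytest.approx(0.02, abs=1e-12)

    def test_short_overlap_signals_no_comparison(self):
        rng = np.random.default_rng(5)
        assert matcher.p_distance(make_seq(rng, 120), make_seq(rng, 120)) is None


class TestAlignmentOracles:
    def test_hamming_oracle_on_gapfree_equal_length_pairs(self):
        """On equal-length pairs with few substitutions, identity is Hamming identity."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = make_seq(rng, 400)
            k = int(rng.integers(0, 12))
            pos = rng.choice(400, size=k, replace=False)
            b = mutate_at(a, pos)
            ident, overlap = matcher.pairwise_identity(a, b)
            assert overlap == 400
            assert ident == pytest.approx(100.0 * (400 - k) / 400)

    def test_score_matches_biopython_pairwise_aligner(self):
        """Optimal overlap-alignment score agrees with an independent aligner."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0

        rng = np.random.default_rng(7)
        for _ in range(12):
            a = make_seq(rng, int(rng.integers(80, 160)))
            b = list(make_seq(rng, int(rng.integers(80, 160))))
            if rng.random() < 0.7:  # make some pairs related, with indels
                b = list(a)
                for p in rng.choice(len(b), size=5, replace=False):
                    b[p] = "ACGT"[int(rng.integers(4))]
                del b[int(rng.integers(len(b)))]
            b = "".join(b)
            _, _, score = overlap_align(encode(a), encode(b))
            assert score == aligner.score(a, b)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.data())
def test_identity_symmetric_and_bounded(data):
    bases = st.sampled_from("ACGT")
    a = "".join(data.draw(st.lists(bases, min_size=40, max_size=80)))
    b = "".join(data.draw(st.lists(bases, min_size=40, max_size=80)))
    ra = matcher.pairwise_identity(a, b, min_overlap_bp=10)
    rb = matcher.pairwise_identity(b, a, min_overlap_bp=10)
    assert ra == rb
    if ra is not None:
        assert 0.0 <= ra[0] <= 100.0
        da = matcher.p_distance(a, b, min_overlap_bp=10)
        assert da == pytest.approx(1.0 - ra[0] / 100.0)


class TestTopHit:
    def test_identical_record_is_best_hit(self):
        rng = np.random.default_rng(8)
        seq = make_seq(rng, 658)
        other = mutate_at(seq, range(0, 658, 10))
        m = matcher.top_hit(_query(seq), [_ref("Rfar", other), _ref("Rsame", seq)])
        assert m.best_record_id == "Rsame"
        assert m.best_identity_pct == 100.0
        assert m.hits_above_threshold[0] == ("Rsame", 100.0)

    def test_empty_library(self):
        m = matcher.top_hit(_query(make_seq(np.random.default_rng(9), 658)), [])
        assert m.best_record_id is None
        assert m.hits_above_threshold == ()
        assert m.has_sequence

    def test_no_sequence_signal_distinct_from_no_hit(self):
        q = QuerySpecimen(specimen_id="Q1", morph_lineage=L(family="Tortricidae"))
        m = matcher.top_hit(q, [_ref("R1", "ACGT" * 170)])
        assert not m.has_sequence
        assert m.best_record_id is None

    def test_tie_broken_by_record_id_ascending(self):
        rng = np.random.default_rng(10)
        seq = make_seq(rng, 600)
        near = mutate_at(seq, range(0, 600, 100))  # 6 mismatches -> 99.0%
        m = matcher.top_hit(_query(seq), [_ref("Rb", near), _ref("Ra", near)])
        assert [h[0] for h in m.hits_above_threshold] == ["Ra", "Rb"]
        assert m.best_identity_pct == 99.0

    def test_best_identity_monotone_under_library_growth(self, small_sim):
        records = small_sim["records"]
        queries = [q for q in small_sim["queries"] if q.has_sequence][:10]
        lib1, lib2 = records[:8], records[:20]
        for q in queries:
            m1 = matcher.top_hit(q, lib1, threshold_pct=0.0)
            m2 = matcher.top_hit(q, lib2, threshold_pct=0.0)
            b1 = m1.best_identity_pct if m1.best_identity_pct is not None else -1.0
            b2 = m2.best_identity_pct if m2.best_identity_pct is not None else -1.0
            assert b2 >= b1
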