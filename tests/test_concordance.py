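"""Five-category classification, precedence and aggregate tables."""

import numpy as np
import pytest

from barcodeaudit import concordance, matcher
from barcodeaudit.concordance import Category, classify, classify_queries
from barcodeaudit.library_io import PRBD, SLBR, QuerySpecimen, ReferenceRecord
from barcodeaudit.matcher import MatchResult
from barcodeaudit.taxonomy import TaxonLineage

from conftest import make_seq, mutate_at

L = TaxonLineage.from_names

SPECIES_X = L(family="Tortricidae", genus="Archips", species="Archips packardiana")
SPECIES_SIS = L(family="Tortricidae", genus="Archips", species="Archips alberta")
FAMILY_ONLY = L(family="Tortricidae")
OTHER_FAMILY_SP = L(family="Gelechiidae", genus="Sitotroga", species="Sitotroga cerealella")
BIN_ONLY = TaxonLineage(interim_label="BOLD:AAA0001")


def _match(qid="Q1", hits=(), sub=None, has_sequence=True):
    hits = tuple(hits)
    return MatchResult(
        query_id=qid,
        best_record_id=hits[0][0] if hits else None,
        best_identity_pct=hits[0][1] if hits else None,
        hits_above_threshold=hits,
        best_subthreshold=sub,
        has_sequence=has_sequence,
    )


LOOKUP = {
    "Rx": SPECIES_X,
    "Rsis": SPECIES_SIS,
    "Rfam": FAMILY_ONLY,
    "Rother": OTHER_FAMILY_SP,
    "Rbin": BIN_ONLY,
}


class TestClassify:
    @pytest.mark.parametrize(
        "morph, match, category, rationale",
        [
            # >98% hit named deeper than the morphological ID
            (FAMILY_ONLY, _match(hits=[("Rx", 99.2)]), Category.DNA_LOWER, "hit_lower_consistent"),
            # identical species
            (SPECIES_X, _match(hits=[("Rx", 99.9)]), Category.CONCORDANT, "identical_species"),
            # hit named higher but consistent
            (SPECIES_X, _match(hits=[("Rfam", 99.0)]), Category.CONCORDANT, "hit_higher_consistent"),
            # same lowest rank, same name
            (FAMILY_ONLY, _match(hits=[("Rfam", 99.0)]), Category.CONCORDANT, "identical_at_rank"),
            # BIN-only record
            (FAMILY_ONLY, _match(hits=[("Rbin", 99.0)]), Category.INTERIM, "bin_only"),
            # sub-threshold rescue with the same Linnaean name
            (SPECIES_X, _match(hits=[], sub=("Rx", 97.1)), Category.INTERIM, "sub_threshold_same_name"),
            # congeneric sister species
            (SPECIES_X, _match(hits=[("Rsis", 99.0)]), Category.INTERIM, "sister_species"),
            # nothing at all
            (SPECIES_X, _match(hits=[]), Category.NO_MATCH, "no_hit"),
            # sub-threshold hit with a different name does not rescue
            (SPECIES_X, _match(hits=[], sub=("Rother", 97.5)), Category.NO_MATCH, "no_hit"),
            # disjoint top hit
            (SPECIES_X, _match(hits=[("Rother", 99.0)]), Category.DISCORDANT, "disjoint"),
            # sequencing failure
            (SPECIES_X, _match(has_sequence=False), Category.NO_MATCH, "no_sequence"),
        ],
    )
    def test_decision_table(self, morph, match, category, rationale):
        res = classify(morph, match, LOOKUP)
        assert res.category is category
        assert res.rationale == rationale

    def test_classification_uses_top_hit_and_annotates_conflicts(self):
        """A concordant top hit with a discordant runner-up keeps category 2
        but carries the conflicting lineage as evidence."""
        res = classify(SPECIES_X, _match(hits=[("Rx", 99.5), ("Rother", 99.1)]), LOOKUP)
        assert res.category is Category.CONCORDANT
        assert len(res.conflicting_lineages) == 1
        assert "Gelechiidae" in res.conflicting_lineages[0]

    def test_unresolvable_hit_id_is_a_hard_error(self):
        with pytest.raises(LookupError, match="Rghost"):
            classify(SPECIES_X, _match(hits=[("Rghost", 99.0)]), LOOKUP)

    def test_classification_deterministic(self):
        m = _match(hits=[("Rx", 99.5), ("Rother", 99.1)])
        assert classify(SPECIES_X, m, LOOKUP) == classify(SPECIES_X, m, LOOKUP)


def _engineered_fixture():
    """Five queries engineered to land one in each category."""
    rng = np.random.default_rng(42)
    base = make_seq(rng, 500)
    seq_x = base
    seq_bin = mutate_at(base, range(0, 500, 4))  # far from base
    seq_other = mutate_at(base, range(1, 500, 4))
    unmatched = make_seq(rng, 500)

    records = [
        ReferenceRecord(record_id="Rx", sequence=seq_x, lineage=SPECIES_X, year_added=2009),
        ReferenceRecord(record_id="Rbin", sequence=seq_bin, lineage=BIN_ONLY,
                        bin_label="BOLD:AAA0001", year_added=2009),
        ReferenceRecord(record_id="Rother", sequence=seq_other, lineage=OTHER_FAMILY_SP,
                        year_added=2009),
    ]
    queries = [
        QuerySpecimen("Q1", FAMILY_ONLY, sequence=seq_x),           # -> 1 (deeper hit)
        QuerySpecimen("Q2", SPECIES_X, sequence=seq_x),             # -> 2 (identical)
        QuerySpecimen("Q3", FAMILY_ONLY, sequence=seq_bin),         # -> 3 (BIN only)
        QuerySpecimen("Q4", FAMILY_ONLY, sequence=unmatched),       # -> 4 (no match)
        QuerySpecimen("Q5", SPECIES_X, sequence=seq_other),         # -> 5 (disjoint)
    ]
    return records, queries


class TestClassifyQueries:
    def test_one_query_per_category(self):
        records, queries = _engineered_fixture()
        results, failures = classify_queries(queries, records)
        assert failures == []
        assert {r.specimen_id: int(r.category) for r in results} == {
            "Q1": 1, "Q2": 2, "Q3": 3, "Q4": 4, "Q5": 5,
        }

    def test_empty_library_yields_only_no_match(self):
        _, queries = _engineered_fixture()
        results, _ = classify_queries(queries, [])
        assert all(r.category is Category.NO_MATCH for r in results)


class TestConcordanceTable:
    def test_counts_sum_to_sequenced_queries(self, small_sim):
        table = concordance.concordance_table(
            small_sim["queries"], small_sim["records"], [2009, 2012], [SLBR, PRBD]
        )
        cats = [f"n_cat{i}" for i in range(1, 6)]
        assert (table[cats].sum(axis=1) == table["n_sequenced"]).all()
        n_seq = sum(q.has_sequence for q in small_sim["queries"])
        assert (table["n_sequenced"] == n_seq).all()

    def test_no_match_count_non_increasing_with_library_growth(self, small_sim):
        cfg = small_sim["config"]
        table = concordance.concordance_table(
            small_sim["queries"], small_sim["records"], list(cfg.years), [SLBR]
        )
        assert table["n_cat4"].iloc[-1] < table["n_sequenced"].iloc[-1]  # not vacuous
        assert (table["n_cat4"].diff().dropna() <= 0).all()


class TestSpeciesLevelComparison:
    def test_verbatim_library_gives_full_concordance(self):
        rng = np.random.default_rng(3)
        seqs = [make_seq(rng, 520) for _ in range(3)]
        lineages = [
            L(family="Tortricidae", genus="Archips", species=f"Archips species{i}")
            for i in range(3)
        ]
        records = [
            ReferenceRecord(record_id=f"R{i}", sequence=s, lineage=lin,
                            is_public=True, year_added=2009)
            for i, (s, lin) in enumerate(zip(seqs, lineages))
        ]
        queries = [
            QuerySpecimen(f"Q{i}", lin, sequence=s)
            for i, (s, lin) in enumerate(zip(seqs, lineages))
        ]
        out = concordance.species_level_comparison(queries, records, PRBD)
        assert out["n_both"] == out["n_total_sequenced"] == 3
        assert out["n_both_concordant"] == 3
        assert out["n_both_discordant"] == 0

    def test_injected_library_misidentification_counts_discordant(self):
        rng = np.random.default_rng(4)
        seq = make_seq(rng, 520)
        wrong = L(family="Gelechiidae", genus="Sitotroga", species="Sitotroga cerealella")
        records = [ReferenceRecord(record_id="R0", sequence=seq, lineage=wrong,
                                   is_public=True, year_added=2009)]
        queries = [QuerySpecimen("Q0", SPECIES_X, sequence=seq)]
        out = concordance.species_level_comparison(queries, records, PRBD)
        assert out["n_both_discordant"] == 1

    def test_empty_library_no_dna_species(self):
        queries = [QuerySpecimen("Q0", SPECIES_X, sequence="ACGT" * 130)]
        out = concordance.species_level_comparison(queries, [], PRBD)
        assert out["n_dna_species"] == 0
        assert out["n_morph_species"] == 1
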