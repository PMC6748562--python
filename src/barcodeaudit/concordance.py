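"""Morphology-vs-DNA concordance classification.

Each sequenced specimen is assigned to exactly one of five categories by
comparing its morphological identification with the lineage of its top
library hit:

1. *DNA lower* — a >98% match to a record named at a lower (deeper) rank
   than the morphological identification, consistent at all shared ranks;
2. *concordant* — a >98% match to a record with the identical species
   name, or to a record named at a higher rank that is consistent with the
   lower-level morphological identification (including identical
   identifications at the same non-species rank);
3. *interim* — a >98% match to a BIN-only record, a <98% match to a record
   with the same Linnaean name, or a >98% match to a congeneric sister
   species;
4. *no match* — nothing above the threshold and no same-name rescue below
   it;
5. *discordant* — the top >98% hit disagrees with the morphological
   identification at some shared rank.

Specimens without sequence data are reported separately (the
sequencing-failure bucket) and never enter the category denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import matcher
from .library_io import LibraryView, QuerySpecimen, ReferenceRecord, snapshot
from .matcher import MatchResult
from .reporting import pct
from .taxonomy import LineageRelation, Rank, TaxonLineage, relation

__all__ = [
    "Category",
    "ConcordanceResult",
    "classify",
    "classify_queries",
    "concordance_table",
    "species_level_comparison",
    "CATEGORY_LABELS",
]


class Category(IntEnum):
    DNA_LOWER = 1
    CONCORDANT = 2
    INTERIM = 3
    NO_MATCH = 4
    DISCORDANT = 5


CATEGORY_LABELS = {
    Category.DNA_LOWER: "1_dna_lower",
    Category.CONCORDANT: "2_concordant",
    Category.INTERIM: "3_interim",
    Category.NO_MATCH: "4_no_match",
    Category.DISCORDANT: "5_discordant",
}

#: rationale -> category consistency map (machine-readable sub-rules)
RATIONALE_CATEGORY = {
    "hit_lower_consistent": Category.DNA_LOWER,
    "identical_species": Category.CONCORDANT,
    "hit_higher_consistent": Category.CONCORDANT,
    "identical_at_rank": Category.CONCORDANT,
    "bin_only": Category.INTERIM,
    "sub_threshold_same_name": Category.INTERIM,
    "sister_species": Category.INTERIM,
    "no_hit": Category.NO_MATCH,
    "no_sequence": Category.NO_MATCH,
    "disjoint": Category.DISCORDANT,
}


@dataclass(frozen=True)
class ConcordanceResult:
    specimen_id: str
    category: Category
    rationale: str
    best_record_id: Optional[str] = None
    best_identity_pct: Optional[float] = None
    #: lineages of other supra-threshold hits that conflict with the morph ID
    conflicting_lineages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert RATIONALE_CATEGORY[self.rationale] is self.category


_RELATION_OUTCOME: dict[LineageRelation, tuple[Category, str]] = {
    LineageRelation.IDENTICAL_SPECIES: (Category.CONCORDANT, "identical_species"),
    LineageRelation.DESCENDANT: (Category.DNA_LOWER, "hit_lower_consistent"),
    LineageRelation.ANCESTOR: (Category.CONCORDANT, "hit_higher_consistent"),
    LineageRelation.IDENTICAL_AT_RANK: (Category.CONCORDANT, "identical_at_rank"),
    LineageRelation.INTERIM_ONLY: (Category.INTERIM, "bin_only"),
    LineageRelation.SISTER_SPECIES: (Category.INTERIM, "sister_species"),
    LineageRelation.DISJOINT: (Category.DISCORDANT, "disjoint"),
}


def _same_name_at_lowest_rank(morph: TaxonLineage, hit: TaxonLineage) -> bool:
    lowest = morph.lowest_named_rank()
    if not isinstance(lowest, Rank):
        return False
    return morph.key_at(lowest) is not None and morph.key_at(lowest) == hit.key_at(lowest)


def classify(
    morph: TaxonLineage,
    match: MatchResult,
    hit_lineage_lookup: Mapping[str, TaxonLineage] | Callable[[str], TaxonLineage],
) -> ConcordanceResult:
    """Classify one specimen from its match result.

    The decision is made on the single top hit; the sub-threshold same-name
    rescue is consulted only when nothing clears the threshold.  Other
    supra-threshold hits whose lineage is disjoint from the morphological
    identification are carried along as a conflict annotation.
    """
    lookup = hit_lineage_lookup if callable(hit_lineage_lookup) else hit_lineage_lookup.__getitem__

    if not match.has_sequence:
        return ConcordanceResult(match.query_id, Category.NO_MATCH, "no_sequence")

    if not match.hits_above_threshold:
        if match.best_subthreshold is not None:
            rid, ident = match.best_subthreshold
            try:
                sub_lineage = lookup(rid)
            except KeyError:
                raise LookupError(f"unresolvable hit record id {rid!r}") from None
            if _same_name_at_lowest_rank(morph, sub_lineage):
                return ConcordanceResult(
                    match.query_id,
                    Category.INTERIM,
                    "sub_threshold_same_name",
                    best_record_id=rid,
                    best_identity_pct=ident,
                )
        return ConcordanceResult(match.query_id, Category.NO_MATCH, "no_hit")

    top_id, top_identity = match.hits_above_threshold[0]
    try:
        top_lineage = lookup(top_id)
    except KeyError:
        raise LookupError(f"unresolvable hit record id {top_id!r}") from None
    category, rationale = _RELATION_OUTCOME[relation(morph, top_lineage)]

    conflicts = []
    for rid, _ in match.hits_above_threshold[1:]:
        try:
            lin = lookup(rid)
        except KeyError:
            raise LookupError(f"unresolvable hit record id {rid!r}") from None
        if not lin.is_interim_only() and relation(morph, lin) is LineageRelation.DISJOINT:
            conflicts.append(str(lin))

    return ConcordanceResult(
        match.query_id,
        category,
        rationale,
        best_record_id=top_id,
        best_identity_pct=top_identity,
        conflicting_lineages=tuple(conflicts),
    )


def _lineage_lookup(records: Sequence[ReferenceRecord]) -> dict[str, TaxonLineage]:
    return {r.record_id: r.lineage for r in records}


def classify_queries(
    queries: Sequence[QuerySpecimen],
    records: Sequence[ReferenceRecord],
    threshold_pct: float = matcher.DEFAULT_THRESHOLD_PCT,
    min_overlap_bp: int = matcher.DEFAULT_MIN_OVERLAP_BP,
    scores: Optional[pd.DataFrame] = None,
) -> tuple[list[ConcordanceResult], list[str]]:
    """Classify every sequenced query against one library snapshot.

    Returns (results for sequenced queries, ids of sequence-less queries).
    """
    if scores is None:
        scores = matcher.score_table(queries, records, min_overlap_bp)
    lookup = _lineage_lookup(records)
    record_ids = set(lookup)
    results: list[ConcordanceResult] = []
    failures: list[str] = []
    for q in queries:
        if not q.has_sequence:
            failures.append(q.specimen_id)
            continue
        m = matcher.match_from_scores(
            q, scores, record_ids=record_ids, threshold_pct=threshold_pct, min_overlap_bp=min_overlap_bp
        )
        results.append(classify(q.morph_lineage, m, lookup))
    return results, failures


def concordance_table(
    queries: Sequence[QuerySpecimen],
    records: Sequence[ReferenceRecord],
    years: Sequence[int],
    views: Sequence[LibraryView],
    threshold_pct: float = matcher.DEFAULT_THRESHOLD_PCT,
    min_overlap_bp: int = matcher.DEFAULT_MIN_OVERLAP_BP,
    scores: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Category counts and percentages per (year, view) snapshot.

    For each snapshot the five category counts sum to the number of queries
    with sequence data.  Alignments are computed once against the full
    record set and re-used across snapshots.
    """
    if scores is None:
        scores = matcher.score_table(queries, records, min_overlap_bp)
    rows = []
    for view in views:
        for year in years:
            snap = snapshot(records, year, view)
            results, failures = classify_queries(
                queries, snap, threshold_pct, min_overlap_bp, scores=scores
            )
            n_seq = len(results)
            counts = {c: 0 for c in Category}
            for res in results:
                counts[res.category] += 1
            row = {"year": year, "view": view.name, "n_sequenced": n_seq, "n_no_sequence": len(failures)}
            for c in Category:
                row[f"n_cat{int(c)}"] = counts[c]
                row[f"pct_cat{int(c)}"] = pct(counts[c], n_seq) if n_seq else 0.0
            n_identified = n_seq - counts[Category.NO_MATCH]
            row["n_identified"] = n_identified
            row["pct_identified"] = pct(n_identified, n_seq) if n_seq else 0.0
            rows.append(row)
    return pd.DataFrame(rows)


def species_level_comparison(
    queries: Sequence[QuerySpecimen],
    records: Sequence[ReferenceRecord],
    view: LibraryView,
    year: Optional[int] = None,
    threshold_pct: float = matcher.DEFAULT_THRESHOLD_PCT,
    min_overlap_bp: int = matcher.DEFAULT_MIN_OVERLAP_BP,
    scores: Optional[pd.DataFrame] = None,
) -> dict[str, int]:
    """Species-level identification arithmetic for one view.

    Counts specimens identified to species by morphology, by DNA (top
    supra-threshold hit carries a species name), and by both; the
    both-species subset is split into concordant (categories 1-2), interim
    (3) and discordant (5) outcomes.
    """
    snap = snapshot(records, year, view) if year is not None else [
        r for r in records if view.admits(r)
    ]
    if scores is None:
        scores = matcher.score_table(queries, snap, min_overlap_bp)
    lookup = _lineage_lookup(snap)
    record_ids = set(lookup)

    n_sequenced = 0
    n_morph_species = 0
    n_dna_species = 0
    n_both = 0
    both_split = {"concordant": 0, "interim": 0, "discordant": 0}
    for q in queries:
        if not q.has_sequence:
            continue
        n_sequenced += 1
        morph_sp = q.morph_lineage.name_at(Rank.SPECIES) is not None
        if morph_sp:
            n_morph_species += 1
        m = matcher.match_from_scores(
            q, scores, record_ids=record_ids, threshold_pct=threshold_pct, min_overlap_bp=min_overlap_bp
        )
        dna_sp = (
            m.best_record_id is not None
            and lookup[m.best_record_id].name_at(Rank.SPECIES) is not None
        )
        if dna_sp:
            n_dna_species += 1
        if morph_sp and dna_sp:
            n_both += 1
            res = classify(q.morph_lineage, m, lookup)
            if res.category in (Category.DNA_LOWER, Category.CONCORDANT):
                both_split["concordant"] += 1
            elif res.category is Category.INTERIM:
                both_split["interim"] += 1
            elif res.category is Category.DISCORDANT:
                both_split["discordant"] += 1
    return {
        "n_total_sequenced": n_sequenced,
        "n_morph_species": n_morph_species,
        "n_dna_species": n_dna_species,
        "n_both": n_both,
        "n_both_concordant": both_split["concordant"],
        "n_both_interim": both_split["interim"],
        "n_both_discordant": both_split["discordant"],
    }
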