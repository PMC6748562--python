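"""Pairwise identity, p-distance and best-hit retrieval.

This is the local stand-in for a BOLD identification request: every query
is compared exhaustively against the library (libraries here are
desk-scale, so no indexing heuristics are needed).  The alignment contract
is the standard barcode-identification one — global alignment with free
terminal gaps (match +1, mismatch −1, gaps −2), identity computed as
matches over aligned columns with terminal-gap columns excluded, IUPAC
ambiguity codes matching whenever their base sets intersect.  Comparisons
whose aligned overlap falls below ``min_overlap_bp`` yield no result and
contribute no hit.

Hits above the identification threshold use a *strict* inequality
(identity > threshold); an identity of exactly 98.0 against a 98.0
threshold is not a hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._align import AlphabetError, encode, overlap_align
from .library_io import QuerySpecimen, ReferenceRecord

__all__ = [
    "DEFAULT_THRESHOLD_PCT",
    "DEFAULT_MIN_OVERLAP_BP",
    "PairwiseComparison",
    "MatchResult",
    "pairwise_identity",
    "p_distance",
    "top_hit",
    "score_table",
    "match_from_scores",
]

DEFAULT_THRESHOLD_PCT = 98.0
DEFAULT_MIN_OVERLAP_BP = 300


@dataclass(frozen=True)
class PairwiseComparison:
    identity_pct: float
    overlap: int
    matches: int


def compare(a: str, b: str, min_overlap_bp: int = DEFAULT_MIN_OVERLAP_BP) -> Optional[PairwiseComparison]:
    """Align two sequences; ``None`` when the aligned overlap is too short."""
    matches, columns, _score = overlap_align(encode(a), encode(b))
    if columns < min_overlap_bp:
        return None
    return PairwiseComparison(identity_pct=100.0 * matches / columns, overlap=columns, matches=matches)


def pairwise_identity(
    a: str, b: str, min_overlap_bp: int = DEFAULT_MIN_OVERLAP_BP
) -> Optional[tuple[float, int]]:
    """(identity %, overlap bp) of the best overlap alignment, or ``None``."""
    cmp = compare(a, b, min_overlap_bp)
    if cmp is None:
        return None
    return cmp.identity_pct, cmp.overlap


def p_distance(a: str, b: str, min_overlap_bp: int = DEFAULT_MIN_OVERLAP_BP) -> Optional[float]:
    """Proportion of non-matching aligned columns, or ``None`` on short overlap."""
    cmp = compare(a, b, min_overlap_bp)
    if cmp is None:
        return None
    return 1.0 - cmp.identity_pct / 100.0


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one query against a library snapshot.

    ``hits_above_threshold`` lists every (record_id, identity %) strictly
    above the threshold, sorted by identity descending with ties broken by
    record_id ascending.  The best sub-threshold hit is retained because
    the concordance rules allow a below-threshold match with the same
    Linnaean name to rescue an otherwise unidentified specimen.
    """

    query_id: str
    best_record_id: Optional[str] = None
    best_identity_pct: Optional[float] = None
    hits_above_threshold: tuple[tuple[str, float], ...] = ()
    threshold_pct: float = DEFAULT_THRESHOLD_PCT
    min_overlap_bp: int = DEFAULT_MIN_OVERLAP_BP
    best_subthreshold: Optional[tuple[str, float]] = None
    has_sequence: bool = True

    @property
    def has_hit(self) -> bool:
        return bool(self.hits_above_threshold)


def _sort_hits(hits: list[tuple[str, float]]) -> list[tuple[str, float]]:
    return sorted(hits, key=lambda h: (-h[1], h[0]))


def score_table(
    queries: Sequence[QuerySpecimen],
    records: Sequence[ReferenceRecord],
    min_overlap_bp: int = DEFAULT_MIN_OVERLAP_BP,
) -> pd.DataFrame:
    """All-vs-all identities (long format: query_id, record_id, identity_pct, overlap).

    Comparisons with insufficient overlap are omitted.  Computing this once
    and slicing per snapshot avoids re-aligning when the same queries are
    identified against several year/view snapshots.
    """
    enc_records = [(r.record_id, encode(r.sequence)) for r in records]
    rows: list[tuple[str, str, float, int]] = []
    for q in queries:
        if q.sequence is None:
            continue
        eq = encode(q.sequence)
        for rid, er in enc_records:
            matches, columns, _score = overlap_align(eq, er)
            if columns >= min_overlap_bp:
                rows.append((q.specimen_id, rid, 100.0 * matches / columns, columns))
    return pd.DataFrame(rows, columns=["query_id", "record_id", "identity_pct", "overlap"])


def match_from_scores(
    query: QuerySpecimen,
    scores: pd.DataFrame,
    record_ids: Optional[Iterable[str]] = None,
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
    min_overlap_bp: int = DEFAULT_MIN_OVERLAP_BP,
) -> MatchResult:
    """Build a :class:`MatchResult` from a precomputed score table.

    ``record_ids``, when given, restricts scoring to a library snapshot.
    """
    if not query.has_sequence:
        return MatchResult(
            query_id=query.specimen_id,
            threshold_pct=threshold_pct,
            min_overlap_bp=min_overlap_bp,
            has_sequence=False,
        )
    sub = scores[scores["query_id"] == query.specimen_id]
    if record_ids is not None:
        wanted = set(record_ids)
        sub = sub[sub["record_id"].isin(wanted)]
    pairs = list(zip(sub["record_id"], sub["identity_pct"]))
    above = _sort_hits([p for p in pairs if p[1] > threshold_pct])
    below = _sort_hits([p for p in pairs if p[1] <= threshold_pct])
    return MatchResult(
        query_id=query.specimen_id,
        best_record_id=above[0][0] if above else None,
        best_identity_pct=above[0][1] if above else None,
        hits_above_threshold=tuple(above),
        threshold_pct=threshold_pct,
        min_overlap_bp=min_overlap_bp,
        best_subthreshold=below[0] if below else None,
        has_sequence=True,
    )


def top_hit(
    query: QuerySpecimen,
    library: Sequence[ReferenceRecord],
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
    min_overlap_bp: int = DEFAULT_MIN_OVERLAP_BP,
) -> MatchResult:
    """Exhaustively match one query against a library (possibly empty)."""
    if not query.has_sequence:
        return MatchResult(
            query_id=query.specimen_id,
            threshold_pct=threshold_pct,
            min_overlap_bp=min_overlap_bp,
            has_sequence=False,
        )
    scores = score_table([query], library, min_overlap_bp)
    return match_from_scores(
        query, scores, record_ids=None, threshold_pct=threshold_pct, min_overlap_bp=min_overlap_bp
    )
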