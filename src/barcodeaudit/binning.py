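"""BIN-surrogate MOTU clustering and taxonomic concordance audit.

Sequences are clustered by single linkage on pairwise p-distance: two
records share a MOTU exactly when a chain of pairs, each within the
distance threshold, connects them.  This is a deliberate surrogate for
BOLD's Refined Single Linkage (RESL) — the Markov-refinement stage is not
reproduced and no equivalence with official BINs is claimed.  The default
threshold of 0.022 is the conventional BIN seed value.

Each multi-member cluster is audited for taxonomic concordance: it is
discordant when any rank carries two or more distinct names among its
members (a cluster mixing two families is discordant even with no species
names anywhere), concordant when all named ranks agree — members named
only at higher ranks are consistent with deeper names, and interim-only
members impose no constraint.  Single-member clusters are flagged
``singleton`` and excluded from the concordance denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from ._align import encode, overlap_align
from .library_io import ReferenceRecord
from .reporting import pct
from .taxonomy import Rank, TaxonLineage

__all__ = [
    "DEFAULT_BIN_THRESHOLD",
    "MotuStatus",
    "MotuCluster",
    "cluster",
    "audit_cluster",
    "bin_size_summary",
]

DEFAULT_BIN_THRESHOLD = 0.022

#: sentinel distance for pairs whose overlap is too short to compare;
#: far above any plausible threshold, so such pairs contribute no edge.
_NO_EDGE = 9.0


class MotuStatus(str, Enum):
    CONCORDANT = "concordant"
    DISCORDANT = "discordant"
    SINGLETON = "singleton"


@dataclass(frozen=True)
class MotuCluster:
    cluster_id: str
    member_record_ids: frozenset[str]
    status: Optional[MotuStatus] = None
    distinct_names_per_rank: Optional[Mapping[Rank, frozenset[str]]] = None

    @property
    def n_members(self) -> int:
        return len(self.member_record_ids)


def _pdistance_condensed(
    records: Sequence[ReferenceRecord], min_overlap_bp: int
) -> np.ndarray:
    enc = [encode(r.sequence) for r in records]
    n = len(enc)
    out = np.empty(n * (n - 1) // 2, dtype=np.float64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            matches, columns, _score = overlap_align(enc[i], enc[j])
            out[k] = (1.0 - matches / columns) if columns >= min_overlap_bp else _NO_EDGE
            k += 1
    return out


def cluster(
    records: Sequence[ReferenceRecord],
    distance_threshold: float = DEFAULT_BIN_THRESHOLD,
    min_overlap_bp: int = 300,
) -> list[MotuCluster]:
    """Single-linkage MOTUs at ``distance_threshold`` (inclusive) on p-distance.

    Cluster ids are the lexicographically smallest member record id, so the
    result is invariant to input order.  Clusters partition the input.
    """
    if not records:
        return []
    if len(records) == 1:
        rid = records[0].record_id
        return [MotuCluster(cluster_id=rid, member_record_ids=frozenset([rid]))]
    condensed = _pdistance_condensed(records, min_overlap_bp)
    labels = fcluster(linkage(condensed, method="single"), t=distance_threshold, criterion="distance")
    groups: dict[int, list[str]] = {}
    for record, label in zip(records, labels):
        groups.setdefault(int(label), []).append(record.record_id)
    clusters = [
        MotuCluster(cluster_id=min(ids), member_record_ids=frozenset(ids))
        for ids in groups.values()
    ]
    return sorted(clusters, key=lambda c: c.cluster_id)


def audit_cluster(
    motu: MotuCluster,
    lineage_lookup: Mapping[str, TaxonLineage] | Callable[[str], TaxonLineage],
) -> MotuCluster:
    """Assign concordant / discordant / singleton status to one MOTU."""
    lookup = lineage_lookup if callable(lineage_lookup) else lineage_lookup.__getitem__
    names_per_rank: dict[Rank, dict[str, str]] = {}
    for rid in sorted(motu.member_record_ids):
        lineage = lookup(rid)
        for rank, name in lineage.names.items():
            names_per_rank.setdefault(rank, {}).setdefault(name.casefold(), name)
    distinct = {
        rank: frozenset(by_key.values()) for rank, by_key in names_per_rank.items()
    }
    if motu.n_members == 1:
        status = MotuStatus.SINGLETON
    elif any(len(names) >= 2 for names in distinct.values()):
        status = MotuStatus.DISCORDANT
    else:
        status = MotuStatus.CONCORDANT
    return MotuCluster(
        cluster_id=motu.cluster_id,
        member_record_ids=motu.member_record_ids,
        status=status,
        distinct_names_per_rank=distinct,
    )


def bin_size_summary(clusters: Sequence[MotuCluster]) -> dict:
    """Cluster-size arithmetic: singleton / multi-member / at-most-10-record counts."""
    n_clusters = len(clusters)
    n_singleton = sum(1 for c in clusters if c.n_members == 1)
    n_multi = n_clusters - n_singleton
    n_le_10 = sum(1 for c in clusters if c.n_members <= 10)
    summary = {
        "n_clusters": n_clusters,
        "n_singleton": n_singleton,
        "n_multi": n_multi,
        "n_le_10_members": n_le_10,
    }
    if n_clusters:
        summary["pct_singleton"] = pct(n_singleton, n_clusters)
        summary["pct_multi"] = pct(n_multi, n_clusters)
        summary["pct_le_10"] = pct(n_le_10, n_clusters)
    return summary
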