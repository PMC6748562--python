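"""Linnaean lineages and the rank-relation calculus.

A morphological identification and a DNA-based match are each a (possibly
partial) lineage over the six ranks order, superfamily, family, subfamily,
genus, species, optionally carrying an interim MOTU/BIN label (e.g.
``BOLD:AAP2599``) when no Linnaean name is available.  Comparing the two
lineages yields one of a small set of relations (identical species,
ancestor, descendant, congeneric sister species, disjoint, interim-only,
identical-at-rank) that downstream code maps onto concordance categories.

Only ranks named on *both* sides are ever compared, so missing intermediate
ranks never create disagreement.  Name comparison is case-insensitive exact
match after whitespace normalisation; no synonym resolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Iterable, Literal, Mapping, Optional, Union

__all__ = [
    "Rank",
    "RANKS",
    "INTERIM",
    "TaxonLineage",
    "LineageRelation",
    "LineageError",
    "relation",
    "lowest_named_rank",
]


class LineageError(ValueError):
    """A lineage violates its structural invariants."""


class Rank(IntEnum):
    """Taxonomic rank; the integer value is the depth (order=0 ... species=5)."""

    ORDER = 0
    SUPERFAMILY = 1
    FAMILY = 2
    SUBFAMILY = 3
    GENUS = 4
    SPECIES = 5

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "Rank":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise LineageError(f"unknown rank label: {label!r}") from None


RANKS: tuple[Rank, ...] = tuple(Rank)

#: Sentinel returned by :func:`lowest_named_rank` for interim-only lineages.
INTERIM: Literal["interim"] = "interim"


def _norm(name: str) -> str:
    return " ".join(name.split())


def _truncate_to_binomen(name: str) -> str:
    """Drop subspecific epithets: keep at most the first two name tokens."""
    parts = name.split()
    return " ".join(parts[:2]) if len(parts) > 2 else name


@dataclass(frozen=True)
class TaxonLineage:
    """An identification: named ranks plus an optional interim (BIN) label.

    ``names`` maps :class:`Rank` to a taxon name; any subset of ranks may be
    present.  At least one named rank or an interim label is required.  A
    species name implies a genus name (a binomen names its genus).
    """

    names: Mapping[Rank, str] = field(default_factory=dict)
    interim_label: Optional[str] = None

    def __post_init__(self) -> None:
        cleaned: dict[Rank, str] = {}
        for rank, name in self.names.items():
            if not isinstance(rank, Rank):
                rank = Rank.from_label(str(rank))
            name = _norm(str(name))
            if not name:
                continue
            if rank is Rank.SPECIES:
                name = _truncate_to_binomen(name)
            cleaned[rank] = name
        label = _norm(self.interim_label) if self.interim_label else None
        object.__setattr__(self, "names", dict(sorted(cleaned.items())))
        object.__setattr__(self, "interim_label", label or None)
        if not self.names and not self.interim_label:
            raise LineageError("empty lineage: no named rank and no interim label")
        if Rank.SPECIES in self.names and Rank.GENUS not in self.names:
            raise LineageError(
                f"species name {self.names[Rank.SPECIES]!r} without a genus name"
            )

    @classmethod
    def from_names(cls, interim_label: Optional[str] = None, **names: Optional[str]) -> "TaxonLineage":
        """Build from keyword rank labels, e.g. ``from_names(family="Tortricidae")``."""
        mapping = {
            Rank.from_label(k): v for k, v in names.items() if v is not None and str(v).strip()
        }
        return cls(names=mapping, interim_label=interim_label)

    @property
    def named_ranks(self) -> tuple[Rank, ...]:
        return tuple(self.names)

    def name_at(self, rank: Rank) -> Optional[str]:
        return self.names.get(rank)

    def key_at(self, rank: Rank) -> Optional[str]:
        """Case-folded comparison key for the name at ``rank``."""
        name = self.names.get(rank)
        return name.casefold() if name is not None else None

    def lowest_named_rank(self) -> Union[Rank, Literal["interim"]]:
        """Deepest rank carrying a name; ``"interim"`` if only a BIN label exists."""
        if self.names:
            return max(self.names)
        return INTERIM

    def truncated(self, rank: Rank) -> "TaxonLineage":
        """Copy keeping only names at ``rank`` and above (no interim label)."""
        kept = {r: n for r, n in self.names.items() if r <= rank}
        return TaxonLineage(names=kept)

    def is_interim_only(self) -> bool:
        return not self.names

    def __str__(self) -> str:
        parts = [f"{r.label}={n}" for r, n in self.names.items()]
        if self.interim_label:
            parts.append(f"interim={self.interim_label}")
        return "; ".join(parts)


class LineageRelation(Enum):
    """Outcome of comparing a morphological lineage with a hit lineage."""

    IDENTICAL_SPECIES = "identical_species"
    ANCESTOR = "ancestor"  # hit is shallower than, and consistent with, morph
    DESCENDANT = "descendant"  # hit is deeper than, and consistent with, morph
    SISTER_SPECIES = "sister_species"  # congeners with different epithets
    DISJOINT = "disjoint"  # some rank named on both sides disagrees
    INTERIM_ONLY = "interim_only"  # hit carries only a BIN label
    IDENTICAL_AT_RANK = "identical_at_rank"  # same lowest non-species rank, all agree


def lowest_named_rank(lineage: TaxonLineage) -> Union[Rank, Literal["interim"]]:
    """Module-level convenience wrapper for :meth:`TaxonLineage.lowest_named_rank`."""
    if not isinstance(lineage, TaxonLineage):
        raise LineageError(f"not a lineage: {lineage!r}")
    return lineage.lowest_named_rank()


def relation(morph: TaxonLineage, hit: TaxonLineage) -> LineageRelation:
    """Relate a morphological identification to a reference-record lineage.

    Decision order: interim-only hit; both species-named -> identical
    species or congeneric sister; disagreement at any rank named on both
    sides -> disjoint; otherwise compare depths of the lowest named ranks
    (deeper hit -> descendant, shallower -> ancestor, equal ->
    identical-at-rank).
    """
    if hit.is_interim_only():
        return LineageRelation.INTERIM_ONLY
    if morph.is_interim_only():
        raise LineageError("morphological lineage has no Linnaean names to compare")

    m_sp, h_sp = morph.key_at(Rank.SPECIES), hit.key_at(Rank.SPECIES)
    if m_sp is not None and h_sp is not None:
        if m_sp == h_sp:
            return LineageRelation.IDENTICAL_SPECIES
        if morph.key_at(Rank.GENUS) == hit.key_at(Rank.GENUS):
            return LineageRelation.SISTER_SPECIES

    shared = [r for r in morph.names if r in hit.names and r is not Rank.SPECIES]
    if any(morph.key_at(r) != hit.key_at(r) for r in shared):
        return LineageRelation.DISJOINT

    m_depth = morph.lowest_named_rank()
    h_depth = hit.lowest_named_rank()
    assert isinstance(m_depth, Rank) and isinstance(h_depth, Rank)
    if h_depth > m_depth:
        return LineageRelation.DESCENDANT
    if h_depth < m_depth:
        return LineageRelation.ANCESTOR
    return LineageRelation.IDENTICAL_AT_RANK
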