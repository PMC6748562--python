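"""Synthetic taxonomies, barcode libraries and interception query sets.

The generator emulates the structure of a border-interception barcode
audit so every pipeline stage is testable with known ground truth and
without downloads: a multi-rank moth-like taxonomy; COI-length sequences
evolved under a uniform (Jukes–Cantor-like) substitution model with
intraspecific variation far below interspecific divergence; a reference
library that grows over calendar years with a public/non-public record
split; and intercepted specimens whose morphological identifications are
truncated at varying ranks and occasionally misidentified.

Defaults mirror the conditions of the interception study the pipeline is
built around: 241 specimens of which 16.6% fail sequencing, 6.5% yield
only a ~407 bp fragment, 38.3% carry a species-level morphological name;
a 160-species taxonomy with Zipf-skewed interception abundance (heavy
skew is what produces many singleton MOTUs in real interception data);
and an 11-year (2009–2019) library growth schedule that starts steep and
plateaus after 2015.

Misidentifications are modelled as cross-genus errors (a confamilial,
non-congeneric taxon is substituted): a congeneric swap would surface as
a sister-species (interim) call rather than a discordance, whereas
real-world gross misidentifications are what the discordant category is
meant to catch.  Every corruption is recorded in a truth ledger.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .library_io import (
    QuerySpecimen,
    ReferenceRecord,
    write_library,
    write_queries,
)
from .taxonomy import Rank, TaxonLineage

__all__ = [
    "SimulationConfig",
    "Truth",
    "generate_truth",
    "generate_library",
    "generate_queries",
    "write_outputs",
]

_BASES = "ACGT"

_DEFAULT_RANK_DISTRIBUTION = {
    "order": 0.02,
    "superfamily": 0.03,
    "family": 0.42,
    "subfamily": 0.05,
    "genus": 0.10,
    "species": 0.38,
}

_ORIGIN_COUNTRIES = (
    "Mexico",
    "Ghana",
    "Thailand",
    "Colombia",
    "Ecuador",
    "Italy",
    "Netherlands",
    "Australia",
)


@dataclass
class SimulationConfig:
    """All knobs of the simulated study, with the study conditions as defaults."""

    seed: int = 0
    n_families: int = 10
    genera_per_family: int = 4
    species_per_genus: int = 4
    seq_length_bp: int = 658
    intraspecific_divergence: float = 0.005
    interspecific_divergence: float = 0.05
    years: tuple[int, ...] = tuple(range(2009, 2020))
    records_per_year: tuple[int, ...] = (55, 20, 16, 13, 11, 9, 8, 6, 4, 4, 4)
    public_fraction_by_year: tuple[float, ...] = (0.35,) * 11
    morph_rank_distribution: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RANK_DISTRIBUTION)
    )
    morph_misid_rate: float = 0.02
    sequencing_failure_rate: float = 0.166
    fragment_rate: float = 0.065
    fragment_length_bp: int = 407
    n_queries: int = 241
    library_species_fraction: float = 0.85
    abundance_skew: float = 1.0  # Zipf exponent; 0 = uniform species abundance
    ensure_species_coverage: bool = False  # round-robin library sampling

    def validate(self) -> None:
        if min(self.n_families, self.genera_per_family, self.species_per_genus) < 1:
            raise ValueError("taxonomy dimensions must be at least 1")
        if self.seq_length_bp < 1:
            raise ValueError("seq_length_bp must be positive")
        if not 0 <= self.intraspecific_divergence < self.interspecific_divergence:
            raise ValueError("need 0 <= intraspecific < interspecific divergence")
        if len(self.records_per_year) != len(self.years):
            raise ValueError("records_per_year must match years in length")
        if len(self.public_fraction_by_year) != len(self.years):
            raise ValueError("public_fraction_by_year must match years in length")
        for name in (
            "morph_misid_rate",
            "sequencing_failure_rate",
            "fragment_rate",
            "library_species_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1], got {v}")
        for p in self.public_fraction_by_year:
            if not 0.0 <= p <= 1.0:
                raise ValueError("public fractions must be proportions")
        dist = self.morph_rank_distribution
        if any(p < 0 for p in dist.values()) or abs(sum(dist.values()) - 1.0) > 1e-9:
            raise ValueError("morph_rank_distribution must be non-negative and sum to 1")
        for label in dist:
            Rank.from_label(label)

    @property
    def n_species(self) -> int:
        return self.n_families * self.genera_per_family * self.species_per_genus

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("years", "records_per_year", "public_fraction_by_year"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key in ("years", "records_per_year", "public_fraction_by_year"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass(frozen=True)
class Truth:
    """Ground-truth taxonomy: lineages, ancestral haplotypes, BIN labels."""

    species: tuple[str, ...]
    lineages: dict[str, TaxonLineage]
    ancestors: dict[str, np.ndarray]  # species -> base indices (0..3)
    bins: dict[str, str]

    def ancestor_seq(self, species: str) -> str:
        return _to_str(self.ancestors[species])


def _to_str(arr: np.ndarray) -> str:
    return "".join(_BASES[i] for i in arr)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a uniform other base."""
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n)) % 4
    return out


def _abundance_weights(n: int, skew: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** skew
    return w / w.sum()


def generate_truth(config: SimulationConfig) -> Truth:
    """Build the taxonomy and per-species ancestral haplotypes.

    Ancestral sequences descend root -> family -> genus -> species with
    expected per-site substitution rates of 4x, 2x and 1x the
    interspecific divergence, so congeneric species are the closest
    heterospecific pairs.  Deterministic under the config seed.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    root = rng.integers(0, 4, size=config.seq_length_bp, dtype=np.int64)
    d = config.interspecific_divergence

    species: list[str] = []
    lineages: dict[str, TaxonLineage] = {}
    ancestors: dict[str, np.ndarray] = {}
    bins: dict[str, str] = {}
    idx = 0
    for fi in range(config.n_families):
        family = f"Simulidae{fi + 1:02d}"
        superfamily = f"Simuloidea{fi // 2 + 1:02d}"
        family_anc = _mutate(root, 4 * d, rng)
        for gi in range(config.genera_per_family):
            genus = f"Simulus{fi + 1:02d}{gi + 1:02d}"
            subfamily = f"Simulinae{fi + 1:02d}{gi // 2 + 1:02d}"
            genus_anc = _mutate(family_anc, 2 * d, rng)
            for si in range(config.species_per_genus):
                idx += 1
                binomen = f"{genus} species{si + 1:02d}"
                species.append(binomen)
                lineages[binomen] = TaxonLineage(
                    names={
                        Rank.ORDER: "Lepidoptera",
                        Rank.SUPERFAMILY: superfamily,
                        Rank.FAMILY: family,
                        Rank.SUBFAMILY: subfamily,
                        Rank.GENUS: genus,
                        Rank.SPECIES: binomen,
                    },
                    interim_label=f"SIM:{idx:04d}",
                )
                ancestors[binomen] = _mutate(genus_anc, d, rng)
                bins[binomen] = f"SIM:{idx:04d}"
    return Truth(
        species=tuple(species), lineages=lineages, ancestors=ancestors, bins=bins
    )


def _confamilial_swap(
    truth: Truth, species: str, rng: np.random.Generator
) -> Optional[str]:
    """A different-genus, same-family species; None when the family has one genus."""
    lineage = truth.lineages[species]
    family = lineage.key_at(Rank.FAMILY)
    genus = lineage.key_at(Rank.GENUS)
    candidates = [
        s
        for s in truth.species
        if truth.lineages[s].key_at(Rank.FAMILY) == family
        and truth.lineages[s].key_at(Rank.GENUS) != genus
    ]
    if not candidates:
        return None
    return candidates[rng.integers(len(candidates))]


def _other_at_rank(
    truth: Truth, species: str, rank: Rank, rng: np.random.Generator
) -> Optional[str]:
    """A species whose name at ``rank`` differs from that of ``species``."""
    key = truth.lineages[species].key_at(rank)
    candidates = [s for s in truth.species if truth.lineages[s].key_at(rank) != key]
    if not candidates:
        return None
    return candidates[rng.integers(len(candidates))]


def generate_library(
    config: SimulationConfig, truth: Optional[Truth] = None
) -> tuple[list[ReferenceRecord], pd.DataFrame]:
    """Grow a reference library over the configured years.

    Species are drawn with the configured abundance skew (or round-robin
    when ``ensure_species_coverage`` is set); haplotypes are mutated from
    the species ancestor at the intraspecific divergence; the public flag
    is sampled per year; a fraction of records carry only a family-level
    name (interim/BIN label retained); misidentified records swap their
    lineage for a confamilial non-congeneric taxon.  Returns the records
    and a truth ledger (record_id, year, true vs attached species, flags).
    """
    config.validate()
    if truth is None:
        truth = generate_truth(config)
    rng = np.random.default_rng([config.seed, 1])
    weights = _abundance_weights(len(truth.species), config.abundance_skew)
    species_arr = np.asarray(truth.species, dtype=object)

    coverage_cycle: list[str] = []
    records: list[ReferenceRecord] = []
    ledger_rows = []
    serial = 0
    for yi, year in enumerate(config.years):
        for _ in range(config.records_per_year[yi]):
            serial += 1
            if config.ensure_species_coverage:
                if not coverage_cycle:
                    coverage_cycle = list(rng.permutation(species_arr))
                true_species = coverage_cycle.pop()
            else:
                true_species = str(rng.choice(species_arr, p=weights))
            hap = _mutate(truth.ancestors[true_species], config.intraspecific_divergence, rng)

            attached = truth.lineages[true_species]
            misid = bool(rng.random() < config.morph_misid_rate)
            species_level = bool(rng.random() < config.library_species_fraction)
            if misid:
                swap = _confamilial_swap(truth, true_species, rng)
                if swap is None:
                    misid = False
                else:
                    attached = truth.lineages[swap]
            if not species_level:
                attached = attached.truncated(Rank.FAMILY)
            attached = TaxonLineage(
                names=attached.names, interim_label=truth.bins[true_species]
            )

            record_id = f"R{year}-{serial:04d}"
            records.append(
                ReferenceRecord(
                    record_id=record_id,
                    sequence=_to_str(hap),
                    lineage=attached,
                    bin_label=truth.bins[true_species],
                    is_public=bool(rng.random() < config.public_fraction_by_year[yi]),
                    year_added=year,
                    country_of_origin=str(rng.choice(_ORIGIN_COUNTRIES)),
                    country_of_interception=None,
                    capture_exception=False,
                )
            )
            ledger_rows.append(
                {
                    "record_id": record_id,
                    "year_added": year,
                    "true_species": true_species,
                    "attached_name": str(attached),
                    "species_level": species_level,
                    "misidentified": misid,
                }
            )
    return records, pd.DataFrame(ledger_rows)


def generate_queries(
    config: SimulationConfig, truth: Optional[Truth] = None, n: Optional[int] = None
) -> tuple[list[QuerySpecimen], pd.DataFrame]:
    """Sample intercepted specimens with known ground truth.

    Each specimen draws a true species (same abundance skew as the
    library), may fail sequencing, may yield only a fragment, and carries
    a morphological lineage truncated at a sampled rank and possibly
    misidentified (cross-genus swap at the reported rank).  Returns the
    specimens and a truth ledger.
    """
    config.validate()
    if truth is None:
        truth = generate_truth(config)
    if n is None:
        n = config.n_queries
    rng = np.random.default_rng([config.seed, 2])
    weights = _abundance_weights(len(truth.species), config.abundance_skew)
    species_arr = np.asarray(truth.species, dtype=object)
    rank_labels = list(config.morph_rank_distribution)
    rank_probs = np.asarray([config.morph_rank_distribution[r] for r in rank_labels])

    specimens: list[QuerySpecimen] = []
    ledger_rows = []
    for i in range(1, n + 1):
        true_species = str(rng.choice(species_arr, p=weights))
        sequence: Optional[str] = None
        fragment = False
        if rng.random() >= config.sequencing_failure_rate:
            hap = _mutate(truth.ancestors[true_species], config.intraspecific_divergence, rng)
            sequence = _to_str(hap)
            if rng.random() < config.fragment_rate:
                fragment = True
                sequence = sequence[: config.fragment_length_bp]

        morph_rank = Rank.from_label(str(rng.choice(rank_labels, p=rank_probs)))
        misid = bool(rng.random() < config.morph_misid_rate)
        source_species = true_species
        if misid:
            if morph_rank is Rank.SPECIES or morph_rank is Rank.GENUS:
                swap = _confamilial_swap(truth, true_species, rng)
            else:
                swap = _other_at_rank(truth, true_species, morph_rank, rng)
            if swap is None:
                misid = False
            else:
                source_species = swap
        morph = truth.lineages[source_species].truncated(morph_rank)

        stage = str(rng.choice(["larva", "pupa", "adult"], p=[0.8, 0.1, 0.1]))
        specimen_id = f"Q{i:04d}"
        specimens.append(
            QuerySpecimen(
                specimen_id=specimen_id,
                morph_lineage=morph,
                sequence=sequence,
                life_stage=stage,
                country_of_origin=str(rng.choice(_ORIGIN_COUNTRIES)),
                country_of_interception="USA",
            )
        )
        ledger_rows.append(
            {
                "specimen_id": specimen_id,
                "true_species": true_species,
                "morph_rank": morph_rank.label,
                "morph_name": str(morph),
                "misidentified": misid,
                "sequenced": sequence is not None,
                "fragment": fragment,
            }
        )
    return specimens, pd.DataFrame(ledger_rows)


def write_outputs(
    outdir,
    records: Sequence[ReferenceRecord],
    queries: Sequence[QuerySpecimen],
    library_ledger: pd.DataFrame,
    query_ledger: pd.DataFrame,
    config: SimulationConfig,
) -> None:
    """Emit the library/query FASTA+TSV dialect plus truth ledgers and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_library(records, outdir / "library.fasta", outdir / "library.tsv")
    write_queries(queries, outdir / "queries.fasta", outdir / "queries.tsv")
    library_ledger.to_csv(outdir / "library_truth.tsv", sep="\t", index=False)
    query_ledger.to_csv(outdir / "query_truth.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "config.yaml")
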