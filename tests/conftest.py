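"""Shared fixtures: small seeded simulations and handcrafted sequence sets."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from barcodeaudit.synthetic import (
    SimulationConfig,
    generate_library,
    generate_queries,
    generate_truth,
)


def make_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate_at(seq: str, positions, offset: int = 1) -> str:
    """Deterministically substitute the given positions (cyclic base shift)."""
    bases = "ACGT"
    out = list(seq)
    for p in positions:
        out[p] = bases[(bases.index(out[p]) + offset) % 4]
    return "".join(out)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast four-year growth scenario: 12 species, short sequences."""
    return SimulationConfig(
        seed=7,
        n_families=3,
        genera_per_family=2,
        species_per_genus=2,
        seq_length_bp=520,
        years=(2009, 2010, 2011, 2012),
        records_per_year=(6, 6, 6, 6),
        public_fraction_by_year=(0.5, 0.5, 0.5, 0.5),
        n_queries=40,
        fragment_length_bp=407,
        sequencing_failure_rate=0.1,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    truth = generate_truth(small_config)
    records, lib_ledger = generate_library(small_config, truth)
    queries, q_ledger = generate_queries(small_config, truth)
    return {
        "config": small_config,
        "truth": truth,
        "records": records,
        "library_ledger": lib_ledger,
        "queries": queries,
        "query_ledger": q_ledger,
    }


@pytest.fixture(scope="session")
def recovery_config() -> SimulationConfig:
    """Parameter-recovery conditions: complete species-level public library.

    Intraspecific divergence is kept at 0.002 so conspecific identity sits
    safely above the 98% threshold and the check isolates the classifier
    rather than threshold-tail behaviour; the morphological rank
    distribution has no order-level mass because an order-level
    misidentification cannot be expressed in a one-order taxonomy.
    """
    return SimulationConfig(
        seed=11,
        n_families=3,
        genera_per_family=3,
        species_per_genus=3,
        seq_length_bp=658,
        intraspecific_divergence=0.002,
        years=(2019,),
        records_per_year=(54,),
        public_fraction_by_year=(1.0,),
        morph_rank_distribution={
            "order": 0.0,
            "superfamily": 0.05,
            "family": 0.40,
            "subfamily": 0.05,
            "genus": 0.10,
            "species": 0.40,
        },
        morph_misid_rate=0.1,
        sequencing_failure_rate=0.0,
        fragment_rate=0.065,
        fragment_length_bp=407,
        library_species_fraction=1.0,
        abundance_skew=0.0,
        ensure_species_coverage=True,
    )


@pytest.fixture(scope="session")
def clean_library(recovery_config):
    """Complete, correctly identified, species-level, public library."""
    cfg = dataclasses.replace(recovery_config, morph_misid_rate=0.0)
    truth = generate_truth(cfg)
    records, ledger = generate_library(cfg, truth)
    assert not ledger["misidentified"].any()
    # coverage really is complete
    assert set(ledger["true_species"]) == set(truth.species)
    return truth, records
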