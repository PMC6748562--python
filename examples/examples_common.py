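"""Shared small study used by the example scripts (kept tiny so each runs in seconds)."""

from barcodeaudit import SimulationConfig, generate_library, generate_queries, generate_truth


def small_study():
    config = SimulationConfig(
        seed=7,
        n_families=3,
        genera_per_family=2,
        species_per_genus=2,
        seq_length_bp=520,
        years=(2009, 2010, 2011, 2012),
        records_per_year=(6, 6, 6, 6),
        public_fraction_by_year=(0.5,) * 4,
        n_queries=40,
        fragment_length_bp=407,
        sequencing_failure_rate=0.1,
    )
    truth = generate_truth(config)
    records, _ = generate_library(config, truth)
    queries, _ = generate_queries(config, truth)
    return records, queries, config
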