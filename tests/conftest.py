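"""Shared fixtures: small seeded synthetic datasets with ground truth."""

import pytest

from brine18s import synthetic_data as synth


@pytest.fixture(scope="session")
def small_panel():
    """Six kingdoms x two members, 400-nt templates."""
    return synth.generate_reference_panel(
        n_kingdoms=6,
        per_kingdom=2,
        seq_length=400,
        inter_kingdom_divergence=0.30,
        intra_kingdom_divergence=0.03,
        seed=5,
    )


@pytest.fixture(scope="session")
def violation_run(small_panel):
    """700 reads (100/sample) with 10% of each planted violation class."""
    config = synth.default_config(
        n_reads=100,
        seed=17,
        false_amplicon_fraction=0.10,
        short_read_fraction=0.10,
        ambiguous_base_fraction=0.10,
        homopolymer_fraction=0.10,
        lowq_fraction=0.10,
    )
    reads, truth = synth.simulate_reads(small_panel, config)
    return config, reads, truth


@pytest.fixture(scope="session")
def clean_run(small_panel):
    """350 violation-free reads (50/sample)."""
    config = synth.default_config(n_reads=50, seed=23)
    reads, truth = synth.simulate_reads(small_panel, config)
    return config, reads, truth
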