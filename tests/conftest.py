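"""Shared fixtures: the toy nested-gap alignment, small metadata tables, and
the planted-diagnostics simulation used by the end-to-end checks."""

from __future__ import annotations

import pytest

from indelbarcode import AlignedLocus, SampleMetadata, SimulationConfig
from indelbarcode.io_formats import MetadataRecord


@pytest.fixture
def toy_locus() -> AlignedLocus:
    """Four sequences, 12 columns, a 4-column gap nested inside an 8-column gap."""
    return AlignedLocus(
        locus_name="toy",
        ids=("s1", "s2", "s3", "s4"),
        rows=(
            "ACGTACGTACGT",
            "ACGT----ACGT",
            "ACGT----ACGT",
            "AC--------GT",
        ),
    )


@pytest.fixture
def toy_meta() -> SampleMetadata:
    return SampleMetadata(
        records=(
            MetadataRecord("s1", "p1", "spA"),
            MetadataRecord("s2", "p1", "spA"),
            MetadataRecord("s3", "p2", "spB"),
            MetadataRecord("s4", "p2", "spB"),
        )
    )


@pytest.fixture(scope="session")
def planted_config() -> SimulationConfig:
    """Planted species-diagnostic indels with weak substitution signal and
    homoplasious mononucleotide slippage: the conditions under which indel
    coding should out-resolve complete deletion."""
    return SimulationConfig(
        n_species=4,
        pops_per_species=(3, 3),
        inds_per_pop=(2, 2),
        locus_lengths={"loc": 600},
        diagnostic_indels_per_species=3,
        diagnostic_indel_length=(4, 12),
        stem_sub_prob=0.0003,
        pop_sub_prob=0.001,
        tip_sub_prob=0.0005,
        slippage_sites_per_locus=3,
        slippage_rate=0.1,
        seed=5,
    )


@pytest.fixture(scope="session")
def planted_dataset(planted_config):
    from indelbarcode import simulate_dataset

    return simulate_dataset(planted_config)
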