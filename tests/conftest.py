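"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from tealgen.models import DemographicModel, SimConfig
from tealgen.simulate import GenotypeMatrix, SequenceAlignment, simulate_dataset


@pytest.fixture(scope="session")
def study_model() -> DemographicModel:
    """The best-supported divergence model at its point estimates."""
    return DemographicModel(
        theta_es=16388.0,
        theta_iq=48654.0,
        t_div=407.0,
        theta_anc=3225.0,
        migration=((0.0, 8.71e-7), (8.71e-7, 0.0)),
    )


@pytest.fixture(scope="session")
def small_dataset(study_model) -> GenotypeMatrix:
    """A reduced two-deme SNP panel with missing calls (seeded)."""
    cfg = SimConfig(
        seed=11,
        n_loci=12_000,
        locus_length=140,
        missing_rate=0.08,
        samples_per_deme=(12, 6),
    )
    return simulate_dataset(study_model, cfg)


@pytest.fixture()
def toy_matrix() -> GenotypeMatrix:
    """Hand-written 4x5 matrix with known missingness and locus grouping."""
    calls = np.array(
        [
            [0, 1, 2, -1, 1],
            [1, 1, -1, -1, 0],
            [0, 0, 2, 1, 0],
            [2, 1, 2, 0, 1],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        calls=calls,
        locus_ids=np.array([0, 0, 0, 1, 2]),
        individual_ids=["i1", "i2", "i3", "i4"],
        populations=["A", "A", "B", "B"],
    )


@pytest.fixture()
def toy_alignment() -> SequenceAlignment:
    """Six sequences, three distinct haplotypes, two populations."""
    return SequenceAlignment(
        sequences=["AACGT", "AACGT", "AACTT", "AACTT", "GACTT", "AACGT"],
        sample_ids=[f"s{i}" for i in range(6)],
        populations=["P1", "P1", "P1", "P2", "P2", "P2"],
    )
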