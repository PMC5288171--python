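import numpy as np
import pytest

from prmverify import (
    GeneratorConfig,
    PeptideSpec,
    generate_reference_library,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_specs():
    """A 6-peptide / 4-protein panel spanning strong, moderate and null
    effects (quartiles from the published verification table plus two
    non-differential fillers)."""
    return (
        PeptideSpec("PERM", "IANVFTNAFR", 0.56, 2.18, 0.04, 0.13),
        PeptideSpec("PERM", "VVLEGGIDPILR", 0.94, 4.00, 0.08, 0.29),
        PeptideSpec("CADH1", "VFYSITGQGADTPPVGVFIIER", 0.55, 1.27, 0.11, 0.28),
        PeptideSpec("SPIT1", "SFVYGGCLGNK", 0.33, 0.66, 0.07, 0.20),
        PeptideSpec("NULL1", "NULLPEPTIDEA", 0.60, 1.60, 0.60, 1.60),
        PeptideSpec("NULL1", "NULLPEPTIDEB", 0.60, 1.60, 0.60, 1.60),
    )


@pytest.fixture(scope="session")
def small_library(small_specs):
    return generate_reference_library(small_specs, seed=11)


@pytest.fixture(scope="session")
def noise_free_dataset(small_specs, small_library):
    config = GeneratorConfig(
        peptide_specs=small_specs,
        n_tumor=8,
        n_control=6,
        prep_cv=0.0,
        interference_rate=0.0,
        lod_floor=0.0,
        seed=7,
    )
    return simulate_cohort(config, small_library)


@pytest.fixture
def rng():
    return np.random.default_rng(20160716)
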