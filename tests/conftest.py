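import pytest

from sineanchor.core import read_regions, read_repeats
from sineanchor.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """Default-condition synthetic dataset shared across the suite."""
    cfg = SyntheticConfig(seed=11)
    return generate_dataset(cfg, tmp_path_factory.mktemp("dataset"))


@pytest.fixture(scope="session")
def peaks(dataset):
    return read_regions(dataset.peaks_narrowpeak, "narrowpeak")


@pytest.fixture(scope="session")
def repeats(dataset):
    return read_repeats(dataset.elements_bed, "bed6_family")


@pytest.fixture(scope="session")
def b1_elements(repeats):
    return [r for r in repeats if r.subfamily == "B1"]


@pytest.fixture(scope="session")
def clean_motif_dataset(tmp_path_factory):
    """Small dataset with no mutations and certain motif planting, for exact
    motif-anatomy recovery."""
    cfg = SyntheticConfig(
        seed=23,
        genome={"chr1": 500_000, "chr2": 350_000},
        n_peaks=150,
        n_elements=200,
        n_decoy_elements=30,
        mutation_rate=0.0,
        plant_prob=1.0,
    )
    return generate_dataset(cfg, tmp_path_factory.mktemp("clean_motifs"))
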