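import pytest

from hifisim.fixtures import MockCommunitySpec, generate_community
from hifisim.io_formats import RunConfig

PRIMER_27F = "AGRGTTYGATYMTGGCTCAG"
PRIMER_1492R = "RGYTACCTTGTTACGACTT"


@pytest.fixture(scope="session")
def primers():
    return PRIMER_27F, PRIMER_1492R


@pytest.fixture(scope="session")
def default_config():
    return RunConfig()


@pytest.fixture(scope="session")
def small_community(primers):
    """3 genomes with 3/2/1 operon copies at 2% intra-genome divergence."""
    spec = MockCommunitySpec(
        n_genomes=3,
        operons_per_genome=[3, 2, 1],
        asv_core_length=300,
        intra_genome_divergence=0.02,
        seed=0,
    )
    genomes, truth = generate_community(spec, *primers)
    return spec, genomes, truth


@pytest.fixture(scope="session")
def separated_community(primers):
    """Genomes with one operon each: cores are independent random DNA, so
    inter-ASV edit distances are large (well-separated references)."""
    spec = MockCommunitySpec(
        n_genomes=6,
        operons_per_genome=[1] * 6,
        asv_core_length=250,
        intra_genome_divergence=0.0,
        seed=5,
    )
    genomes, truth = generate_community(spec, *primers)
    return spec, genomes, truth
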