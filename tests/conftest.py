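import pytest

from burstchrom import assignquant, simgen
from burstchrom.simgen import (
    CHR4_LIKE,
    EUCHROMATIN,
    ChipKernel,
    ChromSpec,
    SimConfig,
    SmallRNAParams,
    TEFamily,
    WGSParams,
)

LENGTH_PROBS = {
    19: 0.01, 20: 0.01, 21: 0.02, 22: 0.05, 23: 0.10, 24: 0.14, 25: 0.17,
    26: 0.18, 27: 0.14, 28: 0.10, 29: 0.04, 30: 0.02, 31: 0.02,
}


def small_config(seed: int = 0) -> SimConfig:
    """Minutes-scale study conditions for unit tests."""
    return SimConfig(
        master_seed=seed,
        chroms=[
            ChromSpec("chrA", 120_000, EUCHROMATIN, het_blocks=[(80_000, 100_000)]),
            ChromSpec("chr4t", 20_000, CHR4_LIKE),
        ],
        families=[TEFamily("alpha", 1500, 0.45), TEFamily("beta", 1200, 0.40)],
        n_insertions={"alpha": 6, "beta": 3},
        timepoints=["t1", "t2"],
        expression_profile={
            ("alpha", "t1"): 0.005,
            ("alpha", "t2"): 0.017,
            ("beta", "t1"): 0.002,
            ("beta", "t2"): 0.004,
        },
        chip=ChipKernel(5.0, 150.0, 3.0, {"t1": 0.3, "t2": 1.0}),
        wgs=WGSParams(400.0, 40.0, 100, 20.0),
        smallrna=SmallRNAParams({"alpha": 0.5, "beta": 0.3}, 0.8, dict(LENGTH_PROBS)),
        min_insertion_spacing=3000,
    )


@pytest.fixture(scope="session")
def cfg():
    return small_config(0)


@pytest.fixture(scope="session")
def genomes(cfg):
    return simgen.build_genome(cfg)


@pytest.fixture(scope="session")
def reference(genomes):
    return genomes[0]


@pytest.fixture(scope="session")
def sample_genome(genomes):
    return genomes[1]


@pytest.fixture(scope="session")
def truth(genomes):
    return genomes[2]


@pytest.fixture(scope="session")
def te_index(reference):
    return assignquant.SeqIndex(reference.te_consensus, 21)


@pytest.fixture(scope="session")
def genome_index(reference):
    return assignquant.SeqIndex(reference.sequences, 21)
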