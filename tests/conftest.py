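import numpy as np
import pytest

import snpatlas as sa

ISOLATES = ["M", "I12", "E2", "S", "I07"]
TOPOLOGY = "((((M,I12),E2),S),I07);"


@pytest.fixture(scope="session")
def small_sim():
    """A scaled-down isolate set (20 kb) with the default event structure."""
    genomes, truth, planted, newick = sa.simulate_isolate_set(seed=11, length=20_000)
    return genomes, truth, planted, newick


@pytest.fixture(scope="session")
def small_msa(small_sim):
    genomes, _, _, _ = small_sim
    others = [genomes[name] for name in ISOLATES if name != "M"]
    return sa.build_reference_msa(genomes["M"], others)


@pytest.fixture(scope="session")
def indel_free_sim():
    """5-genome simulation with substitutions only (10 kb)."""
    model = sa.EvolutionModel(indel_rate=0.0, te_insertions=[])
    genomes, truth, planted, newick = sa.simulate_isolate_set(
        seed=23, length=10_000, model=model
    )
    return genomes, truth, planted, newick


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def random_dna(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
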