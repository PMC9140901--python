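import numpy as np
import pytest
from hypothesis import settings

import mitoforms as mf

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def random_dna(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


@pytest.fixture(scope="session")
def toy_genome_with_direct_repeat():
    """6 kb circle with a planted 300 bp direct repeat at 500 and 3000."""
    spec = mf.SimGenomeSpec(
        genome_length=6000,
        repeat_plants=(mf.RepeatPlant(300, 500, 3000, "direct"),),
        plastid_length=3000,
        seed=42,
    )
    genome, plastid, truth = mf.build_genome(spec)
    return genome, plastid, truth


@pytest.fixture(scope="session")
def toy_confs(toy_genome_with_direct_repeat):
    genome, _, _ = toy_genome_with_direct_repeat
    pair = mf.RepeatPair("R1", 300, (500, 800), (3000, 3300), "direct", 100.0)
    return genome, pair, mf.enumerate_conformations(genome, pair, flank=500)
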