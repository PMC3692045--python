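import numpy as np
import pytest

import kmersvm as kv


@pytest.fixture(scope="session")
def space6():
    return kv.build_feature_space(6)


@pytest.fixture(scope="session")
def space2():
    return kv.build_feature_space(2)


@pytest.fixture(scope="session")
def toy_genome_indexed():
    """2-Mb single-chromosome soft-masked toy genome with its index."""
    genome = kv.generate_toy_genome(
        genome_spec=(kv.ChromosomeSpec("chrA", 2_000_000, 0.10),),
        gc_background=0.42,
        seed=17,
    )
    return genome, kv.build_genome_index(genome)


@pytest.fixture(scope="session")
def small_labeled_sets():
    """Small planted-motif sets shared by fast training tests."""
    cfg = kv.SyntheticConfig(n_pos=80, fold_negatives=3, seed=23)
    return kv.generate_labeled_sets(cfg)


def random_sequences(rng: np.random.Generator, n: int, length: int) -> list[str]:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [
        bases[rng.integers(0, 4, size=length)].tobytes().decode() for _ in range(n)
    ]
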