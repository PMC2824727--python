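import random

import pytest

from bacomap.rearrange import SignedGenome
from bacomap.simulate import SimConfig


def random_genome(rng: random.Random, n: int, max_chrom: int = 3) -> SignedGenome:
    """Uniform-ish random signed genome over segments 1..n."""
    ids = list(range(1, n + 1))
    rng.shuffle(ids)
    ids = [i if rng.random() < 0.5 else -i for i in ids]
    nch = rng.randint(1, min(max_chrom, n))
    cuts = sorted(rng.sample(range(1, n), nch - 1)) if nch > 1 else []
    chroms, prev = [], 0
    for c in cuts + [n]:
        chroms.append(ids[prev:c])
        prev = c
    return SignedGenome(chroms)


def identity_genome(n: int, n_chrom: int) -> SignedGenome:
    per = n // n_chrom
    assert per * n_chrom == n
    return SignedGenome(
        [list(range(i * per + 1, (i + 1) * per + 1)) for i in range(n_chrom)]
    )


@pytest.fixture
def small_sim_config():
    """Three 240 Mb chromosomes, 8 markers each, modest clone count."""
    return SimConfig(
        n_chromosomes=3,
        chrom_lengths=(240_000_000,) * 3,
        n_clones=120,
        seed=42,
    )


@pytest.fixture
def dense_sim_config():
    """Five chromosomes x 8 markers = 40-marker grid."""
    return SimConfig(
        n_chromosomes=5,
        chrom_lengths=(240_000_000,) * 5,
        n_clones=60,
        seed=7,
    )
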