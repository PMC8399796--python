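import numpy as np
import pytest

from limbtrace.synthetic import SimConfig
from limbtrace.variant_model import make_variant


@pytest.fixture
def small_config() -> SimConfig:
    """A fast trio configuration: 4 small chromosomes, chr3 causal."""
    return SimConfig(
        chromosomes=tuple((f"chr{i}", 2_000_000) for i in range(1, 5)),
        causal_chromosomes=("chr3",),
        father_specific_per_chrom=400,
        mother_specific_per_chrom=400,
        shared_per_chrom=1000,
        seed=42,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def variant(chrom="chr1", pos=100, ref="A", alt="T", zygosity="het",
            depth=20, alt_reads=10, effect="intergenic"):
    """Shorthand for a fully specified variant record."""
    return make_variant(chrom, pos, ref, alt, zygosity, depth, alt_reads, effect)
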