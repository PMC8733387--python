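import pytest
from hypothesis import HealthCheck, settings

import bsamap as b

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def demo_experiment():
    """A paper-style FF x MF experiment with a mid-chromosome sex locus."""
    return b.simulate_bsa_experiment(
        seed=7,
        variants_per_chrom=300,
        chrom_lengths=(("chr1", 10_000_000),),
        sex_locus=("chr1", 5_000_000),
    )


@pytest.fixture(scope="session")
def null_experiment():
    """The same design with the sex trait unlinked to the genome (no locus)."""
    return b.simulate_bsa_experiment(
        seed=11,
        variants_per_chrom=300,
        chrom_lengths=(("chr1", 10_000_000),),
        sex_locus=None,
    )
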