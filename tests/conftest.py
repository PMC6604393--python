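import numpy as np
import pytest

from repmethyl import Replicon, RepliconSpec, build_replicon, simulate_bisulfite_reads


@pytest.fixture(scope="session")
def small_build():
    """Compact replicon: 5-repeat array, small desert, sparse GGCC background."""
    spec = RepliconSpec(
        name="mini",
        length=20_000,
        array_start=8_000,
        n_repeats=5,
        desert_interval=(1_000, 4_000),
        planted_cgatcg={500: 0.02, 15_000: 0.95},
        cas_region=None,
        low_repeats={2: 0.5},
        seed=42,
    )
    return spec, *build_replicon(spec)


@pytest.fixture(scope="session")
def small_reads(small_build):
    spec, rep, truth, ann = small_build
    return simulate_bisulfite_reads(rep, truth, coverage=100, read_len=100,
                                    conversion_rate=0.99, error_rate=0.0, seed=7)


@pytest.fixture(scope="session")
def default_build():
    """Full-size study-condition replicon (103 kb, 50 repeats, 11 kb desert)."""
    spec = RepliconSpec(seed=11)
    return spec, *build_replicon(spec)


def random_replicon(rng, n, circular=False, name="r"):
    seq = "".join(rng.choice(list("ACGT"), size=n))
    return Replicon(name, seq, circular=circular)
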