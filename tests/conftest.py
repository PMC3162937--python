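import pytest

from sstea.profiles import build_all_profiles, calibrate_thresholds
from sstea.simulate import conserved_seed_alignment, default_spec, generate_msa


@pytest.fixture(scope="session")
def seed_alignment():
    """A conserved synthetic family standing in for the curated seed MSA."""
    return conserved_seed_alignment(n=30, mutation_rate=0.2, seed=11)


@pytest.fixture(scope="session")
def profiles(seed_alignment):
    return build_all_profiles(seed_alignment)


@pytest.fixture(scope="session")
def thresholds(profiles):
    # modest calibration sample: cutoffs are stable well below the default
    return calibrate_thresholds(profiles, n_artificial=400, rng_seed=5)


@pytest.fixture(scope="session")
def synthetic_msa():
    """Default planted-structure MSA: 10 subfamilies of 60, focal subfamily
    carries 5 binding columns; plus its truth table."""
    return generate_msa(default_spec(seed=1))
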