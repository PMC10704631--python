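import numpy as np
import pytest

from strainshift.io_filters import SampleRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_paired_samples(n_pairs: int, n_locations: int = 5,
                        dna_yield: float = 10.0) -> list[SampleRecord]:
    """n_pairs colonies spread over n_locations, one nurse + one forager each."""
    samples = []
    for i in range(n_pairs):
        colony = f"L{i % n_locations + 1}C{i + 1}"
        location = f"L{i % n_locations + 1}"
        for state, prefix in (("nurse", "N"), ("forager", "F")):
            samples.append(
                SampleRecord(
                    sample_id=f"{prefix}_{colony}",
                    state=state,
                    colony_id=colony,
                    location_id=location,
                    n_guts=10,
                    pool_mass=100.0,
                    dna_yield=dna_yield,
                )
            )
    return samples


@pytest.fixture
def paired_samples():
    return make_paired_samples(15)
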