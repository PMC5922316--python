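import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mutpatterns as mp

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_genome():
    """Tiny hand-written genome for exact classification checks."""
    return mp.ReferenceGenome({"chr1": "TACGA", "chr2": "TAGCA"})


@pytest.fixture(scope="session")
def random_genome():
    """Seeded 60 kb genome covering all trinucleotide contexts."""
    return mp.make_genome({"chrA": 40_000, "chrB": 20_000}, gc=0.5, seed=123)


@pytest.fixture(scope="session")
def separated_signatures():
    """Three peaked, well-separated synthetic signatures."""
    return mp.make_signature_set(3, seed=7, concentration=0.05)


@pytest.fixture(scope="session")
def small_cohort(random_genome, separated_signatures):
    """Five small catalogues simulated from known mixtures."""
    rng = np.random.default_rng(17)
    weights = rng.dirichlet([0.5] * 3, size=5)
    catalogues = []
    for i in range(5):
        cat, _ = mp.simulate_catalogue(
            random_genome,
            separated_signatures,
            weights[i],
            500,
            sample_id=f"s{i + 1}",
            seed=100 + i,
        )
        catalogues.append(cat)
    return catalogues, weights
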