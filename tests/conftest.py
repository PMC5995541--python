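import numpy as np
import pytest

from riboprox import SimulationSpec, simulate_all
from riboprox.models import FootprintProfile, SamplePair


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded end-to-end dataset shared across tests."""
    return simulate_all(SimulationSpec(n_genes=60, rng_seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_profile(gene_id, sample_id, counts, total=None):
    counts = np.asarray(counts, dtype=float)
    return FootprintProfile(
        gene_id=gene_id,
        sample_id=sample_id,
        counts=counts,
        sample_total_mapped=float(total if total is not None else max(counts.sum(), 1.0)),
    )


def make_pair(bait="b", rep="rep1"):
    return SamplePair(
        bait_id=bait,
        replicate_id=rep,
        pulldown_sample=f"{bait}_{rep}_pulldown",
        input_sample=f"{bait}_{rep}_input",
    )
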