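import numpy as np
import pytest

from epistate import benchmarks
from epistate.synthetic import SyntheticConfig, generate_world


@pytest.fixture(scope="session")
def tiny_world():
    """Small noise-free world for fast unit tests (not for training)."""
    return generate_world(
        SyntheticConfig(
            genome_length=30_000,
            occurrences_per_motif=6,
            noise_sd=0.0,
            mask_density=0.5,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def celltype_result():
    """Cell-type specificity benchmark: tiny split-head model trained with
    ~10% of (locus, cell) pairs held out of the reference world."""
    return benchmarks.run_celltype_benchmark(seed=0)


@pytest.fixture(scope="session")
def unseen_track_result():
    """Unseen-track recovery: one predictable track held out of training on
    a noise-free world, compared against the trained-in fit."""
    return benchmarks.run_unseen_track_benchmark(seed=0)


@pytest.fixture(scope="session")
def variant_result():
    """Motif-competent model on the controlled-background world plus the
    motif-vs-background variant cohorts."""
    return benchmarks.run_variant_benchmark(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
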