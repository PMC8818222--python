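import pytest

from csfcirc.simulate import CohortConfig, simulate_cohort

SMALL = dict(
    n_patients=8,
    missing_samples=(),
    n_genes=40,
    n_circ_total=60,
    n_candidates_true=6,
    n_brain_listed=12,
    decoys_per_sample=10,
    n_mirna_decoys=8,
    chrom_lengths=(("chr1", 100_000), ("chr2", 80_000), ("chr3", 60_000)),
)


def small_config(seed=0, **overrides):
    kwargs = dict(SMALL)
    kwargs.update(overrides)
    return CohortConfig(seed=seed, **kwargs)


@pytest.fixture(scope="session")
def cohort():
    """A small deterministic cohort shared by read-only tests."""
    return simulate_cohort(small_config(seed=11))


@pytest.fixture
def config_factory():
    return small_config
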