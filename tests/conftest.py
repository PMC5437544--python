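import pytest
from hypothesis import HealthCheck, settings

from cladefill.experiments import run_hidden_gene_discovery
from cladefill.synthetic import CladeSpec, generate_clade

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_clade():
    """A tiny 3-species clade for fast unit-level pipeline tests."""
    return generate_clade(
        CladeSpec(n_species=3, n_families=6, n_hidden=2, seed=11)
    )


@pytest.fixture(scope="session")
def e2e_clade():
    """The full noise-free recovery fixture: 3 species, 20 families, 5 hidden."""
    return generate_clade(
        CladeSpec(n_species=3, n_families=20, n_hidden=5, seed=7)
    )


@pytest.fixture(scope="session")
def e2e_run(e2e_clade):
    """One full pipeline run (profile-HMM search included) shared by tests."""
    return run_hidden_gene_discovery(e2e_clade)
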