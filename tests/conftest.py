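import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from drynet.simulate import SynthConfig, generate_dataset  # noqa: E402


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic study (74 metabolites, 2000 genes), fixed seed."""
    return generate_dataset(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def small_noise_free_config():
    """Tiny noise-free design: one always-coupled module of 3, loading 1."""
    from drynet.simulate import ModuleSpec
    return SynthConfig(
        seed=7, n_metabolites=6, n_genes=12, noise_sd=0.0,
        modules=(ModuleSpec("m1", size=3, loading=1.0,
                            treatment_coupling="both", linked_gene_count=2),),
        regulon_size=4,
    )
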