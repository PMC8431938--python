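import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded synthetic cohort shared across tests."""
    from germex.synthetic_data import SimulationConfig, generate_cohort
    return generate_cohort(SimulationConfig(seed=11, n_samples=800, n_variants=200))


@pytest.fixture
def toy_variants():
    return pd.DataFrame([
        {"chrom": "1", "pos": 100, "ref": "G", "alt": "A", "build": "GRCh37",
         "gene": "GENE_A", "function_class": "nonsense", "traits": "Myopathy",
         "classification": "P", "inheritance": "AR", "af": 1e-5},
        {"chrom": "2", "pos": 200, "ref": "C", "alt": "T", "build": "GRCh37",
         "gene": "GENE_B", "function_class": "missense",
         "traits": "Deafness, autosomal recessive", "classification": "LP",
         "inheritance": "AD", "af": 2e-5},
    ])
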