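import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_genotype_matrix(values, ids=None, chroms=None, positions=None, alleles=None):
    """Small GenotypeMatrix from a raw dosage array."""
    from ethnoprs.genio import GenotypeMatrix

    values = np.asarray(values, dtype=float)
    n, m = values.shape
    ids = ids or [f"rs{j}" for j in range(m)]
    chroms = chroms or ["1"] * m
    positions = positions or list(range(100, 100 + m))
    alleles = alleles or [("A", "G")] * m
    variants = pd.DataFrame(
        {
            "id": ids,
            "chrom": chroms,
            "pos": positions,
            "allele_effect": [a for a, _ in alleles],
            "allele_other": [b for _, b in alleles],
        }
    )
    samples = pd.DataFrame(
        {"id": [f"s{i}" for i in range(n)], "reported_sex": ["unknown"] * n}
    )
    return GenotypeMatrix(values, variants, samples)


@pytest.fixture
def toy_genotypes():
    rng = np.random.default_rng(11)
    return make_genotype_matrix(rng.binomial(2, 0.3, size=(30, 8)).astype(float))


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated population reused across read-only tests."""
    from ethnoprs.synthetic import SimulationConfig, simulate_study

    cfg = SimulationConfig(n_variants=600, n_causal=40, target_h2=0.5, fst=0.1, seed=7)
    return simulate_study(cfg, n_samples=[400], case_fractions=[0.3])[0]
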