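import numpy as np
import pandas as pd
import pytest

from breedgwas import GenotypeMatrix, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """10 breeds x 15 samples, 300 SNPs, mild missingness — general-purpose."""
    cfg = SimulationConfig(
        n_breeds=10, samples_per_breed=15, n_snps=300, missing_rate=0.03, seed=11
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def study_cohort():
    """Default-scale cohort: 63 breeds, the design the pipeline emulates."""
    cfg = SimulationConfig(seed=7)
    return simulate_cohort(cfg)


def toy_genotypes(dosages, chroms=None, positions=None, breeds=None):
    """Hand-built GenotypeMatrix from a plain dosage array."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    snps = pd.DataFrame(
        {
            "snp": [f"s{j}" for j in range(m)],
            "chrom": chroms if chroms is not None else ["1"] * m,
            "pos": positions if positions is not None else np.arange(1, m + 1) * 1000,
            "a1": ["A"] * m,
            "a2": ["G"] * m,
        }
    )
    samples = pd.DataFrame(
        {
            "sample": [f"i{i}" for i in range(n)],
            "breed": breeds if breeds is not None else ["b1"] * n,
        }
    )
    return GenotypeMatrix(d, snps, samples)
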