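import numpy as np
import pandas as pd
import pytest

from bvsmap.geno_io import GenotypeDataset


def make_snp_map(p, chrom="1", spacing=1000, start=1000):
    return pd.DataFrame(
        {
            "snp_id": [f"snp_{j}" for j in range(p)],
            "chrom": chrom,
            "pos_bp": start + spacing * np.arange(p),
            "allele_ref": "A",
            "allele_alt": "B",
        }
    )


def random_dataset(n, p, seed=0, freq_range=(0.1, 0.9)):
    """Linkage-equilibrium dosage panel with common alleles only."""
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*freq_range, size=p)
    dos = rng.binomial(1, freqs, size=(n, p)) + rng.binomial(1, freqs, size=(n, p))
    return GenotypeDataset(dos.astype(float), make_snp_map(p))


@pytest.fixture(scope="session")
def ld_panel():
    """Small LD-structured panel shared across tests."""
    from bvsmap.simulate import SimulationScenario, simulate_genotypes

    scn = SimulationScenario(
        n_samples=600, n_snps=800, n_causal=10, h2=0.5, seed=123
    )
    ds = simulate_genotypes(scn)
    keep = ds.maf() > 0.01
    return ds.take_snps(np.flatnonzero(keep))
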