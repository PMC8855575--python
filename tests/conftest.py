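import numpy as np
import pandas as pd
import pytest

from zeapop import simulate as sim
from zeapop.genotypes import GenotypeMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """Four-population cohort, small genome, reused across read-only tests."""
    return sim.simulate_cohort(n_snps=3000, n_chrom=3,
                               chrom_length_bp=5_000_000,
                               missing_rate=0.05, seed=11)


@pytest.fixture(scope="session")
def clean_cohort():
    """No-missingness cohort for phase/haplotype identities."""
    return sim.simulate_cohort(n_snps=1500, n_chrom=2,
                               chrom_length_bp=3_000_000,
                               missing_rate=0.0, seed=21)


def make_gm(dosage, haplotypes=None, chrom="chr1", start_pos=100, spacing=1000):
    """Small hand-built GenotypeMatrix from a dosage array."""
    dosage = np.asarray(dosage, dtype=np.float32)
    n, m = dosage.shape
    variants = pd.DataFrame({
        "chrom": chrom,
        "pos": start_pos + spacing * np.arange(m),
        "id": [f"s{j}" for j in range(m)],
        "ref": "A",
        "alt": "T",
    })
    samples = [f"ind{i}" for i in range(n)]
    return GenotypeMatrix(samples, variants, dosage, haplotypes)
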