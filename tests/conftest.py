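import numpy as np
import pandas as pd
import pytest

from regiongwas.io import StudyGenotypes, variant_frame
from regiongwas.simulate import build_haplotype_pool


@pytest.fixture(scope="session")
def small_pool():
    """A modest shared haplotype pool (400 haplotypes x 300 SNPs)."""
    return build_haplotype_pool(n_hap=400, n_snp=300, block_len=25, seed=7)


@pytest.fixture
def study_factory():
    """Build a StudyGenotypes directly from a dosage matrix."""

    def make(dosage, phenotype=None, sex=None, age=50.0, seed=0,
             chrom="1", spacing=1000):
        dosage = np.asarray(dosage, dtype=np.int8)
        n, m = dosage.shape
        rng = np.random.default_rng(seed)
        if phenotype is None:
            phenotype = np.where(np.arange(n) < n // 2, "case", "control")
        if sex is None:
            sex = rng.choice(["male", "female"], n)
        samples = pd.DataFrame({
            "sid": [f"s{i:04d}" for i in range(n)],
            "phenotype": phenotype, "sex": sex, "age": age, "study": "t",
        })
        variants = variant_frame([chrom] * m, (np.arange(m) + 1) * spacing,
                                 [f"v{j}" for j in range(m)],
                                 ["A"] * m, ["G"] * m)
        return StudyGenotypes(samples, variants, dosage)

    return make
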