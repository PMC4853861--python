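import numpy as np
import pandas as pd
import pytest

from eqtldecon.intervals import IntervalSet
from eqtldecon.simulate import SimulationConfig, make_planted_study, simulate_study
from eqtldecon.types import GenotypeMatrix


@pytest.fixture(scope="session")
def planted_study():
    """A synthetic study with 5 planted GWAS->proxy->enhancer->gene chains,
    decoy inactive genes and HLA-excluded index SNPs."""
    return simulate_study(make_planted_study(seed=1))


@pytest.fixture(scope="session")
def null_study():
    """A study with no planted effects, independent SNPs."""
    cfg = SimulationConfig(n_samples=200, n_snps=200, n_genes=50,
                           ld_blocks=((1, 0.0),), seed=7)
    return simulate_study(cfg)


def make_geno(dosage_array, chroms, positions, sample_prefix="s",
              n_alleles=None):
    """Build a GenotypeMatrix from a raw array and metadata lists."""
    dosage_array = np.asarray(dosage_array)
    n, m = dosage_array.shape
    snp_ids = [f"snp{j}" for j in range(m)]
    snps = pd.DataFrame({
        "chrom": chroms, "pos": positions,
        "ref": "A", "alt": "G",
        "n_alleles": n_alleles if n_alleles is not None else [2] * m,
    }, index=pd.Index(snp_ids, name="snp"))
    dosages = pd.DataFrame(dosage_array,
                           index=[f"{sample_prefix}{i}" for i in range(n)],
                           columns=snp_ids)
    return GenotypeMatrix(dosages=dosages, snps=snps)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=100_000,
                     max_len=5_000, with_score=False):
    starts = rng.integers(0, max_pos, size=n)
    lengths = rng.integers(1, max_len, size=n)
    df = pd.DataFrame({
        "chrom": rng.choice(chroms, size=n),
        "start": starts, "end": starts + lengths,
        "name": [f"iv{i}" for i in range(n)],
    })
    if with_score:
        df["score"] = rng.uniform(0, 10, size=n)
    return IntervalSet(df)
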