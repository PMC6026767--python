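import numpy as np
import pandas as pd
import pytest

from poolsweep import simulate


@pytest.fixture
def tiny_config():
    """One short linkage group, two small pools per group, fixed seed."""
    return simulate.SimulationConfig(
        seed=7,
        n_linkage_groups=1,
        lg_length_bp=100_000,
        snp_density=0.005,
        n_genes=40,
        gene_length_bp=1_000,
        pools=[
            simulate.PoolSpec("o1", "orchard", 10, 12.0),
            simulate.PoolSpec("w1", "wild_north", 10, 12.0),
        ],
    )


@pytest.fixture
def site_table():
    """Hand-built per-pool counts covering filter edge cases."""
    return pd.DataFrame({
        "chrom": ["lg1"] * 6,
        "pos": [10, 20, 30, 40, 50, 60],
        "ref_allele": list("AACCGT"),
        "alt_allele": list("CCAATG"),
        "ref_count": [3, 8, 10, 0, 5, 12],
        "alt_count": [2, 2, 0, 9, 5, 4],
        "pool_id": ["p1"] * 6,
    })


def make_genotype_matrix(genotypes, groups, chrom="lg1", start_pos=1):
    """Helper: wrap a plain list-of-lists genotype table."""
    from poolsweep.validation import GenotypeMatrix

    gt = np.asarray(genotypes, dtype=np.int8)
    n_sites = gt.shape[1]
    return GenotypeMatrix(
        genotypes=gt,
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=np.arange(start_pos, start_pos + n_sites, dtype=np.int64),
        samples=[f"s{i}" for i in range(gt.shape[0])],
        groups=list(groups),
    )
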