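import numpy as np
import pandas as pd
import pytest

from regulatlas.datatypes import GenotypeMatrix


def make_genotypes(dosages, positions=None, chrom="1", sample_ids=None):
    """Build a GenotypeMatrix from an explicit dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=0) / 2.0
    freq = np.where(np.isnan(freq), 0.0, freq)
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=int),
            "ref": "A",
            "alt": "T",
            "maf": np.minimum(freq, 1 - freq),
            "missing_rate": np.isnan(dosages).mean(axis=0),
        }
    )
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(sample_ids, dosages, variants)


def orthogonal_dosage_matrix(n_bits: int) -> np.ndarray:
    """2^n_bits samples x n_bits columns of exactly uncorrelated 0/2 dosages."""
    n = 2**n_bits
    cols = [(np.arange(n) >> b) & 1 for b in range(n_bits)]
    return np.asarray(cols, dtype=float).T * 2.0


@pytest.fixture(scope="session")
def small_scenario():
    """A compact multi-tissue scenario with planted truth, reused read-only."""
    import regulatlas as ra

    G = ra.simulate_genotypes(200, 600, block_size=40, switch_prob=0.15, n_subpops=2, seed=11)
    expr, truth = ra.simulate_expression(
        G,
        tissues=("RT", "SH", "LB"),
        n_genes=120,
        cis_fraction=0.25,
        effect_size=1.0,
        n_specific_per_tissue=4,
        specific_fold=8.0,
        seed=11,
    )
    return G, expr, truth
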