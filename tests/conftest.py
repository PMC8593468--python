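import numpy as np
import pandas as pd
import pytest

from cnvherit import SimConfig, SnpPanel, simulate_population


@pytest.fixture(scope="session")
def small_population():
    """One modest population reused across read-only tests."""
    cfg = SimConfig(
        n_animals=400, n_snps=600, n_chrom=5, n_cnv_loci=20, seed=11,
        n_ped_pairs=60, var_snp=0.6, var_cnv=0.05, var_total_genetic=1.0,
    )
    return cfg, simulate_population(cfg)


@pytest.fixture()
def tiny_panel():
    """Hand-built 4-animal x 5-SNP panel with known genotypes."""
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(5)],
            "chrom": [1, 1, 1, 2, 2],
            "pos_bp": [100, 200, 300, 100, 200],
            "index": range(5),
        }
    )
    geno = np.array(
        [
            [0, 1, 2, 0, 1],
            [2, 1, 0, 1, 1],
            [1, 1, 1, 2, 0],
            [0, 0, 2, 2, 2],
        ],
        dtype=float,
    )
    return SnpPanel(np.array([f"a{i}" for i in range(4)], object), geno, snp_map)


def make_grm_from_snps(n, m, rng, maf=(0.1, 0.5)):
    """Simulated-SNP GRM for the variance-component tests."""
    p = rng.uniform(*maf, m)
    geno = rng.binomial(2, p, size=(n, m)).astype(float)
    coded = geno - 1
    freq = (coded.mean(axis=0) + 1) / 2
    het = freq * (1 - freq)
    poly = het > 0
    z = coded[:, poly] - 2 * (freq[poly] - 0.5)
    return z @ z.T / (2 * het[poly].sum())


def make_cnv_grm(n, n_loci, rng, carrier_freq=0.03):
    """GRM from rare CNV loci under carrier-dosage (procedure-1) coding:
    normal state +1, single carrier 0, so the implied allele frequency is
    consistent with the column variance and the mean diagonal is near 1."""
    carrier = rng.binomial(1, carrier_freq, size=(n, n_loci)).astype(float)
    coded = 1.0 - carrier
    freq = (coded.mean(axis=0) + 1) / 2
    het = freq * (1 - freq)
    poly = het > 0
    z = coded[:, poly] - 2 * (freq[poly] - 0.5)
    return z @ z.T / (2 * het[poly].sum())
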