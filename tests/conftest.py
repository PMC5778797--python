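import numpy as np
import pytest

from sweepscan import genotype_io as gio


@pytest.fixture
def small_table() -> gio.GenotypeTable:
    """4 samples x 6 SNPs with mixed calls and one missing cell."""
    rng = np.random.default_rng(1)
    calls = rng.integers(0, 3, size=(4, 6)).astype(np.int8)
    calls[1, 2] = gio.MISSING
    return gio.GenotypeTable(
        sample_ids=[f"s{i}" for i in range(4)],
        populations=["A", "A", "B", "B"],
        snp_ids=[f"m{j}" for j in range(6)],
        chromosomes=["1"] * 3 + ["2"] * 3,
        positions=np.array([100, 200, 300, 100, 250, 400]),
        allele_a=["A"] * 6,
        allele_b=["C"] * 6,
        calls=calls,
    )


def random_table(seed: int, n: int = 20, m: int = 30,
                 missing_rate: float = 0.05) -> gio.GenotypeTable:
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, m)
    calls = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    calls[rng.random(size=calls.shape) < missing_rate] = gio.MISSING
    pops = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    return gio.GenotypeTable(
        sample_ids=[f"s{i:03d}" for i in range(n)],
        populations=pops,
        snp_ids=[f"m{j}" for j in range(m)],
        chromosomes=["1"] * m,
        positions=np.arange(1, m + 1) * 100,
        allele_a=["A"] * m,
        allele_b=["B"] * m,
        calls=calls,
    )
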