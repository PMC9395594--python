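import numpy as np
import pandas as pd
import pytest

from rohscape import GenotypeDataset, SimParams, simulate_wright_fisher
from rohscape.genotype_io import SNP_COLUMNS


def make_snps(bps_by_chrom: dict[str, list[int]], alleles=("A", "G")) -> pd.DataFrame:
    """Build a marker map DataFrame from {chrom: [bp, ...]}."""
    rows = []
    k = 0
    for chrom, bps in bps_by_chrom.items():
        for bp in bps:
            k += 1
            rows.append((str(chrom), f"m{k}", bp / 1e6, int(bp), alleles[0], alleles[1]))
    return pd.DataFrame(rows, columns=SNP_COLUMNS)


def make_dataset(
    calls: np.ndarray,
    bps_by_chrom: dict[str, list[int]] | None = None,
    populations: list[str] | None = None,
) -> GenotypeDataset:
    """Build a GenotypeDataset from a call matrix; default map is chrom 1, 1 Mb spacing."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_snps = calls.shape
    if bps_by_chrom is None:
        bps_by_chrom = {"1": [1_000_000 * (j + 1) for j in range(n_snps)]}
    snps = make_snps(bps_by_chrom)
    assert len(snps) == n_snps
    pops = populations or ["POP"] * n_samples
    samples = pd.DataFrame(
        {"sample_id": [f"s{i + 1}" for i in range(n_samples)], "population": pops}
    )
    return GenotypeDataset(snps=snps, samples=samples, calls=calls)


def random_positions(rng: np.random.Generator, n: int, length_bp: int = 50_000_000) -> list[int]:
    """n distinct sorted positions, cheap for large length_bp."""
    u = np.unique(rng.integers(1, length_bp + 1, size=2 * n + 16))
    pick = rng.choice(len(u), size=n, replace=False)
    return np.sort(u[pick]).tolist()


def random_dataset(rng: np.random.Generator, n_samples=8, n_snps=40, missing_rate=0.05):
    calls = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    calls[rng.random(calls.shape) < missing_rate] = -1
    return make_dataset(calls, {"1": random_positions(rng, n_snps)})


@pytest.fixture(scope="session")
def wf_founders():
    """Outbred founder panel: 20 samples, 3 chromosomes, ~2700 polymorphic SNPs."""
    ds, truth = simulate_wright_fisher(
        SimParams(
            seed=7,
            n_snps=3000,
            n_autosomes=3,
            chrom_length_bp=100_000_000,
            ne_trajectory=((50, 200),),
            sample_sizes={"FOUNDER": 20},
            missing_rate=0.0,
        )
    )
    return ds


@pytest.fixture(scope="session")
def island_cohort():
    """Single-population WF cohort with a 30%-carrier autozygosity island implanted."""
    from rohscape import implant_island
    from rohscape.simulate import find_supported_region

    ds, _ = simulate_wright_fisher(
        SimParams(
            seed=21,
            n_snps=1200,
            n_autosomes=2,
            chrom_length_bp=100_000_000,
            ne_trajectory=((40, 150),),
            sample_sizes={"P": 20},
            missing_rate=0.01,
        )
    )
    lo, hi = find_supported_region(ds, "1")
    ds2, truth = implant_island(ds, "1", lo, hi, 0.3, seed=22)
    return ds2, truth
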