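"""Forward-in-time genotype simulation with known truth.

Every analysis stage in this package is validated against data whose answer
is known by construction.  This module provides three generators:

* :func:`simulate_wright_fisher` — a discrete-generation diploid
  Wright-Fisher population with recombination (Haldane map, no
  interference), bi-allelic mutation and an arbitrary stepwise Ne
  trajectory.  Used to test LD-based Ne estimation and drift behaviour.
* :func:`simulate_pedigree_inbreeding` — offspring bred through fixed
  pedigree designs (full-sib, half-sib, doubled-gamete "selfing-like",
  outbred) whose expected autozygous genome fraction is a textbook
  constant.  Used to test ROH calling and F_ROH recovery.
* :func:`implant_island` — forces a chosen genomic region to be fully
  homozygous in a chosen fraction of samples, creating an autozygosity
  hotspot with an exactly known span and carrier count.

The default scale (a few chromosomes of 50-100 Mb, a few thousand mapped
SNPs, cohorts of 20-50) mirrors a livestock SNP50-style panel at reduced
marker density so the whole suite runs on a desktop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import HET, HOM_A, HOM_B, MISSING, GenotypeDataset, SNP_COLUMNS

# pedigree expectations for the autozygous genome fraction
PEDIGREE_F = {"outbred": 0.0, "half_sib": 0.125, "full_sib": 0.25, "selfing_like": 1.0}


@dataclass(frozen=True)
class SimParams:
    """Wright-Fisher simulation settings.

    ne_trajectory is a list of (n_generations, diploid_Ne) epochs run in
    order from past to present; recomb_rate is in cM/Mb; mutation_rate is
    per site per generation; sample_sizes maps population label -> number of
    individuals drawn (without replacement) from the final generation.
    """

    n_autosomes: int = 3
    chrom_length_bp: int = 100_000_000
    n_snps: int = 3000
    ne_trajectory: Sequence[tuple[int, int]] = ((100, 100),)
    recomb_rate: float = 1.0
    mutation_rate: float = 0.0
    sample_sizes: dict[str, int] = field(default_factory=lambda: {"POP1": 30})
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_autosomes < 1 or self.n_snps < 1 or self.chrom_length_bp < 1:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        for gens, ne in self.ne_trajectory:
            if gens < 1 or ne < 2:
                raise ValueError("each epoch needs gens >= 1 and Ne >= 2")
        if any(n < 1 for n in self.sample_sizes.values()):
            raise ValueError("sample sizes must be positive")


@dataclass
class TruthRecord:
    """Ground truth attached to a simulated dataset."""

    expected_f: pd.Series | None = None
    islands: list[dict] = field(default_factory=list)
    ne_epochs: list[tuple[int, int]] = field(default_factory=list)

    def ne_at_generations_ago(self, t: int) -> int | None:
        """Simulated Ne t generations before sampling, None if past the log."""
        ago = 0
        for gens, ne in reversed(self.ne_epochs):
            ago += gens
            if t <= ago:
                return ne
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        if self.expected_f is not None:
            for sid, f in self.expected_f.items():
                rows.append(("expected_f", sid, f))
        for isl in self.islands:
            rows.append(
                ("island", f"{isl['chrom']}:{isl['start_bp']}:{isl['end_bp']}", isl["carrier_fraction"])
            )
        for gens, ne in self.ne_epochs:
            rows.append(("ne_epoch", str(gens), ne))
        return pd.DataFrame(rows, columns=["kind", "key", "value"])


# ---------------------------------------------------------------------------
# marker maps and meiosis
# ---------------------------------------------------------------------------


def _sample_positions(rng: np.random.Generator, n: int, length_bp: int) -> np.ndarray:
    """n distinct sorted positions in [1, length_bp], uniform, without a full permutation."""
    u = np.unique(rng.integers(1, length_bp + 1, size=2 * n + 16))
    while len(u) < n:  # only reachable when n is close to length_bp
        u = np.unique(np.concatenate([u, rng.integers(1, length_bp + 1, size=n)]))
    pick = rng.choice(len(u), size=n, replace=False)
    return np.sort(u[pick])


def _make_map(rng: np.random.Generator, params: SimParams) -> pd.DataFrame:
    per = np.full(params.n_autosomes, params.n_snps // params.n_autosomes)
    per[: params.n_snps % params.n_autosomes] += 1
    frames = []
    for c in range(params.n_autosomes):
        n = int(per[c])
        bp = _sample_positions(rng, n, params.chrom_length_bp)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": str(c + 1),
                    "snp_id": [f"snp{c + 1}_{k + 1}" for k in range(n)],
                    "cm": bp / 1e6 * params.recomb_rate,
                    "bp": bp.astype(np.int64),
                    "allele_a": "A",
                    "allele_b": "G",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[SNP_COLUMNS]


def interval_recomb_fractions(snps: pd.DataFrame) -> np.ndarray:
    """Recombination fraction for the interval preceding each SNP.

    Haldane map function, r = (1 - exp(-2d))/2 with d in Morgans from the cM
    column; the first SNP of every chromosome gets 0.5 (independent
    segregation between chromosomes, random phase at the start of each one).
    """
    cm = snps["cm"].to_numpy(dtype=float)
    chrom = snps["chrom"].to_numpy()
    d = np.diff(cm, prepend=cm[0]) / 100.0
    r = 0.5 * (1.0 - np.exp(-2.0 * np.clip(d, 0.0, None)))
    new_chrom = np.ones(len(snps), dtype=bool)
    new_chrom[1:] = chrom[1:] != chrom[:-1]
    r[new_chrom] = 0.5
    return r


def _gametes(
    rng: np.random.Generator,
    haplotypes: np.ndarray,
    parent_idx: np.ndarray,
    rfrac: np.ndarray,
) -> np.ndarray:
    """Draw one recombinant gamete per parent index (vectorized over gametes)."""
    n_gam = len(parent_idx)
    crossover = rng.random((n_gam, len(rfrac))) < rfrac[None, :]
    which = np.cumsum(crossover, axis=1) & 1
    rows = 2 * parent_idx[:, None] + which
    return haplotypes[rows, np.arange(haplotypes.shape[1])[None, :]]


# ---------------------------------------------------------------------------
# Wright-Fisher engine
# ---------------------------------------------------------------------------


def simulate_wright_fisher(params: SimParams) -> tuple[GenotypeDataset, TruthRecord]:
    """Forward diploid Wright-Fisher simulation; deterministic given the seed.

    Founders draw alleles independently per site at uniform(0.05, 0.95)
    frequencies (mimicking an ascertained common-variant array); each later
    generation draws two parents uniformly per offspring and transmits
    recombinant gametes.  After the last epoch the requested samples are
    drawn without replacement, monomorphic SNPs are dropped and genotypes
    are masked missing at ``missing_rate``.
    """
    rng = np.random.default_rng(params.seed)
    snps = _make_map(rng, params)
    rfrac = interval_recomb_fractions(snps)
    n_sites = len(snps)

    ne0 = params.ne_trajectory[0][1]
    freqs = rng.uniform(0.05, 0.95, size=n_sites)
    haps = (rng.random((2 * ne0, n_sites)) < freqs[None, :]).astype(np.int8)

    for gens, ne in params.ne_trajectory:
        for _ in range(gens):
            n_prev = haps.shape[0] // 2
            parents = rng.integers(0, n_prev, size=2 * ne)
            haps = _gametes(rng, haps, parents, rfrac)
            if params.mutation_rate > 0:
                n_mut = rng.binomial(haps.size, params.mutation_rate)
                if n_mut:
                    flat = rng.integers(0, haps.size, size=n_mut)
                    haps.flat[flat] = 1 - haps.flat[flat]

    n_final = haps.shape[0] // 2
    n_requested = sum(params.sample_sizes.values())
    if n_requested > n_final:
        raise ValueError(
            f"requested {n_requested} samples but final population has {n_final}"
        )
    chosen = rng.choice(n_final, size=n_requested, replace=False)
    calls = (haps[2 * chosen] + haps[2 * chosen + 1]).astype(np.int8)

    sample_ids, pops = [], []
    k = 0
    for pop, n in params.sample_sizes.items():
        for _ in range(n):
            k += 1
            sample_ids.append(f"{pop}_{k}")
            pops.append(pop)
    samples = pd.DataFrame({"sample_id": sample_ids, "population": pops})

    # drop SNPs monomorphic in the sampled cohort
    poly = (calls.min(axis=0) != calls.max(axis=0))
    calls = calls[:, poly]
    snps = snps.loc[poly].reset_index(drop=True)

    if params.missing_rate > 0:
        mask = rng.random(calls.shape) < params.missing_rate
        calls[mask] = MISSING

    ds = GenotypeDataset(snps=snps, samples=samples, calls=calls)
    truth = TruthRecord(
        expected_f=pd.Series(0.0, index=samples["sample_id"]),
        ne_epochs=list(params.ne_trajectory),
    )
    return ds, truth


# ---------------------------------------------------------------------------
# pedigree designs
# ---------------------------------------------------------------------------


def _phase_founders(rng: np.random.Generator, base: GenotypeDataset) -> np.ndarray:
    """Random phasing of founder genotypes into haplotypes (2n, L)."""
    calls = base.calls
    n, L = calls.shape
    haps = np.zeros((2 * n, L), dtype=np.int8)
    for i in range(n):
        g = calls[i]
        h1 = np.where(g == HOM_B, 1, 0).astype(np.int8)
        h2 = h1.copy()
        het = g == HET
        coin = rng.random(het.sum()) < 0.5
        h1[het] = coin
        h2[het] = 1 - coin.astype(np.int8)
        # missing founder genotypes transmitted as allele_a
        haps[2 * i], haps[2 * i + 1] = h1, h2
    return haps


def simulate_pedigree_inbreeding(
    base: GenotypeDataset,
    design: str,
    n_offspring: int,
    seed: int = 0,
    recomb_fractions: np.ndarray | None = None,
) -> tuple[GenotypeDataset, TruthRecord]:
    """Breed offspring through a fixed mating design with known expected F.

    Designs: ``outbred`` (unrelated founder pair, F=0), ``half_sib``
    (mating of paternal half sibs, F=0.125), ``full_sib`` (mating of full
    sibs, F=0.25) and ``selfing_like`` (a single recombinant gamete doubled
    into a fully homozygous individual, F=1).  Founder genotypes come from
    ``base`` (randomly phased); each offspring gets an independent pedigree
    realization over founders cycled from the base cohort.
    """
    if design not in PEDIGREE_F:
        raise ValueError(f"unknown design {design!r}; options {sorted(PEDIGREE_F)}")
    if base.n_samples < 4:
        raise ValueError("base dataset must contain at least 4 founders")
    rng = np.random.default_rng(seed)
    founder_haps = _phase_founders(rng, base)
    rfrac = (
        interval_recomb_fractions(base.snps)
        if recomb_fractions is None
        else np.asarray(recomb_fractions, dtype=float)
    )
    n_f = base.n_samples
    L = base.n_snps

    def gamete(haps_pair: np.ndarray) -> np.ndarray:
        return _gametes(rng, haps_pair, np.zeros(1, dtype=int), rfrac)[0]

    def child(hap_pool: np.ndarray, p1: int, p2: int) -> np.ndarray:
        g1 = gamete(hap_pool[2 * p1 : 2 * p1 + 2])
        g2 = gamete(hap_pool[2 * p2 : 2 * p2 + 2])
        return np.stack([g1, g2])

    offspring = np.zeros((n_offspring, L), dtype=np.int8)
    for k in range(n_offspring):
        a, b, c, d = ((np.arange(4) + 4 * k) % n_f).tolist()
        if design == "outbred":
            pair = child(founder_haps, a, b)
        elif design == "selfing_like":
            g = gamete(founder_haps[2 * a : 2 * a + 2])
            pair = np.stack([g, g])
        else:
            if design == "full_sib":
                sib1 = child(founder_haps, a, b)
                sib2 = child(founder_haps, a, b)
            else:  # half_sib: shared sire a, dams b and c
                sib1 = child(founder_haps, a, b)
                sib2 = child(founder_haps, a, c)
            pool = np.concatenate([sib1, sib2])
            pair = child(pool, 0, 1)
        offspring[k] = pair[0] + pair[1]

    samples = pd.DataFrame(
        {
            "sample_id": [f"{design}_{k + 1}" for k in range(n_offspring)],
            "population": design,
        }
    )
    ds = GenotypeDataset(snps=base.snps.copy(), samples=samples, calls=offspring)
    truth = TruthRecord(
        expected_f=pd.Series(PEDIGREE_F[design], index=samples["sample_id"])
    )
    return ds, truth


# ---------------------------------------------------------------------------
# autozygosity islands
# ---------------------------------------------------------------------------


def find_supported_region(
    dataset: GenotypeDataset,
    chrom: str,
    n_region_snps: int = 150,
    max_gap_bp: int = 900_000,
) -> tuple[int, int]:
    """(start_bp, end_bp) of a central run of SNPs with no large inter-SNP gap.

    An implanted island is only detectable by a window caller if the region
    holds enough consecutive SNPs without gaps that would split a run; this
    picks such a region (the most central qualifying window) or raises when
    the map cannot support one.
    """
    block = dataset.snps[dataset.snps["chrom"].astype(str) == str(chrom)]
    bp = block["bp"].to_numpy()
    n = len(bp)
    if n < n_region_snps:
        raise ValueError(f"chromosome {chrom} has only {n} SNPs")
    gap_ok = np.diff(bp) <= max_gap_bp
    best = None
    center = (n - n_region_snps) / 2
    for j0 in range(0, n - n_region_snps + 1):
        if gap_ok[j0 : j0 + n_region_snps - 1].all():
            if best is None or abs(j0 - center) < abs(best - center):
                best = j0
    if best is None:
        raise ValueError(f"no {n_region_snps}-SNP window on chromosome {chrom} without gaps > {max_gap_bp} bp")
    return int(bp[best]), int(bp[best + n_region_snps - 1])


def implant_island(
    dataset: GenotypeDataset,
    chrom: str,
    start_bp: int,
    end_bp: int,
    carrier_fraction: float,
    seed: int = 0,
) -> tuple[GenotypeDataset, TruthRecord]:
    """Set a region fully homozygous (hom allele_a, no missing) in a sample subset.

    Exactly ceil(carrier_fraction * n_samples) carriers are chosen uniformly
    without replacement; other samples are untouched.
    """
    if not (0.0 < carrier_fraction <= 1.0):
        raise ValueError("carrier_fraction must lie in (0, 1]")
    chrom = str(chrom)
    in_region = (
        (dataset.snps["chrom"].astype(str) == chrom)
        & (dataset.snps["bp"] >= start_bp)
        & (dataset.snps["bp"] <= end_bp)
    ).to_numpy()
    if not in_region.any():
        raise ValueError(f"region {chrom}:{start_bp}-{end_bp} contains no SNPs")
    rng = np.random.default_rng(seed)
    n = dataset.n_samples
    n_carriers = int(np.ceil(carrier_fraction * n))
    carriers = rng.choice(n, size=n_carriers, replace=False)
    calls = dataset.calls.copy()
    calls[np.ix_(carriers, np.nonzero(in_region)[0])] = HOM_A
    ds = GenotypeDataset(snps=dataset.snps.copy(), samples=dataset.samples.copy(), calls=calls)
    truth = TruthRecord(
        islands=[
            {
                "chrom": chrom,
                "start_bp": int(start_bp),
                "end_bp": int(end_bp),
                "carrier_fraction": carrier_fraction,
                "n_carriers": n_carriers,
                "carrier_idx": np.sort(carriers).tolist(),
            }
        ]
    )
    return ds, truth
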