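"""Effective population size from binned LD decay.

Pairs of intra-chromosomal SNPs are binned by physical distance; within a
bin the mean genotypic (phase-free) r-squared, corrected for finite sample
size by subtracting 1/n, estimates E[r^2] at genetic distance c Morgans.
Under the standard drift-recombination expectation
E[r^2] ~ 1/(alpha + 4*Ne*c) + 1/n, each bin yields

    Ne = (1/r2_adj - alpha) / (4 c),     t = 1/(2 c) generations ago,

so short-range bins probe ancient Ne and long-range bins recent Ne.
``alpha`` is 1 for a pure drift model, 2.2 when mutation is accommodated.
Physical distance converts to genetic distance at ``map_rate`` cM/Mb
(default 1, the standard assumption for livestock SNP arrays).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset

_R2_EPS = 1e-6


@dataclass(frozen=True)
class NeParams:
    min_dist_bp: int = 50_000
    max_dist_bp: int = 4_000_000
    n_bins: int = 30
    alpha: float = 1.0
    sample_size_correction: bool = True
    map_rate: float = 1.0  # cM per Mb
    min_maf: float = 0.05

    def __post_init__(self) -> None:
        if self.min_dist_bp >= self.max_dist_bp:
            raise ValueError("min_dist_bp must be below max_dist_bp")
        if self.n_bins < 1 or self.alpha <= 0:
            raise ValueError("n_bins must be >= 1 and alpha > 0")


def genotype_r2(dataset: GenotypeDataset, snp_i: int, snp_j: int) -> float:
    """Squared Pearson correlation of dosages over samples complete at both SNPs."""
    if dataset.snps["chrom"].iat[snp_i] != dataset.snps["chrom"].iat[snp_j]:
        raise ValueError("SNPs must lie on the same chromosome")
    x = dataset.calls[:, snp_i].astype(float)
    y = dataset.calls[:, snp_j].astype(float)
    ok = (dataset.calls[:, snp_i] != MISSING) & (dataset.calls[:, snp_j] != MISSING)
    if ok.sum() < 2:
        raise ValueError("need at least 2 samples complete at both SNPs")
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def pairwise_r2_matrix(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(r2, n) matrices of pairwise-complete genotypic r^2 for a call matrix.

    Entry (i, j) is the squared dosage correlation over samples complete at
    both SNPs; NaN where undefined (fewer than 2 shared samples or zero
    variance).
    """
    d = calls.astype(float)
    valid = calls != MISSING
    d[~valid] = 0.0
    v = valid.astype(float)
    n = v.T @ v  # pairwise complete counts
    s1 = d.T @ v  # sum of x over complete pairs
    s2 = (d**2).T @ v
    sxy = d.T @ d
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - s1 * s1.T / n
        varx = s2 - s1**2 / n
        r2 = cov**2 / (varx * varx.T)
    r2[n < 2] = np.nan
    return r2, n


def _chrom_r2_pairs(
    calls: np.ndarray, bp: np.ndarray, min_d: int, max_d: int
) -> tuple[np.ndarray, np.ndarray]:
    """(distances, r2) for all SNP pairs on one chromosome with distance in [min_d, max_d)."""
    n_snp = calls.shape[1]
    r2, n = pairwise_r2_matrix(calls)
    dist = np.abs(bp[:, None] - bp[None, :])
    iu = np.triu_indices(n_snp, k=1)
    dist_u = dist[iu]
    r2_u = r2[iu]
    keep = (dist_u >= min_d) & (dist_u < max_d) & np.isfinite(r2_u) & (n[iu] >= 2)
    return dist_u[keep], r2_u[keep]


def bin_ld(dataset: GenotypeDataset, params: NeParams = NeParams()) -> pd.DataFrame:
    """Mean adjusted r^2 per equal-width distance bin (columns: bin stats).

    SNPs below ``min_maf`` are excluded before pairing; empty bins are
    dropped.  The sample-size correction subtracts 1/n_samples and floors
    the result at a small positive epsilon.
    """
    if params.min_maf > 0:
        from .qc import minor_allele_frequency, snp_call_rate

        keep = np.array(
            [
                snp_call_rate(dataset, j) > 0
                and minor_allele_frequency(dataset, j) >= params.min_maf
                for j in range(dataset.n_snps)
            ]
        )
        dataset = dataset.subset(snp_idx=np.nonzero(keep)[0])

    dists, r2s = [], []
    for chrom, sl in dataset.chrom_slices().items():
        calls = dataset.calls[:, sl]
        bp = dataset.snps["bp"].to_numpy()[sl].astype(np.int64)
        if calls.shape[1] < 2:
            continue
        d, r = _chrom_r2_pairs(calls, bp, params.min_dist_bp, params.max_dist_bp)
        dists.append(d)
        r2s.append(r)
    if not dists:
        return pd.DataFrame(
            columns=["bin_lo_bp", "bin_hi_bp", "mean_dist_bp", "c_morgans", "mean_r2", "mean_r2_adj", "n_pairs"]
        )
    dist = np.concatenate(dists)
    r2 = np.concatenate(r2s)

    edges = np.linspace(params.min_dist_bp, params.max_dist_bp, params.n_bins + 1)
    idx = np.clip(np.searchsorted(edges, dist, side="right") - 1, 0, params.n_bins - 1)
    rows = []
    n_samples = dataset.n_samples
    for b in range(params.n_bins):
        sel = idx == b
        if not sel.any():
            continue
        mean_r2 = float(r2[sel].mean())
        adj = mean_r2 - (1.0 / n_samples if params.sample_size_correction else 0.0)
        adj = max(adj, _R2_EPS)
        mean_dist = float(dist[sel].mean())
        rows.append(
            {
                "bin_lo_bp": edges[b],
                "bin_hi_bp": edges[b + 1],
                "mean_dist_bp": mean_dist,
                "c_morgans": params.map_rate * mean_dist / 1e8,
                "mean_r2": mean_r2,
                "mean_r2_adj": adj,
                "n_pairs": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def ne_from_bin(mean_r2_adj: float, c: float, alpha: float = 1.0) -> tuple[int, float]:
    """(t generations ago, Ne) from one bin's adjusted mean r^2 at distance c Morgans."""
    if not (0.0 < mean_r2_adj < 1.0):
        raise ValueError("mean_r2_adj must lie strictly between 0 and 1")
    if c <= 0:
        raise ValueError("c must be positive")
    t = int(round(1.0 / (2.0 * c)))
    ne = (1.0 / mean_r2_adj - alpha) / (4.0 * c)
    return t, float(round(ne))


def ne_trajectory(
    dataset: GenotypeDataset,
    params: NeParams = NeParams(),
    by_population: bool = True,
) -> pd.DataFrame:
    """Ne estimates per distance bin, per population, sorted by t ascending.

    Bins whose adjusted r^2 falls outside (0, 1) or that yield Ne <= 0 are
    dropped; an error is raised when nothing remains.
    """
    groups: list[tuple[str, GenotypeDataset]] = []
    if by_population:
        for pop, grp in dataset.samples.groupby("population", sort=False):
            idx = np.asarray(grp.index)
            groups.append((str(pop), dataset.subset(sample_idx=idx)))
    else:
        groups.append(("ALL", dataset))

    rows = []
    for pop, sub in groups:
        binned = bin_ld(sub, params)
        for b in binned.itertuples():
            if not (0.0 < b.mean_r2_adj < 1.0):
                continue
            t, ne = ne_from_bin(b.mean_r2_adj, b.c_morgans, params.alpha)
            if ne <= 0:
                continue
            rows.append(
                {
                    "population": pop,
                    "t_generations": t,
                    "c_morgans": b.c_morgans,
                    "mean_r2_adj": b.mean_r2_adj,
                    "ne": ne,
                    "n_pairs": b.n_pairs,
                }
            )
    if not rows:
        raise ValueError("no usable LD bins for Ne estimation")
    out = pd.DataFrame(rows).sort_values(["population", "t_generations"]).reset_index(drop=True)
    return out
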