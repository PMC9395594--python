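"""Population-structure utilities: LD pruning, IBS relatedness filtering, PCA.

Pruning is the greedy windowed procedure of PLINK's ``--indep-pairwise``:
within each 50-SNP window (advancing 5 SNPs) pairs with genotypic r^2 above
0.5 are broken by removing the lower-MAF member (tie: the later map
position).  Relatedness filtering removes one member of each pair with IBS
similarity above a cutoff.  PCA operates on mean-imputed dosages centered
by 2p and scaled by sqrt(2p(1-p)) per SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset


@dataclass(frozen=True)
class PruneParams:
    window_snps: int = 50
    step_snps: int = 5
    r2_max: float = 0.5

    def __post_init__(self) -> None:
        if not (self.window_snps > self.step_snps >= 1):
            raise ValueError("need window_snps > step_snps >= 1")
        if not (0.0 < self.r2_max <= 1.0):
            raise ValueError("r2_max must lie in (0, 1]")


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # sample_id, population, PC1..PCk
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray


def _pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return np.nan
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    if xv.std() == 0 or yv.std() == 0:
        return np.nan
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def _maf(x: np.ndarray) -> float:
    obs = x[x != MISSING]
    if len(obs) == 0:
        return 0.0
    p = obs.sum() / (2 * len(obs))
    return min(p, 1 - p)


def ld_prune(dataset: GenotypeDataset, params: PruneParams = PruneParams()) -> np.ndarray:
    """Indices of SNPs retained after greedy windowed LD pruning.

    Windows never cross chromosome boundaries.  Within a window, the first
    (map-order) retained pair with r^2 > r2_max loses its lower-MAF member
    (tie: later bp goes); this repeats until the window is clean, then the
    window advances by step_snps.
    """
    from .ne import pairwise_r2_matrix

    keep = np.ones(dataset.n_snps, dtype=bool)
    mafs = np.array([_maf(dataset.calls[:, j]) for j in range(dataset.n_snps)])
    for chrom, sl in dataset.chrom_slices().items():
        lo, hi = sl.start, sl.stop
        for w0 in range(lo, hi, params.step_snps):
            w1 = min(w0 + params.window_snps, hi)
            r2mat, _ = pairwise_r2_matrix(dataset.calls[:, w0:w1])
            while True:
                live = [j for j in range(w0, w1) if keep[j]]
                removed = False
                for a in range(len(live)):
                    for b in range(a + 1, len(live)):
                        i, j = live[a], live[b]
                        r2 = r2mat[i - w0, j - w0]
                        if np.isfinite(r2) and r2 > params.r2_max:
                            if mafs[i] < mafs[j]:
                                drop = i
                            elif mafs[j] < mafs[i]:
                                drop = j
                            else:
                                drop = j  # tie: later map position
                            keep[drop] = False
                            removed = True
                            break
                    if removed:
                        break
                if not removed:
                    break
            if w1 == hi:
                break
    return np.nonzero(keep)[0]


def ibs_matrix(dataset: GenotypeDataset) -> pd.DataFrame:
    """Sample x sample IBS similarity: mean of (2 - |dosage_i - dosage_j|)/2.

    Computed over SNPs non-missing in both samples; symmetric with unit
    diagonal; NaN where a pair shares no complete SNP.
    """
    if dataset.n_samples < 2:
        raise ValueError("need at least 2 samples")
    calls = dataset.calls.astype(float)
    valid = dataset.calls != MISSING
    # O(n^2 m) direct loop; n is a few hundred at most in this setting
    n = dataset.n_samples
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            if not ok.any():
                sim[i, j] = sim[j, i] = np.nan
                continue
            diff = np.abs(calls[i, ok] - calls[j, ok])
            sim[i, j] = sim[j, i] = float(((2.0 - diff) / 2.0).mean())
    ids = dataset.samples["sample_id"]
    return pd.DataFrame(sim, index=ids, columns=ids)


def remove_related(dataset: GenotypeDataset, ibs_cutoff: float = 0.65) -> GenotypeDataset:
    """Drop one member of each sample pair with IBS strictly above the cutoff.

    While any pair exceeds the cutoff, the member with the lower call rate
    is removed (tie: the lexicographically larger sample_id); deterministic.
    """
    if not (0.0 < ibs_cutoff < 1.0):
        raise ValueError("ibs_cutoff must lie in (0, 1)")
    sim = ibs_matrix(dataset).to_numpy()
    np.fill_diagonal(sim, 0.0)
    call_rates = (dataset.calls != MISSING).mean(axis=1)
    ids = dataset.samples["sample_id"].to_numpy()
    alive = np.ones(dataset.n_samples, dtype=bool)
    while True:
        worst = None
        for i in range(dataset.n_samples):
            if not alive[i]:
                continue
            for j in range(i + 1, dataset.n_samples):
                if alive[j] and np.isfinite(sim[i, j]) and sim[i, j] > ibs_cutoff:
                    worst = (i, j)
                    break
            if worst:
                break
        if worst is None:
            break
        i, j = worst
        if call_rates[i] < call_rates[j]:
            drop = i
        elif call_rates[j] < call_rates[i]:
            drop = j
        else:
            drop = i if ids[i] > ids[j] else j
        alive[drop] = False
    return dataset.subset(sample_idx=np.nonzero(alive)[0])


def pca(dataset: GenotypeDataset, k: int = 10) -> PcaResult:
    """Top-k principal components of scaled genotype dosages.

    Missing dosages are mean-imputed per SNP; dosages are centered by 2p and
    scaled by sqrt(2p(1-p)); fixed SNPs (p in {0,1}) are dropped.
    Eigenvalues are those of the sample covariance of the scaled matrix.
    """
    if k > dataset.n_samples - 1:
        raise ValueError(f"k={k} exceeds n_samples-1={dataset.n_samples - 1}")
    d = dataset.dosage()
    with np.errstate(invalid="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-missing SNPs -> NaN, dropped
            mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(np.nan_to_num(mean), inds[1])
    p = mean / 2.0
    keep = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    d = d[:, keep]
    p = p[keep]
    z = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    m = z.shape[1]
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    eig = s**2 / m
    coords = u[:, :k] * s[:k]
    frames = dataset.samples[["sample_id", "population"]].copy()
    for c in range(k):
        frames[f"PC{c + 1}"] = coords[:, c]
    return PcaResult(
        coordinates=frames,
        eigenvalues=eig[:k],
        variance_fractions=eig[:k] / eig.sum(),
    )
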