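"""Marker quality control: autosome subsetting, call rate, MAF and HWE filters.

Stages run in a fixed order — autosomes, call rate, MAF, Hardy-Weinberg —
each stage seeing the previous stage's output, and every removal is logged
with its reason.  All comparisons are strict inequalities against the
thresholds (a SNP exactly at 95% call rate is retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import MISSING, HET, HOM_A, HOM_B, GenotypeDataset


@dataclass(frozen=True)
class QcParams:
    """Thresholds for marker QC.

    min_call_rate : SNPs with call rate strictly below are removed (default 0.95).
    min_maf : SNPs with minor allele frequency strictly below are removed (0.05).
    hwe_p_cutoff : SNPs with exact-test p strictly below are removed (1e-5).
    n_autosomes : autosome labels 1..n are retained (29, the caprine/bovine count).
    hwe_per_population : test HWE within each population (keep a SNP only if it
        passes in every population) instead of on the pooled cohort.
    hwe_method : "exact" (Wigginton-style) or "chisq".
    """

    min_call_rate: float = 0.95
    min_maf: float = 0.05
    hwe_p_cutoff: float = 1e-5
    n_autosomes: int = 29
    hwe_per_population: bool = False
    hwe_method: str = "exact"

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_call_rate <= 1.0 and 0.0 <= self.min_maf <= 1.0):
            raise ValueError("min_call_rate and min_maf must lie in [0, 1]")
        if not (0.0 < self.hwe_p_cutoff < 1.0):
            raise ValueError("hwe_p_cutoff must lie in (0, 1)")
        if self.n_autosomes < 1:
            raise ValueError("n_autosomes must be >= 1")
        if self.hwe_method not in ("exact", "chisq"):
            raise ValueError("hwe_method must be 'exact' or 'chisq'")


@dataclass
class QcStage:
    name: str
    n_snps_before: int
    n_snps_after: int
    n_samples: int


@dataclass
class QcReport:
    """Per-stage attrition counts plus the removed SNP ids with reasons."""

    stages: list[QcStage] = field(default_factory=list)
    removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "reason"])
    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.n_snps_before, s.n_snps_after, s.n_samples) for s in self.stages],
            columns=["stage", "n_snps_before", "n_snps_after", "n_samples"],
        )


class EmptyDatasetError(RuntimeError):
    """All SNPs were removed by QC."""


def snp_call_rate(dataset: GenotypeDataset, snp_index: int) -> float:
    """Fraction of samples with a non-missing call at one SNP."""
    col = dataset.calls[:, snp_index]
    return float((col != MISSING).sum() / dataset.n_samples)


def genotype_counts(dataset: GenotypeDataset, snp_index: int) -> tuple[int, int, int]:
    """(n_hom_a, n_het, n_hom_b) at one SNP, missing excluded."""
    col = dataset.calls[:, snp_index]
    return int((col == HOM_A).sum()), int((col == HET).sum()), int((col == HOM_B).sum())


def minor_allele_frequency(dataset: GenotypeDataset, snp_index: int) -> float:
    """min(p, 1-p) with p the allele_b frequency among non-missing calls."""
    n_a, n_het, n_b = genotype_counts(dataset, snp_index)
    n_alleles = 2 * (n_a + n_het + n_b)
    if n_alleles == 0:
        raise ValueError(
            f"SNP {dataset.snps['snp_id'].iat[snp_index]!r} has no non-missing calls"
        )
    p = (2 * n_b + n_het) / n_alleles
    return float(min(p, 1.0 - p))


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test (Wigginton-style).

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability is <= that of the observed count.
    Monomorphic SNPs return 1.0.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")
    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_minor == 0:
        return 1.0
    # P(het = h | allele counts) ∝ 2^h * n! / (n_aa! n_ab! n_bb!) with
    # n_ab = h, constrained by parity of the minor-allele count.
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    n_aa = (n_minor - hets) // 2
    n_bb = n - hets - n_aa
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(n_aa + 1)
        - gammaln(n_bb + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.nonzero(hets == n_het)[0][0]]
    # tolerance guards against ties lost to floating point
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_chisq_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-degree-of-freedom chi-square HWE test (no continuity correction)."""
    from scipy.stats import chi2

    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")
    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, df=1))


def subset_autosomes(dataset: GenotypeDataset, n_autosomes: int = 29) -> np.ndarray:
    """Boolean keep-mask for SNPs on autosomes 1..n_autosomes."""
    labels = {str(i) for i in range(1, n_autosomes + 1)}
    return dataset.snps["chrom"].astype(str).isin(labels).to_numpy()


def apply_qc(dataset: GenotypeDataset, params: QcParams = QcParams()) -> tuple[GenotypeDataset, QcReport]:
    """Run the four QC stages in order and report attrition."""
    if dataset.n_snps == 0:
        raise EmptyDatasetError("dataset has no SNPs")
    report = QcReport()
    removed_rows: list[tuple[str, str]] = []
    ds = dataset

    def _apply(name: str, keep: np.ndarray) -> None:
        nonlocal ds
        dropped = ds.snps.loc[~keep, "snp_id"]
        removed_rows.extend((sid, name) for sid in dropped)
        report.stages.append(QcStage(name, ds.n_snps, int(keep.sum()), ds.n_samples))
        ds = ds.subset(snp_idx=np.nonzero(keep)[0])

    _apply("non_autosomal", subset_autosomes(ds, params.n_autosomes))
    if ds.n_snps:
        rates = np.array([snp_call_rate(ds, j) for j in range(ds.n_snps)])
        _apply("call_rate", rates >= params.min_call_rate)
    if ds.n_snps:
        mafs = np.array(
            [
                minor_allele_frequency(ds, j) if snp_call_rate(ds, j) > 0 else 0.0
                for j in range(ds.n_snps)
            ]
        )
        _apply("maf", mafs >= params.min_maf)
    if ds.n_snps:
        test = hwe_exact_p if params.hwe_method == "exact" else hwe_chisq_p
        if params.hwe_per_population:
            pvals = np.ones(ds.n_snps)
            for pop, idx in ds.samples.groupby("population").groups.items():
                sub = ds.subset(sample_idx=np.asarray(list(idx)))
                for j in range(ds.n_snps):
                    pvals[j] = min(pvals[j], test(*genotype_counts(sub, j)))
        else:
            pvals = np.array([test(*genotype_counts(ds, j)) for j in range(ds.n_snps)])
        _apply("hwe", pvals >= params.hwe_p_cutoff)

    report.removed = pd.DataFrame(removed_rows, columns=["snp_id", "reason"])
    if ds.n_snps == 0:
        raise EmptyDatasetError("QC removed every SNP")
    return ds, report
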