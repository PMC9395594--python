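"""Genomic inbreeding coefficients F_HOM and F_ROH.

F_HOM is the method-of-moments estimator behind PLINK's ``--het``:
F_HOM = (O_HOM - E_HOM) / (L - E_HOM), with E_HOM summed over the sample's
non-missing SNPs as 1 - 2*p*q * n/(n-1) (cohort allele frequency p, n the
number of non-missing alleles at the SNP).  Positive values indicate an
excess of homozygous genotypes.

F_ROH is the fraction of the SNP-covered autosome lying inside the sample's
ROH segments: F_ROH = L_ROH / L_AUTO.  L_AUTO defaults to the summed
per-chromosome span (last minus first mapped SNP) of the dataset; a fixed
override in Mb can be supplied for replication against published values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import HET, MISSING, GenotypeDataset
from .roh import LengthClassScheme, RohSet, chrom_spans


def autosome_length_bp(dataset: GenotypeDataset) -> int:
    """Summed per-chromosome span (last - first mapped SNP bp)."""
    return int(chrom_spans(dataset)["span_bp"].sum())


def compute_fhom(dataset: GenotypeDataset) -> pd.DataFrame:
    """Per-sample F_HOM with its O_HOM, E_HOM and L intermediates."""
    calls = dataset.calls
    miss = calls == MISSING
    het = calls == HET
    nonmiss = ~miss

    n_alleles = 2 * nonmiss.sum(axis=0).astype(float)  # per SNP
    with np.errstate(invalid="ignore", divide="ignore"):
        n_b = (np.where(miss, 0, calls)).sum(axis=0).astype(float)
        p = np.where(n_alleles > 0, n_b / np.maximum(n_alleles, 1), np.nan)
        # expected homozygosity per SNP with the small-sample correction
        e_hom_snp = np.where(
            n_alleles > 1,
            1.0 - 2.0 * p * (1.0 - p) * n_alleles / np.maximum(n_alleles - 1.0, 1.0),
            np.nan,
        )

    rows = []
    for i, s in enumerate(dataset.samples.itertuples()):
        use = nonmiss[i] & np.isfinite(e_hom_snp)
        L = int(use.sum())
        o_hom = int((use & ~het[i]).sum())
        e_hom = float(e_hom_snp[use].sum())
        denom = L - e_hom
        f = (o_hom - e_hom) / denom if abs(denom) > 1e-12 else np.nan
        rows.append(
            {
                "sample_id": s.sample_id,
                "population": s.population,
                "O_HOM": o_hom,
                "E_HOM": e_hom,
                "L": L,
                "F_HOM": f,
            }
        )
    return pd.DataFrame(rows)


def compute_froh(roh_set: RohSet, l_auto_bp: int) -> pd.Series:
    """Per-sample F_ROH = summed segment length / l_auto_bp (0 for ROH-free samples)."""
    if l_auto_bp <= 0:
        raise ValueError("l_auto_bp must be positive")
    totals = roh_set.segments.groupby("sample_id")["length_bp"].sum()
    out = pd.Series(0.0, index=roh_set.samples["sample_id"], name="F_ROH")
    if len(totals):
        out.loc[totals.index] = totals / l_auto_bp
    return out


def froh_by_class(
    roh_set: RohSet,
    l_auto_bp: int,
    scheme: LengthClassScheme = LengthClassScheme(),
) -> pd.DataFrame:
    """Per-sample F_ROH split by segment length class (columns sum to the total)."""
    if l_auto_bp <= 0:
        raise ValueError("l_auto_bp must be positive")
    out = pd.DataFrame(
        0.0, index=roh_set.samples["sample_id"], columns=scheme.labels
    )
    for seg in roh_set.segments.itertuples():
        lab = scheme.classify(seg.length_bp / 1e6)
        out.loc[seg.sample_id, lab] += seg.length_bp / l_auto_bp
    out["total"] = out[scheme.labels].sum(axis=1)
    return out


def froh_class_table(
    roh_set: RohSet,
    l_auto_bp: int,
    scheme: LengthClassScheme = LengthClassScheme(),
) -> pd.DataFrame:
    """Population mean +/- sd of per-class F_ROH, rounded to 2 decimals for report."""
    per_sample = froh_by_class(roh_set, l_auto_bp, scheme)
    per_sample["population"] = roh_set.samples.set_index("sample_id")["population"]
    rows = []
    for pop, grp in per_sample.groupby("population", sort=False):
        for lab in list(scheme.labels) + ["total"]:
            rows.append(
                {
                    "population": pop,
                    "class": lab,
                    "mean": round(float(grp[lab].mean()), 2),
                    "sd": round(float(grp[lab].std(ddof=1)) if len(grp) > 1 else 0.0, 2),
                }
            )
    return pd.DataFrame(rows)


def froh_by_chromosome(roh_set: RohSet, dataset: GenotypeDataset) -> pd.DataFrame:
    """Per-sample, per-chromosome F_ROH using each chromosome's SNP span as denominator.

    Chromosomes with fewer than 2 mapped SNPs (zero span) are excluded.
    """
    spans = chrom_spans(dataset)
    counts = dataset.snps.groupby("chrom", sort=False).size()
    usable = [c for c in dataset.chromosomes() if counts[c] >= 2 and spans.loc[c, "span_bp"] > 0]
    out = pd.DataFrame(0.0, index=roh_set.samples["sample_id"], columns=usable)
    for seg in roh_set.segments.itertuples():
        c = str(seg.chrom)
        if c in out.columns:
            out.loc[seg.sample_id, c] += seg.length_bp / spans.loc[c, "span_bp"]
    return out


def froh_fhom_correlation(
    inbreeding_table: pd.DataFrame, grouping: str | None = "population"
) -> pd.Series:
    """Pearson correlation of F_ROH and F_HOM, per population (or pooled if grouping None).

    Groups with fewer than 3 samples or zero variance yield NaN.
    """
    df = inbreeding_table
    def corr(sub: pd.DataFrame) -> float:
        sub = sub.dropna(subset=["F_ROH", "F_HOM"])
        if len(sub) < 3 or sub["F_ROH"].nunique() < 2 or sub["F_HOM"].nunique() < 2:
            return np.nan
        return float(np.corrcoef(sub["F_ROH"], sub["F_HOM"])[0, 1])

    if grouping is None:
        return pd.Series({"ALL": corr(df)})
    return df.groupby(grouping, sort=False).apply(corr, include_groups=False)


def inbreeding_table(
    dataset: GenotypeDataset,
    roh_set: RohSet,
    l_auto_bp: int | None = None,
    scheme: LengthClassScheme = LengthClassScheme(),
) -> pd.DataFrame:
    """Combined per-sample table: F_HOM, total and per-class F_ROH."""
    if l_auto_bp is None:
        l_auto_bp = autosome_length_bp(dataset)
    fhom = compute_fhom(dataset).set_index("sample_id")
    froh = compute_froh(roh_set, l_auto_bp)
    by_class = froh_by_class(roh_set, l_auto_bp, scheme)
    out = fhom.join(froh).join(by_class.add_prefix("F_ROH_"))
    out = out.rename(columns={"F_ROH_total": "F_ROH_total"})
    out["L_ROH_bp"] = (out["F_ROH"] * l_auto_bp).round().astype(np.int64)
    out["L_AUTO_bp"] = l_auto_bp
    return out.reset_index()
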