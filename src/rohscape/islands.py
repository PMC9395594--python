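"""ROH islands: shared-autozygosity hotspots from per-SNP ROH incidence.

For one population, each SNP's incidence is the fraction of individuals with
at least one ROH segment whose interval covers the SNP position.  Islands
are maximal runs of consecutive map-order SNPs whose incidence strictly
exceeds a threshold (conventionally 70%, 50% or 20% of individuals); runs
with fewer than ``min_island_snps`` SNPs are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset
from .roh import RohSet, segment_length_mb

ISLAND_COLUMNS = ["population", "chrom", "start_bp", "end_bp", "n_snps", "length_mb", "peak_pct"]


@dataclass(frozen=True)
class Island:
    population: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    length_mb: float
    peak_pct: float


def snp_incidence(roh_set: RohSet, dataset: GenotypeDataset, population: str) -> pd.Series:
    """Per-SNP fraction of the population's individuals whose ROH cover the SNP.

    Coverage is by bp containment: a segment [start_bp, end_bp] covers every
    SNP position inside it, independent of the caller's SNP bookkeeping.
    """
    pop_samples = roh_set.samples.loc[
        roh_set.samples["population"] == population, "sample_id"
    ]
    if pop_samples.empty:
        raise ValueError(f"unknown or empty population {population!r}")
    n = len(pop_samples)
    bp = dataset.snps["bp"].to_numpy()
    chrom = dataset.snps["chrom"].astype(str).to_numpy()
    counts = np.zeros(dataset.n_snps, dtype=np.int64)
    segs = roh_set.segments
    segs = segs[segs["sample_id"].isin(set(pop_samples))]
    for (sid, c), grp in segs.groupby(["sample_id", "chrom"]):
        on_chrom = chrom == str(c)
        covered = np.zeros(dataset.n_snps, dtype=bool)
        for seg in grp.itertuples():
            covered |= on_chrom & (bp >= seg.start_bp) & (bp <= seg.end_bp)
        counts += covered
    return pd.Series(counts / n, index=dataset.snps["snp_id"], name=population)


def call_islands(
    track: pd.Series,
    dataset: GenotypeDataset,
    threshold_fraction: float,
    min_island_snps: int = 10,
    population: str | None = None,
) -> list[Island]:
    """Maximal runs of consecutive SNPs with incidence strictly above the threshold."""
    if not (0.0 < threshold_fraction <= 1.0):
        raise ValueError("threshold_fraction must lie in (0, 1]")
    pop = population if population is not None else (track.name or "")
    vals = track.to_numpy()
    above = vals > threshold_fraction
    chrom = dataset.snps["chrom"].astype(str).to_numpy()
    bp = dataset.snps["bp"].to_numpy()
    out: list[Island] = []
    i = 0
    n = len(vals)
    while i < n:
        if not above[i] or (i > 0 and above[i - 1] and chrom[i] == chrom[i - 1]):
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1] and chrom[j + 1] == chrom[j]:
            j += 1
        if j - i + 1 >= min_island_snps:
            out.append(
                Island(
                    population=str(pop),
                    chrom=str(chrom[i]),
                    start_bp=int(bp[i]),
                    end_bp=int(bp[j]),
                    n_snps=j - i + 1,
                    length_mb=segment_length_mb(int(bp[i]), int(bp[j])) if bp[j] > bp[i] else 0.0,
                    peak_pct=float(round(100.0 * vals[i : j + 1].max(), 2)),
                )
            )
        i = j + 1
    return out


def islands_table(islands: list[Island]) -> pd.DataFrame:
    rows = [
        (isl.population, isl.chrom, isl.start_bp, isl.end_bp, isl.n_snps, isl.length_mb, isl.peak_pct)
        for isl in islands
    ]
    return pd.DataFrame(rows, columns=ISLAND_COLUMNS)


def scan_islands(
    roh_set: RohSet,
    dataset: GenotypeDataset,
    threshold_fraction: float,
    min_island_snps: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Incidence tracks and island table for every population at one threshold."""
    tracks = {}
    all_islands: list[Island] = []
    for pop in roh_set.populations():
        track = snp_incidence(roh_set, dataset, pop)
        tracks[pop] = track
        all_islands.extend(
            call_islands(track, dataset, threshold_fraction, min_island_snps, pop)
        )
    track_df = pd.DataFrame(tracks)
    track_df.insert(0, "chrom", dataset.snps["chrom"].to_numpy())
    track_df.insert(1, "bp", dataset.snps["bp"].to_numpy())
    return track_df, islands_table(all_islands)


def islands_to_bed(islands: list[Island]) -> str:
    """BED text (0-based half-open) for the island regions."""
    lines = [
        f"{isl.chrom}\t{isl.start_bp - 1}\t{isl.end_bp}\t{isl.population}\t{isl.peak_pct}"
        for isl in islands
    ]
    return "\n".join(lines) + ("\n" if lines else "")
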