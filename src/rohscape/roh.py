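"""Runs-of-homozygosity detection and summary tables.

The caller is the sliding-window ("consecutive runs") algorithm used by
SNP-array ROH tools: windows of ``window_snps`` consecutive same-chromosome
SNPs are scored homozygous when they contain at most ``max_het_in_roh``
heterozygotes and ``max_missing_in_roh`` missing calls; a SNP is flagged
when the fraction of windows covering it that are homozygous exceeds
``window_hit_fraction``; maximal stretches of flagged SNPs, split at
physical gaps above ``max_gap_bp``, become segments if they satisfy the
per-run SNP-count, length, heterozygote and missing constraints.

Defaults correspond to a 50-SNP window, minimum 50 SNPs and 1 Mb per run,
at most five missing calls and no heterozygotes inside a run.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .genotype_io import HET, MISSING, GenotypeDataset

SEGMENT_COLUMNS = ["sample_id", "population", "chrom", "start_bp", "end_bp", "n_snps", "length_bp"]


@dataclass(frozen=True)
class RohParams:
    window_snps: int = 50
    min_snps_in_roh: int = 50
    min_length_bp: int = 1_000_000
    max_missing_in_roh: int = 5
    max_het_in_roh: int = 0
    max_gap_bp: int = 1_000_000
    window_hit_fraction: float = 0.05

    def __post_init__(self) -> None:
        if min(self.window_snps, self.min_snps_in_roh) < 1 or self.min_length_bp <= 0:
            raise ValueError("window_snps, min_snps_in_roh and min_length_bp must be positive")
        if min(self.max_missing_in_roh, self.max_het_in_roh, self.max_gap_bp) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class RohSegment:
    sample_id: str
    population: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass(frozen=True)
class LengthClassScheme:
    """Left-closed, right-open length classes in Mb.

    Default classes 0-5, 5-10, 10-20, 20-40, >40; the caller's 1 Mb minimum
    length means the first class effectively holds 1-5 Mb segments.
    """

    boundaries_mb: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0, 40.0)

    def __post_init__(self) -> None:
        b = self.boundaries_mb
        if len(b) < 1 or any(x >= y for x, y in zip(b, b[1:])):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        b = self.boundaries_mb
        labs = [f"{_trim(x)}-{_trim(y)}" for x, y in zip(b, b[1:])]
        labs.append(f">{_trim(b[-1])}")
        return labs

    def classify(self, length_mb: float) -> str:
        b = self.boundaries_mb
        if length_mb < b[0]:
            raise ValueError(f"length {length_mb} Mb below the first class boundary")
        idx = int(np.searchsorted(np.asarray(b), length_mb, side="right")) - 1
        return self.labels[idx]


def _trim(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


def segment_length_mb(start_bp: int, end_bp: int) -> float:
    """Reporting length in Mb: (end - start)/1e6 rounded half-up to 2 decimals."""
    if end_bp <= start_bp:
        raise ValueError("end_bp must exceed start_bp")
    mb = Decimal(end_bp - start_bp) / Decimal(1_000_000)
    return float(mb.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def detect_roh_individual(
    genotype_row: np.ndarray,
    snp_map: pd.DataFrame,
    params: RohParams = RohParams(),
    sample_id: str = "",
    population: str = "",
) -> list[RohSegment]:
    """Call ROH segments for one individual (see module docstring for the algorithm)."""
    g = np.asarray(genotype_row)
    if len(g) != len(snp_map):
        raise ValueError("genotype_row length does not match the SNP map")
    segments: list[RohSegment] = []
    chroms = snp_map["chrom"].to_numpy()
    bps = snp_map["bp"].to_numpy()
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            block_bp = bps[start:i]
            if not np.all(np.diff(block_bp) >= 0):
                raise ValueError(f"SNP map not sorted by bp within chromosome {chroms[start]}")
            segments.extend(
                _detect_block(
                    g[start:i], block_bp, str(chroms[start]), params, sample_id, population
                )
            )
            start = i
    return segments


def _detect_block(
    g: np.ndarray,
    bp: np.ndarray,
    chrom: str,
    params: RohParams,
    sample_id: str,
    population: str,
) -> list[RohSegment]:
    n = len(g)
    w = params.window_snps
    if n < w:
        return []
    het = (g == HET).astype(np.int64)
    miss = (g == MISSING).astype(np.int64)
    het_c = np.concatenate([[0], np.cumsum(het)])
    miss_c = np.concatenate([[0], np.cumsum(miss)])
    n_win = n - w + 1
    starts = np.arange(n_win)
    win_ok = (
        (het_c[starts + w] - het_c[starts] <= params.max_het_in_roh)
        & (miss_c[starts + w] - miss_c[starts] <= params.max_missing_in_roh)
    ).astype(np.int64)
    ok_c = np.concatenate([[0], np.cumsum(win_ok)])

    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, n_win - 1)
    n_cover = hi - lo + 1
    n_hom = ok_c[hi + 1] - ok_c[lo]
    flagged = n_hom / n_cover > params.window_hit_fraction

    segments: list[RohSegment] = []
    i = 0
    while i < n:
        if not flagged[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flagged[j + 1]:
            j += 1
        # split the flagged stretch at physical gaps
        s = i
        for k in range(i, j + 1):
            if k > s and bp[k] - bp[k - 1] > params.max_gap_bp:
                _maybe_emit(segments, g, bp, chrom, s, k - 1, params, sample_id, population)
                s = k
        _maybe_emit(segments, g, bp, chrom, s, j, params, sample_id, population)
        i = j + 1
    return segments


def _maybe_emit(
    segments: list[RohSegment],
    g: np.ndarray,
    bp: np.ndarray,
    chrom: str,
    s: int,
    e: int,
    params: RohParams,
    sample_id: str,
    population: str,
) -> None:
    run = g[s : e + 1]
    if (
        e - s + 1 >= params.min_snps_in_roh
        and bp[e] - bp[s] >= params.min_length_bp
        and int((run == HET).sum()) <= params.max_het_in_roh
        and int((run == MISSING).sum()) <= params.max_missing_in_roh
    ):
        segments.append(
            RohSegment(sample_id, population, chrom, int(bp[s]), int(bp[e]), int(e - s + 1))
        )


class RohSet:
    """Collection of ROH segments for a cohort, with sample/population metadata."""

    def __init__(self, segments: pd.DataFrame, samples: pd.DataFrame):
        if segments.empty:
            segments = pd.DataFrame(columns=SEGMENT_COLUMNS)
        self.segments = segments.reset_index(drop=True)
        self.samples = samples.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.segments)

    @classmethod
    def from_segments(cls, segs: list[RohSegment], samples: pd.DataFrame) -> "RohSet":
        rows = [
            (s.sample_id, s.population, s.chrom, s.start_bp, s.end_bp, s.n_snps, s.length_bp)
            for s in segs
        ]
        return cls(pd.DataFrame(rows, columns=SEGMENT_COLUMNS), samples)

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.segments[self.segments["sample_id"] == sample_id]

    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["population"]))


def detect_roh(dataset: GenotypeDataset, params: RohParams = RohParams()) -> RohSet:
    """Call ROH for every sample in the dataset."""
    segs: list[RohSegment] = []
    for i, s in enumerate(dataset.samples.itertuples()):
        segs.extend(
            detect_roh_individual(
                dataset.calls[i], dataset.snps, params, s.sample_id, s.population
            )
        )
    return RohSet.from_segments(segs, dataset.samples)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def classify_lengths(
    roh_set: RohSet, scheme: LengthClassScheme = LengthClassScheme()
) -> pd.DataFrame:
    """Per-population segment counts by length class, with Total row and column."""
    pops = roh_set.populations()
    table = pd.DataFrame(0, index=scheme.labels, columns=pops, dtype=int)
    for seg in roh_set.segments.itertuples():
        lab = scheme.classify(seg.length_bp / 1e6)
        table.loc[lab, seg.population] += 1
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table


def roh_summary(roh_set: RohSet, dataset: GenotypeDataset | None = None) -> pd.DataFrame:
    """Per-population mean segment count per individual, mean/longest length, plus cohort row.

    The mean count divides by ALL individuals in the population, including
    those without any segment.
    """
    samples = dataset.samples if dataset is not None else roh_set.samples
    segs = roh_set.segments
    rows = []
    for pop, grp in samples.groupby("population", sort=False):
        p_segs = segs[segs["population"] == pop]
        n_ind = len(grp)
        rows.append(
            {
                "population": pop,
                "n_individuals": n_ind,
                "n_segments": len(p_segs),
                "mean_roh_per_individual": len(p_segs) / n_ind if n_ind else np.nan,
                "mean_length_mb": p_segs["length_bp"].mean() / 1e6 if len(p_segs) else 0.0,
                "longest_mb": p_segs["length_bp"].max() / 1e6 if len(p_segs) else 0.0,
            }
        )
    with_roh = segs["sample_id"].nunique()
    rows.append(
        {
            "population": "ALL",
            "n_individuals": len(samples),
            "n_segments": len(segs),
            "mean_roh_per_individual": len(segs) / len(samples) if len(samples) else np.nan,
            "mean_length_mb": segs["length_bp"].mean() / 1e6 if len(segs) else 0.0,
            "longest_mb": segs["length_bp"].max() / 1e6 if len(segs) else 0.0,
            "n_individuals_with_roh": with_roh,
        }
    )
    return pd.DataFrame(rows)


def chrom_spans(dataset: GenotypeDataset) -> pd.DataFrame:
    """First/last mapped SNP position per chromosome."""
    g = dataset.snps.groupby("chrom", sort=False)["bp"]
    out = pd.DataFrame({"first_bp": g.min(), "last_bp": g.max()})
    out["span_bp"] = out["last_bp"] - out["first_bp"]
    return out


def chrom_counts_and_coverage(roh_set: RohSet, dataset: GenotypeDataset) -> pd.DataFrame:
    """Per chromosome and population: segment count and mean fraction covered by ROH.

    Coverage divides summed segment length by (chromosome span x population
    size) so an individual with a whole-chromosome segment in a population
    of one gives coverage 1.
    """
    spans = chrom_spans(dataset)
    segs = roh_set.segments
    pops = roh_set.populations()
    rows = []
    for chrom in dataset.chromosomes():
        span = spans.loc[chrom, "span_bp"]
        c_segs = segs[segs["chrom"].astype(str) == str(chrom)]
        for pop in pops + ["ALL"]:
            p_segs = c_segs if pop == "ALL" else c_segs[c_segs["population"] == pop]
            n_ind = (
                len(roh_set.samples)
                if pop == "ALL"
                else int((roh_set.samples["population"] == pop).sum())
            )
            cov = (
                float(p_segs["length_bp"].sum()) / (span * n_ind)
                if span > 0 and n_ind > 0
                else 0.0
            )
            rows.append(
                {
                    "chrom": chrom,
                    "population": pop,
                    "n_segments": len(p_segs),
                    "coverage": cov,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# independent oracle (naive re-implementation used by the test suite)
# ---------------------------------------------------------------------------


def brute_force_roh(
    genotype_row: np.ndarray,
    snp_map: pd.DataFrame,
    params: RohParams = RohParams(),
    sample_id: str = "",
    population: str = "",
) -> list[RohSegment]:
    """Naive O(n*w) scanner implementing the same definition with plain loops.

    Kept deliberately simple and separate from the vectorized caller so the
    two can be cross-checked on random instances.
    """
    g = list(genotype_row)
    out: list[RohSegment] = []
    # group indices per chromosome, in order
    blocks: list[list[int]] = []
    for k in range(len(g)):
        if blocks and snp_map["chrom"].iat[k] == snp_map["chrom"].iat[blocks[-1][-1]]:
            blocks[-1].append(k)
        else:
            blocks.append([k])
    w = params.window_snps
    for block in blocks:
        n = len(block)
        if n < w:
            continue
        hom_windows = []
        for s in range(n - w + 1):
            win = [g[block[s + t]] for t in range(w)]
            n_het = sum(1 for x in win if x == HET)
            n_miss = sum(1 for x in win if x == MISSING)
            hom_windows.append(
                n_het <= params.max_het_in_roh and n_miss <= params.max_missing_in_roh
            )
        flagged = []
        for i in range(n):
            covering = [s for s in range(n - w + 1) if s <= i <= s + w - 1]
            frac = sum(1 for s in covering if hom_windows[s]) / len(covering)
            flagged.append(frac > params.window_hit_fraction)
        # maximal flagged stretches, split at gaps
        runs: list[list[int]] = []
        cur: list[int] = []
        for i in range(n):
            if not flagged[i]:
                if cur:
                    runs.append(cur)
                cur = []
                continue
            if cur and (
                snp_map["bp"].iat[block[i]] - snp_map["bp"].iat[cur[-1]] > params.max_gap_bp
            ):
                runs.append(cur)
                cur = []
            cur.append(block[i])
        if cur:
            runs.append(cur)
        for run in runs:
            vals = [g[k] for k in run]
            start = int(snp_map["bp"].iat[run[0]])
            end = int(snp_map["bp"].iat[run[-1]])
            if (
                len(run) >= params.min_snps_in_roh
                and end - start >= params.min_length_bp
                and sum(1 for x in vals if x == HET) <= params.max_het_in_roh
                and sum(1 for x in vals if x == MISSING) <= params.max_missing_in_roh
            ):
                out.append(
                    RohSegment(
                        sample_id,
                        population,
                        str(snp_map["chrom"].iat[run[0]]),
                        start,
                        end,
                        len(run),
                    )
                )
    return out
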