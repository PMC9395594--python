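"""PLINK-family genotype I/O and the pipeline's in-memory data model.

The central container is :class:`GenotypeDataset`: a (samples x SNPs) matrix of
diploid genotype codes together with a marker map and per-sample population
labels.  Genotype codes count copies of ``allele_b``:

* ``0`` — homozygous ``allele_a``
* ``1`` — heterozygous
* ``2`` — homozygous ``allele_b``
* ``-1`` — missing

Supported dialects are PLINK text (PED/MAP) and PLINK 1 binary
(BED/BIM/FAM, SNP-major).  In the BIM file, ``allele_b`` corresponds to the
A1 (fifth) column, so the genotype code is the A1 dosage; minor allele
frequencies are always recomputed from counts rather than trusted from file
column order.

Non-autosomal chromosome codes (0, X, Y, MT, ...) are retained at read time;
removing them is an explicit, logged QC stage.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)
HOM_A = np.int8(0)
HET = np.int8(1)
HOM_B = np.int8(2)

_BED_MAGIC = b"\x6c\x1b\x01"

SNP_COLUMNS = ["chrom", "snp_id", "cm", "bp", "allele_a", "allele_b"]
SAMPLE_COLUMNS = ["sample_id", "population"]


class PlinkFormatError(ValueError):
    """Raised when a PLINK-family file violates its format contract."""


def chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    """Sort numeric chromosome labels numerically, everything else after."""
    c = str(chrom)
    if c.isdigit():
        return (0, int(c))
    return (1, c)


@dataclass(frozen=True)
class SnpRecord:
    """One marker: chromosome label, id, genetic (cM) and physical (bp) position."""

    chrom: str
    snp_id: str
    cm: float
    bp: int
    allele_a: str
    allele_b: str


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    population: str


@dataclass
class GenotypeDataset:
    """Samples x SNPs diploid genotype matrix with marker map and labels.

    Parameters
    ----------
    snps : pandas.DataFrame
        Columns ``chrom, snp_id, cm, bp, allele_a, allele_b``, sorted by
        (chrom, bp) with chromosome blocks contiguous.
    samples : pandas.DataFrame
        Columns ``sample_id, population``.
    calls : numpy.ndarray of int8, shape (n_samples, n_snps)
        Genotype codes in {-1, 0, 1, 2}.
    """

    snps: pd.DataFrame
    samples: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # -- basic properties -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def validate(self) -> None:
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"({len(self.samples)} samples, {len(self.snps)} SNPs)"
            )
        if self.n_snps:
            bad = ~np.isin(self.calls, [-1, 0, 1, 2])
            if bad.any():
                raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
            ids = self.snps["snp_id"]
            if ids.duplicated().any():
                dup = ids[ids.duplicated()].iloc[0]
                raise PlinkFormatError(f"duplicate snp_id {dup!r}")
            if (self.snps["bp"] <= 0).any():
                raise ValueError("bp positions must be positive")
            # chromosome blocks contiguous, bp ascending within block
            chroms = self.snps["chrom"].to_numpy()
            seen: set[str] = set()
            prev = None
            for c in chroms:
                if c != prev:
                    if c in seen:
                        raise ValueError(f"chromosome {c} appears in two blocks")
                    seen.add(c)
                    prev = c
            for _, block in self.snps.groupby("chrom", sort=False):
                if not block["bp"].is_monotonic_increasing:
                    raise ValueError("bp must be ascending within each chromosome")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id")

    def chromosomes(self) -> list[str]:
        """Chromosome labels in map order."""
        return list(dict.fromkeys(self.snps["chrom"]))

    def chrom_slices(self) -> dict[str, slice]:
        """Map chromosome label -> slice of SNP indices (blocks are contiguous)."""
        out: dict[str, slice] = {}
        chroms = self.snps["chrom"].to_numpy()
        if len(chroms) == 0:
            return out
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out

    def dosage(self) -> np.ndarray:
        """Float copy of calls with missing as NaN (allele_b count)."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    # -- subsetting --------------------------------------------------------

    def subset(
        self,
        sample_idx: Sequence[int] | np.ndarray | None = None,
        snp_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeDataset":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeDataset(
            snps=self.snps.iloc[vi].reset_index(drop=True),
            samples=self.samples.iloc[si].reset_index(drop=True),
            calls=self.calls[np.ix_(si, vi)],
        )

    def sort_map(self) -> "GenotypeDataset":
        """Return a copy with SNPs ordered by (chrom, bp)."""
        order = sorted(
            range(self.n_snps),
            key=lambda i: (chrom_sort_key(self.snps["chrom"].iat[i]), self.snps["bp"].iat[i]),
        )
        return self.subset(snp_idx=order)

    def canonicalize_alleles(self) -> "GenotypeDataset":
        """Reorient each SNP so allele_b is the minor allele.

        Ties at frequency 0.5 are broken so that allele_b is the
        lexicographically larger code.  This is the orientation
        :func:`read_ped_map` infers, making text round-trips exact.
        """
        snps = self.snps.copy()
        calls = self.calls.copy()
        for j in range(self.n_snps):
            col = calls[:, j]
            obs = col[col != MISSING]
            n_b = int((obs == HET).sum() + 2 * (obs == HOM_B).sum())
            n_tot = 2 * len(obs)
            a, b = snps.at[j, "allele_a"], snps.at[j, "allele_b"]
            flip = False
            if n_tot:
                if 2 * n_b > n_tot:
                    flip = True
                elif 2 * n_b == n_tot and a > b:
                    flip = True
            if flip:
                snps.at[j, "allele_a"], snps.at[j, "allele_b"] = b, a
                het = col == HET
                miss = col == MISSING
                col[:] = 2 - col
                col[het] = HET
                col[miss] = MISSING
        return GenotypeDataset(snps=snps, samples=self.samples.copy(), calls=calls)

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.snps.equals(other.snps)
            and self.samples.equals(other.samples)
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# PED/MAP (PLINK text)
# ---------------------------------------------------------------------------


def _as_lines(source) -> list[str]:
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    elif isinstance(source, io.TextIOBase):
        text = source.read()
    else:
        text = source.read()
        if isinstance(text, bytes):
            text = text.decode()
    return [ln for ln in text.splitlines() if ln.strip()]


def read_map(map_source) -> pd.DataFrame:
    rows = []
    for i, line in enumerate(_as_lines(map_source)):
        parts = line.split()
        if len(parts) != 4:
            raise PlinkFormatError(f"MAP line {i + 1}: expected 4 columns, got {len(parts)}")
        rows.append((parts[0], parts[1], float(parts[2]), int(parts[3])))
    df = pd.DataFrame(rows, columns=["chrom", "snp_id", "cm", "bp"])
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise PlinkFormatError(f"duplicate snp_id {dup!r} in MAP")
    return df


def read_ped_map(ped_source, map_source) -> GenotypeDataset:
    """Read a PLINK text fileset.

    The PED family-ID column is taken as the population label; allele "0"
    denotes missing.  Because PED/MAP stores no reference alleles, each SNP
    is oriented so allele_b is the minor allele (frequency tie broken
    lexicographically); SNPs are returned sorted by (chrom, bp).
    """
    snp_df = read_map(map_source)
    n_snps = len(snp_df)
    sample_rows = []
    allele_pairs: list[list[tuple[str, str]]] = []
    for i, line in enumerate(_as_lines(ped_source)):
        parts = line.split()
        if len(parts) != 6 + 2 * n_snps:
            raise PlinkFormatError(
                f"PED row {i + 1}: expected {6 + 2 * n_snps} fields for "
                f"{n_snps} SNPs, got {len(parts)}"
            )
        sample_rows.append((parts[1], parts[0]))
        allele_pairs.append(
            [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n_snps)]
        )
    samples = pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS)
    n_samples = len(samples)

    calls = np.full((n_samples, n_snps), MISSING, dtype=np.int8)
    allele_a = []
    allele_b = []
    for j in range(n_snps):
        counts: dict[str, int] = {}
        for i in range(n_samples):
            for al in allele_pairs[i][j]:
                if al != "0":
                    counts[al] = counts.get(al, 0) + 1
        alleles = sorted(counts)
        if len(alleles) > 2:
            raise PlinkFormatError(
                f"SNP {snp_df['snp_id'].iat[j]!r}: more than two alleles {alleles}"
            )
        if not alleles:
            a, b = "0", "0"
        elif len(alleles) == 1:
            a, b = alleles[0], "0"
        else:
            x, y = alleles  # x < y lexicographically
            # minor allele becomes allele_b; tie -> lexicographically larger
            if counts[x] < counts[y]:
                a, b = y, x
            else:
                a, b = x, y
        allele_a.append(a)
        allele_b.append(b)
        for i in range(n_samples):
            p, q = allele_pairs[i][j]
            if p == "0" or q == "0":
                calls[i, j] = MISSING
            elif p == q:
                calls[i, j] = HOM_B if p == b else HOM_A
            else:
                calls[i, j] = HET

    snp_df = snp_df.assign(allele_a=allele_a, allele_b=allele_b)
    return _sorted_dataset(snp_df[SNP_COLUMNS], samples, calls)


def _sorted_dataset(snps: pd.DataFrame, samples: pd.DataFrame, calls: np.ndarray) -> GenotypeDataset:
    order = sorted(
        range(len(snps)),
        key=lambda i: (chrom_sort_key(snps["chrom"].iat[i]), snps["bp"].iat[i]),
    )
    return GenotypeDataset(
        snps=snps.iloc[order].reset_index(drop=True),
        samples=samples,
        calls=calls[:, order],
    )


def write_ped_map(dataset: GenotypeDataset, ped_sink, map_sink) -> None:
    """Write PED/MAP; missing written as "0 0", heterozygote as "allele_a allele_b"."""
    map_lines = [
        f"{r.chrom}\t{r.snp_id}\t{_fmt_cm(r.cm)}\t{r.bp}"
        for r in dataset.snps.itertuples()
    ]
    _write_text(map_sink, "\n".join(map_lines) + ("\n" if map_lines else ""))

    a = dataset.snps["allele_a"].to_numpy()
    b = dataset.snps["allele_b"].to_numpy()
    ped_lines = []
    for i, s in enumerate(dataset.samples.itertuples()):
        fields = [s.population, s.sample_id, "0", "0", "0", "-9"]
        row = dataset.calls[i]
        for j in range(dataset.n_snps):
            g = row[j]
            if g == MISSING:
                fields += ["0", "0"]
            elif g == HOM_A:
                fields += [a[j], a[j]]
            elif g == HET:
                fields += [a[j], b[j]]
            else:
                fields += [b[j], b[j]]
        ped_lines.append(" ".join(fields))
    _write_text(ped_sink, "\n".join(ped_lines) + ("\n" if ped_lines else ""))


def _fmt_cm(cm: float) -> str:
    return str(int(cm)) if float(cm).is_integer() else repr(float(cm))


def _write_text(sink, text: str) -> None:
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text)
    else:
        sink.write(text)


# ---------------------------------------------------------------------------
# BED/BIM/FAM (PLINK 1 binary, SNP-major)
# ---------------------------------------------------------------------------

# PLINK 1 2-bit codes -> genotype code (A1 = allele_b is the counted allele):
# 00 = hom A1 -> 2, 01 = missing -> -1, 10 = het -> 1, 11 = hom A2 -> 0
_BED_DECODE = np.array([HOM_B, MISSING, HET, HOM_A], dtype=np.int8)
_BED_ENCODE = {int(HOM_B): 0b00, int(MISSING): 0b01, int(HET): 0b10, int(HOM_A): 0b11}


def read_bim(bim_source) -> pd.DataFrame:
    rows = []
    for i, line in enumerate(_as_lines(bim_source)):
        parts = line.split()
        if len(parts) != 6:
            raise PlinkFormatError(f"BIM line {i + 1}: expected 6 columns, got {len(parts)}")
        chrom, snp_id, cm, bp, a1, a2 = parts
        rows.append((chrom, snp_id, float(cm), int(bp), a2, a1))
    df = pd.DataFrame(rows, columns=SNP_COLUMNS)
    if df["snp_id"].duplicated().any():
        raise PlinkFormatError("duplicate snp_id in BIM")
    return df


def read_fam(fam_source) -> pd.DataFrame:
    rows = []
    for i, line in enumerate(_as_lines(fam_source)):
        parts = line.split()
        if len(parts) != 6:
            raise PlinkFormatError(f"FAM line {i + 1}: expected 6 columns, got {len(parts)}")
        rows.append((parts[1], parts[0]))
    if not rows:
        raise PlinkFormatError("FAM file contains no samples")
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def _read_bytes(source) -> bytes:
    if isinstance(source, (str, Path)):
        return Path(source).read_bytes()
    return source.read()


def read_bed_bim_fam(bed_source, bim_source, fam_source) -> GenotypeDataset:
    """Read a PLINK 1 binary fileset (SNP-major)."""
    snps = read_bim(bim_source)
    samples = read_fam(fam_source)
    raw = _read_bytes(bed_source)
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(
            f"bad BED magic bytes {raw[:3]!r}; expected SNP-major PLINK 1 header"
        )
    n_samples, n_snps = len(samples), len(snps)
    bytes_per_snp = (n_samples + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if len(body) != bytes_per_snp * n_snps:
        raise PlinkFormatError(
            f"BED body has {len(body)} bytes; expected {bytes_per_snp * n_snps} "
            f"for {n_samples} samples x {n_snps} SNPs"
        )
    mat = body.reshape(n_snps, bytes_per_snp)
    # unpack 2-bit fields, lowest bits first within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (mat[:, :, None] >> shifts[None, None, :]) & 0b11
    two_bit = two_bit.reshape(n_snps, bytes_per_snp * 4)[:, :n_samples]
    calls = _BED_DECODE[two_bit].T.copy()
    return _sorted_dataset(snps, samples, calls)


def write_bed_bim_fam(dataset: GenotypeDataset, bed_sink, bim_sink, fam_sink) -> None:
    bim_lines = [
        f"{r.chrom}\t{r.snp_id}\t{_fmt_cm(r.cm)}\t{r.bp}\t{r.allele_b}\t{r.allele_a}"
        for r in dataset.snps.itertuples()
    ]
    _write_text(bim_sink, "\n".join(bim_lines) + ("\n" if bim_lines else ""))
    fam_lines = [
        f"{s.population}\t{s.sample_id}\t0\t0\t0\t-9" for s in dataset.samples.itertuples()
    ]
    _write_text(fam_sink, "\n".join(fam_lines) + ("\n" if fam_lines else ""))

    n_samples = dataset.n_samples
    bytes_per_snp = (n_samples + 3) // 4
    enc = np.zeros((dataset.n_snps, bytes_per_snp * 4), dtype=np.uint8)
    calls_t = dataset.calls.T
    for g, bits in _BED_ENCODE.items():
        enc[:, :n_samples][calls_t == g] = bits
    # padding samples encode as hom A1 (00), ignored on read
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (enc.reshape(dataset.n_snps, bytes_per_snp, 4) << shifts[None, None, :]).sum(
        axis=2, dtype=np.uint16
    ).astype(np.uint8)
    data = _BED_MAGIC + packed.tobytes()
    if isinstance(bed_sink, (str, Path)):
        Path(bed_sink).write_bytes(data)
    else:
        bed_sink.write(data)


# ---------------------------------------------------------------------------
# prefix helpers
# ---------------------------------------------------------------------------


def read_plink_prefix(prefix: str | Path, fmt: str | None = None) -> GenotypeDataset:
    """Read ``prefix.ped/.map`` or ``prefix.bed/.bim/.fam``, autodetecting if fmt is None."""
    prefix = Path(prefix)
    if fmt is None:
        fmt = "bed" if prefix.with_suffix(".bed").exists() else "ped"
    if fmt == "ped":
        return read_ped_map(prefix.with_suffix(".ped"), prefix.with_suffix(".map"))
    if fmt == "bed":
        return read_bed_bim_fam(
            prefix.with_suffix(".bed"), prefix.with_suffix(".bim"), prefix.with_suffix(".fam")
        )
    raise ValueError(f"unknown format {fmt!r}")


def write_plink_prefix(dataset: GenotypeDataset, prefix: str | Path, fmt: str = "ped") -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "ped":
        write_ped_map(dataset, prefix.with_suffix(".ped"), prefix.with_suffix(".map"))
    elif fmt == "bed":
        write_bed_bim_fam(
            dataset, prefix.with_suffix(".bed"), prefix.with_suffix(".bim"), prefix.with_suffix(".fam")
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
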