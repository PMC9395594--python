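"""End-to-end pipeline: QC -> ROH -> inbreeding -> Ne -> islands -> structure.

``run_pipeline`` executes every stage in order on one genotype fileset and
writes the report tables (tab-separated UTF-8 with header lines) plus a
machine-readable manifest.  The same config and input always produce
byte-identical outputs.  Cross-table consistency (class-count totals versus
segment counts, summary means versus totals) is asserted before anything is
written.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .genotype_io import GenotypeDataset, read_plink_prefix
from .inbreeding import (
    autosome_length_bp,
    froh_class_table,
    froh_fhom_correlation,
    inbreeding_table,
)
from .islands import islands_to_bed, scan_islands
from .ne import NeParams, ne_trajectory
from .qc import QcParams, apply_qc
from .roh import LengthClassScheme, RohParams, classify_lengths, detect_roh, roh_summary, chrom_counts_and_coverage
from .structure import PruneParams, ibs_matrix, ld_prune, pca, remove_related


@dataclass
class PipelineConfig:
    input_prefix: str = ""
    input_format: str | None = None  # ped | bed | autodetect
    qc: QcParams = field(default_factory=QcParams)
    roh: RohParams = field(default_factory=RohParams)
    length_classes: LengthClassScheme = field(default_factory=LengthClassScheme)
    ne: NeParams = field(default_factory=NeParams)
    island_thresholds: tuple[float, ...] = (0.7, 0.5, 0.2)
    min_island_snps: int = 10
    prune: PruneParams = field(default_factory=PruneParams)
    ibs_cutoff: float = 0.65
    l_auto_mb: float | None = None  # override; None = compute from data
    n_pcs: int = 10
    out_dir: str = "rohscape_out"
    seed: int = 0

    def __post_init__(self) -> None:
        for t in self.island_thresholds:
            if not (0.0 < t <= 1.0):
                raise ValueError("island thresholds must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, klass in [
            ("qc", QcParams),
            ("roh", RohParams),
            ("ne", NeParams),
            ("prune", PruneParams),
        ]:
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        if "length_classes" in kwargs and isinstance(kwargs["length_classes"], list):
            kwargs["length_classes"] = LengthClassScheme(tuple(kwargs["length_classes"]))
        if "island_thresholds" in kwargs:
            kwargs["island_thresholds"] = tuple(kwargs["island_thresholds"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def conv(x):
            if dataclasses.is_dataclass(x) and not isinstance(x, type):
                return {f.name: conv(getattr(x, f.name)) for f in dataclasses.fields(x)}
            if isinstance(x, tuple):
                return list(x)
            return x

        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}


@dataclass
class ReportBundle:
    qc_report: pd.DataFrame
    roh_segments: pd.DataFrame
    class_counts: pd.DataFrame
    froh_by_class: pd.DataFrame
    inbreeding: pd.DataFrame
    froh_fhom_corr: pd.Series
    roh_summary: pd.DataFrame
    chrom_table: pd.DataFrame
    ne_trajectory: pd.DataFrame
    incidence: pd.DataFrame
    islands: dict[float, pd.DataFrame]
    pca_coords: pd.DataFrame
    pruned_snp_ids: list[str]
    manifest: dict


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def make_manhattan_table(incidence: pd.DataFrame) -> pd.DataFrame:
    """Long-format (population, chrom, bp, incidence %) with a cumulative genome coordinate."""
    if incidence.empty:
        return pd.DataFrame(columns=["population", "chrom", "bp", "incidence_pct", "cum_bp"])
    pops = [c for c in incidence.columns if c not in ("chrom", "bp")]
    offsets = {}
    cum = 0
    for chrom, grp in incidence.groupby("chrom", sort=False):
        offsets[chrom] = cum
        cum += int(grp["bp"].max()) + 1
    rows = []
    for pop in pops:
        for r in incidence.itertuples():
            rows.append(
                {
                    "population": pop,
                    "chrom": r.chrom,
                    "bp": r.bp,
                    "incidence_pct": 100.0 * getattr(r, pop),
                    "cum_bp": offsets[r.chrom] + r.bp,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, dataset: GenotypeDataset | None = None) -> ReportBundle:
    """Run every stage and write tables under config.out_dir. See module docstring."""
    timings: dict[str, float] = {}

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # annotate with the stage name
            raise PipelineError(name, exc) from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        return out

    if dataset is None:
        dataset = stage("read", lambda: read_plink_prefix(config.input_prefix, config.input_format))
    ds, qc_report = stage("qc", lambda: apply_qc(dataset, config.qc))

    roh_set = stage("roh", lambda: detect_roh(ds, config.roh))
    class_counts = stage("classify", lambda: classify_lengths(roh_set, config.length_classes))
    summary = stage("summary", lambda: roh_summary(roh_set, ds))
    chrom_table = stage("chrom", lambda: chrom_counts_and_coverage(roh_set, ds))

    l_auto_bp = (
        int(config.l_auto_mb * 1e6) if config.l_auto_mb else autosome_length_bp(ds)
    )
    inb = stage(
        "inbreeding", lambda: inbreeding_table(ds, roh_set, l_auto_bp, config.length_classes)
    )
    froh_cls = stage("froh_class", lambda: froh_class_table(roh_set, l_auto_bp, config.length_classes))
    corr = stage(
        "correlation",
        lambda: froh_fhom_correlation(
            inb.rename(columns={"F_ROH": "F_ROH"}), "population"
        ),
    )

    ne_df = stage("ne", lambda: ne_trajectory(ds, config.ne))

    incidence = None
    islands: dict[float, pd.DataFrame] = {}
    for thr in config.island_thresholds:
        track_df, isl = stage(
            f"islands_{thr}",
            lambda thr=thr: scan_islands(roh_set, ds, thr, config.min_island_snps),
        )
        if incidence is None:
            incidence = track_df
        islands[thr] = isl
    if incidence is None:
        incidence = pd.DataFrame(columns=["chrom", "bp"])

    pruned_idx = stage("prune", lambda: ld_prune(ds, config.prune))
    pruned = ds.subset(snp_idx=pruned_idx)
    unrelated = stage("ibs", lambda: remove_related(pruned, config.ibs_cutoff))
    k = min(config.n_pcs, unrelated.n_samples - 1)
    pca_res = stage("pca", lambda: pca(unrelated, k))

    # cross-table consistency
    assert int(class_counts.loc["Total", "Total"]) == len(roh_set), "class counts != segments"
    all_row = summary[summary["population"] == "ALL"].iloc[0]
    assert int(all_row["n_segments"]) == len(roh_set), "summary totals != segments"

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "n_samples_in": dataset.n_samples,
        "n_snps_in": dataset.n_snps,
        "n_snps_qc": ds.n_snps,
        "n_segments": len(roh_set),
        "l_auto_bp": l_auto_bp,
        "stage_seconds": timings,
    }

    bundle = ReportBundle(
        qc_report=qc_report.to_frame(),
        roh_segments=roh_set.segments,
        class_counts=class_counts,
        froh_by_class=froh_cls,
        inbreeding=inb,
        froh_fhom_corr=corr,
        roh_summary=summary,
        chrom_table=chrom_table,
        ne_trajectory=ne_df,
        incidence=incidence,
        islands=islands,
        pca_coords=pca_res.coordinates,
        pruned_snp_ids=list(pruned.snps["snp_id"]),
        manifest=manifest,
    )
    _write_bundle(bundle, Path(config.out_dir))
    return bundle


def _write_bundle(bundle: ReportBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)

    def tsv(df: pd.DataFrame, name: str, index: bool = False) -> None:
        df.to_csv(out_dir / name, sep="\t", index=index)

    tsv(bundle.qc_report, "qc_report.tsv")
    tsv(bundle.roh_segments, "roh_segments.tsv")
    tsv(bundle.class_counts, "table2_class_counts.tsv", index=True)
    tsv(bundle.froh_by_class, "table1_froh_by_class.tsv")
    tsv(bundle.inbreeding, "inbreeding.tsv")
    tsv(bundle.roh_summary, "roh_summary.tsv")
    tsv(bundle.chrom_table, "chromosome_table.tsv")
    tsv(bundle.ne_trajectory, "ne_trajectory.tsv")
    tsv(bundle.incidence, "incidence_tracks.tsv")
    tsv(make_manhattan_table(bundle.incidence), "manhattan.tsv")
    for thr, isl in bundle.islands.items():
        pct = int(round(100 * thr))
        tsv(isl, f"table3_islands_{pct}.tsv")
    bed_rows = []
    for thr, isl in bundle.islands.items():
        for r in isl.itertuples():
            bed_rows.append(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{r.population}:{thr}")
    (out_dir / "islands.bed").write_text("\n".join(bed_rows) + ("\n" if bed_rows else ""))
    tsv(bundle.pca_coords, "pca_coordinates.tsv")
    (out_dir / "pruned_snps.txt").write_text("\n".join(bundle.pruned_snp_ids) + "\n")
    bundle.froh_fhom_corr.rename("pearson_r").to_csv(out_dir / "froh_fhom_correlation.tsv", sep="\t")
    manifest = dict(bundle.manifest)
    manifest["stage_seconds"] = {}  # keep outputs byte-reproducible
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
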