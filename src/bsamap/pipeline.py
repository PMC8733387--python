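"""End-to-end orchestration: simulate or load counts, scan, report.

A run is described by a flat :class:`RunConfig` (serialisable to YAML);
every run writes its resolved configuration next to its outputs, so a run
directory is self-describing and reproducible from the seed alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import annot, io
from .scan import ScanConfig, ScanResult, scan
from .sim import simulate_bsa_experiment

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs, as a flat serialisable record."""

    outdir: str = "bsamap_run"
    seed: int = 0
    # input; when counts_path is None a synthetic experiment is simulated
    counts_path: str | None = None
    counts_format: str | None = None
    genes_path: str | None = None
    chrom_lengths: dict[str, int] | None = None
    # scan parameters
    min_index: float = 0.3
    min_depth: int = 7
    window_bp: int = 2_000_000
    step_bp: int = 100_000
    n_bootstrap: int = 1000
    conf_levels: tuple[float, ...] = (0.95, 0.99)
    bulk_size: int = 30
    null_model: str = "two_stage"
    depth_rule: str = "either"
    # simulation parameters (used only without counts_path)
    n_offspring: int = 117
    chrom_length: int = 10_000_000
    n_variants: int = 500
    sex_locus_pos: int | None = 5_000_000
    mean_depth_f: float = 32.0
    mean_depth_m: float = 34.0
    error_rate: float = 0.001
    recomb_rate: float = 4.0
    log_level: str = "INFO"

    def scan_config(self) -> ScanConfig:
        return ScanConfig(
            min_index=self.min_index,
            min_depth=self.min_depth,
            window_bp=self.window_bp,
            step_bp=self.step_bp,
            n_bootstrap=self.n_bootstrap,
            conf_levels=tuple(self.conf_levels),
            bulk_size=self.bulk_size,
            null_model=self.null_model,
            depth_rule=self.depth_rule,
            seed=self.seed,
        )

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["conf_levels"] = list(self.conf_levels)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "conf_levels" in data:
            data["conf_levels"] = tuple(data["conf_levels"])
        return cls(**data)


def _setup_run_logging(outdir: Path, level: str) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    # no timestamps: run directories are byte-reproducible given the seed
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("bsamap")
    root.setLevel(level)
    root.addHandler(handler)
    return handler


def run_pipeline(config: RunConfig) -> ScanResult:
    """Run the scan end to end and write all outputs under ``config.outdir``.

    Outputs: the (simulated or echoed) allele counts, phenotypes for
    simulated runs, the per-depth threshold table, window statistics,
    candidate regions at every confidence level (BED + 1-based TSV), a
    genes-in-region report when a gene table is supplied, the resolved
    configuration and a log file.  Identical config + seed give
    byte-identical outputs.
    """
    scan_cfg = config.scan_config()  # validates parameters up front
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(outdir, config.log_level)
    try:
        if config.counts_path is None:
            logger.info("simulating an FF x MF experiment (seed=%d)", config.seed)
            exp = simulate_bsa_experiment(
                seed=config.seed,
                n_offspring=config.n_offspring,
                bulk_size=config.bulk_size,
                chrom_lengths=(("chr1", config.chrom_length),),
                variants_per_chrom=config.n_variants,
                sex_locus=("chr1", config.sex_locus_pos) if config.sex_locus_pos else None,
                recomb_rate=config.recomb_rate,
                mean_depth_f=config.mean_depth_f,
                mean_depth_m=config.mean_depth_m,
                error_rate=config.error_rate,
            )
            counts = exp.counts
            chrom_lengths = exp.genome.chrom_lengths
            io.write_counts_tsv(counts, outdir / "counts.tsv")
            io.write_phenotypes(exp.phenotypes, outdir / "phenotypes.tsv")
        else:
            counts = io.read_counts(config.counts_path, config.counts_format)
            chrom_lengths = config.chrom_lengths or {
                chrom: int(sub["pos"].max())
                for chrom, sub in counts.groupby("chrom", sort=True)
            }
        logger.info("scanning %d variants on %d chromosomes", len(counts), len(chrom_lengths))
        result = scan(counts, chrom_lengths, scan_cfg)
        io.write_windows(result.windows, outdir / "windows.tsv")
        io.write_thresholds(result.thresholds, outdir / "thresholds.tsv")
        genes = (
            annot.read_genes_tsv(config.genes_path)
            if config.genes_path and str(config.genes_path).endswith(".tsv")
            else annot.read_genes_gff3(config.genes_path)
            if config.genes_path
            else None
        )
        gene_reports = []
        for level, regions in result.regions.items():
            tag = f"{round(level * 100):d}"
            io.write_regions_bed(regions, outdir / f"regions_{tag}.bed")
            io.write_regions_tsv(regions, outdir / f"regions_{tag}.tsv")
            logger.info("%d candidate region(s) at the %s%% level", len(regions), tag)
            if genes is not None:
                for row in regions.itertuples(index=False):
                    hits = annot.genes_in_region(genes, row.chrom, row.start, row.end - 1)
                    hits = hits.assign(region=f"{row.chrom}:{row.start}-{row.end - 1}", level=level)
                    gene_reports.append(hits)
        if genes is not None:
            report = (
                pd.concat(gene_reports, ignore_index=True)
                if gene_reports
                else pd.DataFrame(columns=annot.GENE_COLUMNS + ["region", "level"])
            )
            report.to_csv(outdir / "region_genes.tsv", sep="\t", index=False)
        config.to_yaml(outdir / "config.yaml")
        return result
    finally:
        logging.getLogger("bsamap").removeHandler(handler)
        handler.close()
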