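"""Readers and writers for the pipeline's file formats.

Allele counts travel either as a flat TSV (chrom, pos, ref, alt,
variant_type, refF, altF, refM, altM) or as a minimal two-sample VCF 4.2
whose F_bulk / M_bulk samples carry AD (allelic depth) fields.  All TSV
coordinates are 1-based; candidate regions are additionally written as
0-based half-open BED.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .linkage import MarkerCalls, sex_as_marker
from .sim import COUNT_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_counts_vcf",
    "write_counts_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "read_genotype_matrix",
    "write_windows",
    "write_thresholds",
    "write_regions_bed",
    "write_regions_tsv",
    "regions_to_bed",
    "bed_to_regions",
    "read_fasta",
]

_SEX_PHENOTYPES = {"female", "male", "hermaphrodite"}


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: allele-count table lacks columns {missing}")
    for col in ("refF", "altF", "refM", "altM"):
        if (df[col] < 0).any():
            bad = int(df.index[df[col] < 0][0]) + 2  # +1 header, +1 1-based
            raise ValueError(f"{path}:{bad}: negative read count in column {col}")
    return df[COUNT_COLUMNS].sort_values(["chrom", "pos"], ignore_index=True)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=bsamap
{contigs}##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tF_bulk\tM_bulk
"""


def write_counts_vcf(counts: pd.DataFrame, path, chrom_lengths: dict[str, int] | None = None) -> None:
    """Write allele counts as a minimal VCF 4.2 with F_bulk and M_bulk samples."""
    contigs = ""
    if chrom_lengths:
        contigs = "".join(
            f"##contig=<ID={c},length={l}>\n" for c, l in chrom_lengths.items()
        )
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs))
        for row in counts.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\t"
                f"GT:AD\t./.:{row.refF},{row.altF}\t./.:{row.refM},{row.altM}\n"
            )


def read_counts_vcf(path, multiallelic: str = "skip") -> pd.DataFrame:
    """Read a two-sample VCF with AD fields into the allele-count schema.

    The first sample is taken as the female bulk and the second as the male
    bulk (samples named F_bulk / M_bulk are reordered by name).  Records
    with missing AD are skipped with a logged warning.  Multi-allelic sites
    are skipped (default) or split into one row per alternate allele.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("skip", "split"):
        raise ValueError("multiallelic must be 'skip' or 'split'")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(samples) != 2:
        raise ValueError(f"{path}: expected exactly two bulk samples, found {len(samples)}")
    f_idx, m_idx = (
        (samples.index("F_bulk"), samples.index("M_bulk"))
        if set(samples) == {"F_bulk", "M_bulk"}
        else (0, 1)
    )
    rows = []
    for v in vcf:
        ad = v.format("AD")
        if ad is None or np.any(ad < 0):
            logger.warning("%s:%s missing AD, record skipped", v.CHROM, v.POS)
            continue
        alts = v.ALT
        if len(alts) != 1 and multiallelic == "skip":
            logger.warning("%s:%s multi-allelic record skipped", v.CHROM, v.POS)
            continue
        vtype = "SNP" if all(len(a) == len(v.REF) == 1 for a in alts) else "InDel"
        for ai, alt in enumerate(alts, start=1):
            rows.append(
                {
                    "chrom": v.CHROM,
                    "pos": v.POS,
                    "ref": v.REF,
                    "alt": alt,
                    "variant_type": vtype,
                    "refF": int(ad[f_idx, 0]),
                    "altF": int(ad[f_idx, ai]),
                    "refM": int(ad[m_idx, 0]),
                    "altM": int(ad[m_idx, ai]),
                }
            )
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    return df.sort_values(["chrom", "pos"], ignore_index=True)


def read_counts(path, fmt: str | None = None) -> pd.DataFrame:
    """Read allele counts, inferring VCF vs TSV from the extension if needed."""
    if fmt is None:
        fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "vcf":
        return read_counts_vcf(path)
    if fmt == "tsv":
        return read_counts_tsv(path)
    raise ValueError(f"unknown counts format {fmt!r}")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["individual", "phenotype"]:
        raise ValueError(f"{path}: expected columns individual, phenotype")
    bad = ~df["phenotype"].isin(_SEX_PHENOTYPES)
    if bad.any():
        raise ValueError(f"{path}: unrecognised phenotypes {sorted(df.loc[bad, 'phenotype'])}")
    return df


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes[["individual", "phenotype"]].to_csv(path, sep="\t", index=False)


def read_genotype_matrix(path) -> tuple[list[str], list[MarkerCalls]]:
    """Read a testcross genotype matrix: rows individuals, columns markers.

    Calls are a/b/- per marker.  A column whose values are sex phenotypes is
    automatically recoded as a paternal testcross marker (female -> a,
    male/hermaphrodite -> b).  Returns (individual ids, marker call list).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    first = df.columns[0]
    individuals = df[first].tolist()
    markers = []
    for col in df.columns[1:]:
        values = df[col].fillna("-")
        if set(values.str.lower()) <= _SEX_PHENOTYPES:
            markers.append(sex_as_marker(values.str.lower().tolist(), name=col))
        else:
            markers.append(MarkerCalls(col, values.to_numpy()))
    return individuals, markers


def write_windows(windows: pd.DataFrame, path) -> None:
    windows.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_thresholds(thresholds, path) -> None:
    thresholds.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def regions_to_bed(regions: pd.DataFrame) -> pd.DataFrame:
    """1-based half-open regions -> 0-based half-open BED intervals."""
    bed = regions[["chrom"]].copy()
    bed["start"] = regions["start"] - 1
    bed["end"] = regions["end"] - 1
    bed["name"] = [f"region_{i + 1}" for i in range(len(regions))]
    bed["score"] = regions["peak_value"]
    return bed


def bed_to_regions(bed: pd.DataFrame) -> pd.DataFrame:
    """Exact inverse of :func:`regions_to_bed` on the coordinate columns."""
    out = bed[["chrom"]].copy()
    out["start"] = bed["start"] + 1
    out["end"] = bed["end"] + 1
    if "score" in bed.columns:
        out["peak_value"] = bed["score"]
    return out


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    regions_to_bed(regions).to_csv(path, sep="\t", index=False, header=False,
                                   float_format="%.6g")


def write_regions_tsv(regions: pd.DataFrame, path) -> None:
    """1-based inclusive mirror of the BED output (end column is inclusive)."""
    out = regions.copy()
    out["end"] = out["end"] - 1  # half-open -> inclusive
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
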