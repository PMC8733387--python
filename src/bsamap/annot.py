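"""Gene annotation tables and region-gene intersection reports."""

from __future__ import annotations

import re
from importlib import resources

import pandas as pd

__all__ = [
    "GENE_COLUMNS",
    "genes_in_region",
    "read_genes_tsv",
    "read_genes_gff3",
    "candidate_region_genes",
]

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "annotation"]


def _validate(genes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table lacks columns {missing}")
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene start must not exceed end")
    return genes


def genes_in_region(genes: pd.DataFrame, chrom: str, start: int, end: int) -> pd.DataFrame:
    """Genes overlapping a query interval, 1-based inclusive on both sides.

    A gene overlaps when ``gene.start <= end`` and ``gene.end >= start`` on
    the query chromosome (genome-browser convention: a gene touching the
    boundary base is included).  Results are in positional order.
    """
    if start > end:
        raise ValueError("query start must not exceed end")
    _validate(genes)
    hit = (genes["chrom"] == chrom) & (genes["start"] <= end) & (genes["end"] >= start)
    return genes.loc[hit].sort_values(["start", "end"]).reset_index(drop=True)


def read_genes_tsv(path) -> pd.DataFrame:
    """Read a flat gene table (gene_id, chrom, start, end, annotation)."""
    genes = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return _validate(genes)


_GFF_ID = re.compile(r"(?:^|;)(?:ID|gene_id|Name)=([^;]+)")


def read_genes_gff3(path, feature_types: tuple[str, ...] = ("gene",)) -> pd.DataFrame:
    """Read gene records from a GFF3 file into the flat gene-table schema.

    Keeps rows whose feature type is in ``feature_types``; the gene id is
    taken from the ID/gene_id/Name attribute, and the annotation from the
    remaining attribute string.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, _strand, _phase, attrs = fields
            if ftype not in feature_types:
                continue
            m = _GFF_ID.search(attrs)
            gene_id = m.group(1) if m else f"{chrom}:{start}-{end}"
            rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "annotation": attrs,
                }
            )
    return _validate(pd.DataFrame(rows, columns=GENE_COLUMNS))


def candidate_region_genes() -> pd.DataFrame:
    """The packaged gene table for the mapped candidate interval on chr2."""
    with resources.files("bsamap.data").joinpath("predicted_region_genes.tsv").open() as fh:
        return read_genes_tsv(fh)
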