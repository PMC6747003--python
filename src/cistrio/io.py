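"""Readers and writers for the plain-text formats the pipeline touches.

Dialects
--------
genotype TSV
    columns ``variant_id, chrom, pos, ref, alt`` then one dosage column
    per sample; dosages in {0, 1, 2}, missing encoded as ``.``; ``pos``
    1-based.
expression TSV
    ``gene_id`` as the row key, one column per sample; missing cells are
    empty, ``NA`` or ``.``.
gene BED6
    0-based half-open; converted to 1-based inclusive gene intervals on
    read.
state/region BED
    0-based half-open with the label in the BED name column.
VCF 4.2
    read through cyvcf2 when available; GT fields map ./. -> missing,
    0/0 -> 0, 0/1 -> 1, 1/1 -> 2; multi-allelic records are skipped with
    a warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneInterval, GenotypeMatrix
from .exceptions import FormatError

logger = logging.getLogger(__name__)

_MISSING_TOKENS = ["", "NA", "."]

GENOTYPE_META = ["variant_id", "chrom", "pos", "ref", "alt"]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    """Load a genotype matrix from tabular dosages or VCF.

    Format is inferred from the extension unless ``fmt`` ("tsv" | "vcf")
    is given.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in {".vcf", ".gz"} or path.name.endswith(".vcf.gz") else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_genotype_tsv(path)
    raise FormatError(f"unknown genotype format: {fmt!r}")


def _read_genotype_tsv(path: Path) -> GenotypeMatrix:
    try:
        frame = pd.read_csv(
            path, sep="\t", dtype={"variant_id": str, "chrom": str},
            na_values=_MISSING_TOKENS, keep_default_na=False,
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse genotype TSV ({exc})") from exc
    missing = [c for c in GENOTYPE_META if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: header line 1 lacks columns {missing}")
    frame = frame.set_index("variant_id")
    variants = frame[["chrom", "pos", "ref", "alt"]]
    dosages = frame.drop(columns=["chrom", "pos", "ref", "alt"]).astype(float)
    bad = ~(dosages.isin([0.0, 1.0, 2.0]) | dosages.isna())
    if bad.any().any():
        raise FormatError(f"{path}: dosages must be 0/1/2 or missing")
    return GenotypeMatrix(variants=variants, dosages=dosages)


def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    frame = genotypes.variants.join(genotypes.dosages)
    frame.index.name = "variant_id"
    out = frame.reset_index()
    sample_cols = list(genotypes.dosages.columns)
    out[sample_cols] = out[sample_cols].astype(object)
    for col in sample_cols:
        vals = out[col]
        out[col] = vals.map(lambda v: "." if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False)


def _read_vcf(path: Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise FormatError("cyvcf2 is required to read VCF input") from exc
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    meta, rows, skipped = [], [], 0
    for record in vcf:
        if len(record.ALT) != 1:
            skipped += 1
            continue
        gt = record.gt_types.astype(float)  # 0,1,2; 3 = unknown
        gt[gt == 3] = np.nan
        vid = record.ID or f"{record.CHROM}:{record.POS}"
        meta.append(
            {
                "variant_id": vid,
                "chrom": record.CHROM,
                "pos": record.POS,
                "ref": record.REF,
                "alt": record.ALT[0],
            }
        )
        rows.append(gt)
    if skipped:
        logger.warning("%s: skipped %d multi-allelic record(s)", path, skipped)
    if not rows:
        raise FormatError(f"{path}: no usable biallelic records")
    variants = pd.DataFrame(meta).set_index("variant_id")
    dosages = pd.DataFrame(np.vstack(rows), index=variants.index, columns=samples)
    return GenotypeMatrix(variants=variants, dosages=dosages)


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2 writer with GT-only genotype fields."""
    samples = genotypes.sample_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cistrio\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(genotypes.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        order = genotypes.variants.sort_values(["chrom", "pos"]).index
        for vid in order:
            v = genotypes.variants.loc[vid]
            calls = [
                gt_map.get(d, "./.") if not pd.isna(d) else "./."
                for d in genotypes.dosages.loc[vid]
            ]
            fh.write(
                f"{v['chrom']}\t{int(v['pos'])}\t{vid}\t{v['ref']}\t{v['alt']}"
                f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> ExpressionMatrix:
    frame = pd.read_csv(
        path, sep="\t", index_col=0,
        na_values=_MISSING_TOKENS, keep_default_na=False,
    )
    if frame.index.has_duplicates:
        raise FormatError(f"{path}: duplicate gene ids")
    if frame.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate sample ids")
    frame.index = frame.index.astype(str)
    frame.index.name = "gene_id"
    return ExpressionMatrix(frame.astype(float), scale="raw")


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------


def read_genes_bed(path: str | Path) -> list[GeneInterval]:
    """BED6 gene bodies -> 1-based inclusive :class:`GeneInterval` list."""
    frame = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
        dtype={"chrom": str, "name": str, "strand": str},
    )
    genes = []
    for row in frame.itertuples(index=False):
        genes.append(
            GeneInterval(
                gene_id=row.name,
                chrom=row.chrom,
                start=int(row.start) + 1,  # 0-based half-open -> 1-based inclusive
                end=int(row.end),
                strand=row.strand if row.strand in {"+", "-"} else "+",
            )
        )
    return genes


def write_genes_bed(genes: list[GeneInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n"
            )


def read_states_bed(path: str | Path) -> pd.DataFrame:
    """BroadHMM-style BED (label in column 4) -> segmentation table."""
    frame = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=range(4), names=["chrom", "start", "end", "state"],
        dtype={"chrom": str, "state": str},
    )
    return frame


def read_regions_bed(path: str | Path) -> pd.DataFrame:
    frame = read_states_bed(path)
    return frame.rename(columns={"state": "region"})


# ---------------------------------------------------------------------------
# truth / result tables
# ---------------------------------------------------------------------------


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t")


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
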