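"""Readers and writers for every external format the pipeline touches.

VCF genotypes are read through cyvcf2; tabular formats (expression, gene
annotation, trait QTL catalogs, all pipeline outputs) are TSV; gene sets use
the 3+-column GMT convention. Writers emit a deterministic column order and
fixed float formatting so repeated writes are byte-identical.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    EmptyResultError,
    ExpressionMatrix,
    GenotypeMatrix,
    ParseError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_vcf(path, maf_floor: float = 0.05, missing_ceiling: float = 0.99) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a dosage matrix.

    Dosage is the alt-allele count of the unphased GT call ("0/1" and "1/0"
    both give 1); missing calls become NaN. MAF is computed after excluding
    missing calls. Variants are retained only if ``maf > maf_floor`` and
    ``missing_rate < missing_ceiling``; multi-allelic and non-SNP records are
    dropped with a logged count.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required for VCF input") from exc

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    meta: list[tuple] = []
    n_dropped_shape = 0
    n_dropped_filter = 0
    for i, rec in enumerate(vcf):
        try:
            if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
                n_dropped_shape += 1
                continue
            # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
            g = rec.gt_types.astype(float)
        except Exception as exc:
            raise ParseError(f"malformed VCF record at line index {i}: {exc}") from exc
        g[g == 3] = MISSING
        miss = np.isnan(g)
        missing_rate = float(miss.mean()) if len(g) else 1.0
        if miss.all():
            freq = 0.0
        else:
            freq = float(np.nanmean(g) / 2.0)
        maf = min(freq, 1.0 - freq)
        if not (maf > maf_floor and missing_rate < missing_ceiling):
            n_dropped_filter += 1
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        meta.append((vid, str(rec.CHROM), int(rec.POS), rec.REF, rec.ALT[0], maf, missing_rate))
        rows.append(g)
    if n_dropped_shape:
        logger.info("read_vcf: dropped %d multi-allelic/non-SNP records", n_dropped_shape)
    if n_dropped_filter:
        logger.info("read_vcf: dropped %d records failing MAF/missing filters", n_dropped_filter)
    if not rows:
        raise EmptyResultError(f"no variants retained from {path}")
    variants = pd.DataFrame(
        meta, columns=["variant_id", "chrom", "pos", "ref", "alt", "maf", "missing_rate"]
    )
    return GenotypeMatrix(samples, np.asarray(rows, dtype=float).T, variants)


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write a minimal VCFv4.2 with GT-only calls (inverse of ``read_vcf``)."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = genotypes.variants["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        for j, row in genotypes.variants.iterrows():
            calls = [
                "./." if np.isnan(d) else code[float(d)] for d in genotypes.dosages[:, j]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# expression / annotation / QTL catalog / gene sets
# ---------------------------------------------------------------------------

def read_expression(path) -> ExpressionMatrix:
    """Read a samples x genes TSV with ``sample`` and ``tissue`` columns."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample": str, "tissue": str})
    except Exception as exc:
        raise ParseError(f"cannot parse expression table {path}: {exc}") from exc
    for col in ("sample", "tissue"):
        if col not in df.columns:
            raise ParseError(f"expression table {path} lacks a {col!r} column")
    gene_cols = [c for c in df.columns if c not in ("sample", "tissue")]
    counts = np.empty((len(df), len(gene_cols)))
    for j, g in enumerate(gene_cols):
        col = pd.to_numeric(df[g], errors="coerce")
        if col.isna().any():
            i = int(col.index[col.isna()][0])
            raise ParseError(f"non-numeric count at row {i}, gene {g!r}")
        counts[:, j] = col.to_numpy()
    neg = np.argwhere(counts < 0)
    if len(neg):
        i, j = neg[0]
        raise ParseError(
            f"negative count at sample {df['sample'].iloc[i]!r}, gene {gene_cols[j]!r}"
        )
    return ExpressionMatrix(
        sample_ids=df["sample"].tolist(),
        tissue_labels=df["tissue"].to_numpy(dtype=object),
        gene_ids=gene_cols,
        counts=counts,
    )


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.counts, columns=expr.gene_ids)
    df.insert(0, "tissue", expr.tissue_labels)
    df.insert(0, "sample", expr.sample_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gene_annotation(path) -> pd.DataFrame:
    """Read a BED-like TSV with gene_id, chrom, tss (1-based) and strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    for col in ("gene_id", "chrom", "tss", "strand"):
        if col not in df.columns:
            raise ParseError(f"annotation {path} lacks a {col!r} column")
    if df["gene_id"].duplicated().any():
        raise ParseError(f"annotation {path} has duplicate gene_id values")
    if (df["tss"] < 1).any():
        raise ParseError(f"annotation {path} has tss < 1 (coordinates are 1-based)")
    if not df["strand"].isin(["+", "-"]).all():
        raise ParseError(f"annotation {path} has strand outside {{+,-}}")
    return df.reset_index(drop=True)


def write_gene_annotation(annotation: pd.DataFrame, path) -> None:
    annotation[["gene_id", "chrom", "tss", "strand"]].to_csv(path, sep="\t", index=False)


def read_qtl_catalog(path) -> pd.DataFrame:
    """Read a published trait-QTL catalog (trait, chrom, pos, p, source)."""
    df = pd.read_csv(path, sep="\t", dtype={"trait": str, "chrom": str, "source": str})
    for col in ("trait", "chrom", "pos", "p", "source"):
        if col not in df.columns:
            raise ParseError(f"QTL catalog {path} lacks a {col!r} column")
    if len(df) == 0:
        return df
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        bad = df.loc[(df["p"] <= 0) | (df["p"] > 1), "p"].iloc[0]
        raise ParseError(f"QTL catalog {path}: p={bad} outside (0, 1]")
    dup = df.duplicated(subset=["trait", "chrom", "pos"])
    if dup.any():
        warnings.warn(f"QTL catalog {path}: dropped {int(dup.sum())} duplicate records")
        df = df[~dup]
    return df.reset_index(drop=True)


def read_gene_sets(path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT file into ``{set_id: (description, members)}``.

    Members are deduplicated preserving order; empty sets are dropped.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
            set_id, desc = fields[0], fields[1]
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            if members:
                sets[set_id] = (desc, members)
    return sets


# ---------------------------------------------------------------------------
# output schemas
# ---------------------------------------------------------------------------

_P = "%.5e"   # scientific, 6 significant digits, for p-values
_F = "%.6g"   # effects, SEs, statistics
_SCHEMAS: dict[str, list[tuple[str, str]]] = {
    "assoc": [("predictor_id", "s"), ("beta", _F), ("se", _F), ("z", _F), ("p", _P)],
    "eqtl": [
        ("gene_id", "s"), ("tissue", "s"), ("variant_id", "s"), ("chrom", "s"),
        ("pos", "d"), ("beta", _F), ("se", _F), ("p", _P), ("kind", "s"),
        ("conditional_round", "d"),
    ],
    "cluster": [
        ("cluster_id", "s"), ("variant_id", "s"), ("chrom", "s"), ("pos", "d"),
        ("gene_id", "s"), ("tissue", "s"), ("p", _P), ("is_representative", "d"),
    ],
    "twas": [
        ("gene_id", "s"), ("tissue", "s"), ("trait", "s"), ("beta", _F),
        ("se", _F), ("p", _P),
    ],
    "smr": [
        ("gene_id", "s"), ("tissue", "s"), ("trait", "s"), ("instrument", "s"),
        ("b_xy", _F), ("se_xy", _F), ("p_smr", _P), ("p_heidi", _P),
        ("n_heidi_snps", "d"),
    ],
    "coloc": [
        ("trait", "s"), ("qtl_chrom", "s"), ("qtl_pos", "d"), ("cluster_id", "s"),
        ("variant_id", "s"), ("pos", "d"), ("distance", "d"),
    ],
    "specificity": [
        ("gene_id", "s"), ("tissue", "s"), ("t_stat", _F), ("rank_pct", _F),
        ("median_fc", _F), ("is_specific", "d"),
    ],
    "enrichment": [
        ("set_id", "s"), ("k", "d"), ("K", "d"), ("n", "d"), ("N", "d"),
        ("fold", _F), ("p_hyper", _P), ("fdr", _P),
    ],
}


def _format_cell(value, fmt: str) -> str:
    if fmt == "s":
        return str(value)
    if fmt == "d":
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return "NA"
        return str(int(value))
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "NA"
    return fmt % float(value)


def write_table(records: pd.DataFrame, path, schema_id: str) -> None:
    """Write records under a registered output schema (TSV, fixed formats)."""
    if schema_id not in _SCHEMAS:
        raise ValueError(f"unknown output schema {schema_id!r}")
    schema = _SCHEMAS[schema_id]
    cols = [c for c, _ in schema]
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise ValueError(f"records lack schema {schema_id!r} columns {missing}")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for _, row in records.iterrows():
            fh.write("\t".join(_format_cell(row[c], fmt) for c, fmt in schema) + "\n")


def read_table(path, schema_id: str) -> pd.DataFrame:
    """Re-read a file written by ``write_table``."""
    if schema_id not in _SCHEMAS:
        raise ValueError(f"unknown output schema {schema_id!r}")
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col, fmt in _SCHEMAS[schema_id]:
        if fmt == "s":
            df[col] = df[col].astype(str)
    return df
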