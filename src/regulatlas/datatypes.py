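"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Coordinates are 1-based inclusive (VCF convention); distances are absolute
  bp differences.
* Dosages live in ``{0, 1, 2, NaN}`` where NaN is the missing-call sentinel.
  Downstream mean-imputation is always explicit, never silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Out-of-band missing-dosage marker.
MISSING = np.nan

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "maf", "missing_rate"]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending location."""


class EmptyResultError(ValueError):
    """A filter or reader retained nothing."""


def validate_variant_table(variants: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing_cols:
        raise ValueError(f"variant table missing columns: {missing_cols}")
    if variants["variant_id"].duplicated().any():
        dup = variants["variant_id"][variants["variant_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate variant_id {dup!r}")
    if (variants["pos"] < 1).any():
        raise ValueError("variant pos must be >= 1 (1-based)")
    if (variants["maf"] > 0.5 + 1e-12).any() or (variants["maf"] < 0).any():
        raise ValueError("maf must lie in [0, 0.5]")
    if ((variants["missing_rate"] < 0) | (variants["missing_rate"] > 1)).any():
        raise ValueError("missing_rate must lie in [0, 1]")
    return variants.reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with per-variant metadata.

    ``dosages[i, j]`` is the alt-allele count of sample ``i`` at variant ``j``
    (0, 1, 2) or NaN for a missing call.
    """

    sample_ids: list[str]
    dosages: np.ndarray  # (n_samples, n_variants) float
    variants: pd.DataFrame  # VARIANT_COLUMNS

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("row count != number of samples")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("column count != number of variants")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = self.dosages[~ok].flat[0]
            raise ValueError(f"dosage {bad!r} outside {{0,1,2,missing}}")
        self.variants = validate_variant_table(self.variants)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_index(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"unknown variant {variant_id!r}")
        return int(idx[0])

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [lookup[s] for s in sample_ids]
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in genotype matrix") from None
        return GenotypeMatrix(list(sample_ids), self.dosages[rows], self.variants.copy())

    def imputed(self) -> np.ndarray:
        """Dosages with missing calls replaced by each variant's mean."""
        d = self.dosages.copy()
        mask = np.isnan(d)
        if mask.any():
            with np.errstate(invalid="ignore"):
                col_mean = np.nanmean(d, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            d[mask] = np.broadcast_to(col_mean, d.shape)[mask]
        return d


@dataclass
class ExpressionMatrix:
    """Samples x genes normalized counts with one tissue label per sample."""

    sample_ids: list[str]
    tissue_labels: np.ndarray  # (n_samples,) str
    gene_ids: list[str]
    counts: np.ndarray  # (n_samples, n_genes) float, >= 0
    #: optional per-tissue kept-gene lists produced by ``filter_genes``
    kept_by_tissue: Optional[dict[str, list[str]]] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.tissue_labels = np.asarray(self.tissue_labels, dtype=object)
        if self.counts.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("counts shape does not match sample/gene ids")
        if len(self.tissue_labels) != len(self.sample_ids):
            raise ValueError("one tissue label per sample required")
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[i]!r}, gene {self.gene_ids[j]!r}"
            )

    @property
    def tissues(self) -> list[str]:
        return sorted(set(self.tissue_labels))

    def tissue_rows(self, tissue: str) -> np.ndarray:
        return np.where(self.tissue_labels == tissue)[0]


@dataclass
class TissueBlock:
    """Standardized log2 expression for the samples of one tissue."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray  # (n_samples_in_tissue, n_kept_genes), mean 0 var 1 per gene
    dropped_zero_variance: list[str] = field(default_factory=list)


@dataclass
class ProcessedExpression:
    """Per-tissue standardized log2(count+1) matrices (see ``log_standardize``)."""

    blocks: dict[str, TissueBlock]

    @property
    def tissues(self) -> list[str]:
        return sorted(self.blocks)

    def __getitem__(self, tissue: str) -> TissueBlock:
        return self.blocks[tissue]


@dataclass
class RelationshipMatrix:
    """Symmetric PSD sample-relationship matrix (IBS, GRM or ORM)."""

    values: np.ndarray
    kind: str  # "IBS" | "GRM" | "ORM"
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix not symmetric")
        if self.kind not in {"IBS", "GRM", "ORM"}:
            raise ValueError(f"unknown relationship kind {self.kind!r}")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: list[str]) -> "RelationshipMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [lookup[s] for s in sample_ids]
        return RelationshipMatrix(
            self.values[np.ix_(rows, rows)], self.kind, list(sample_ids)
        )


@dataclass
class PlantedEQTL:
    gene: str
    tissue: str
    variant: str
    effect: float  # in residual-SD units, on the z-scored dosage
    kind: str  # "cis" | "trans"


@dataclass
class SimTruth:
    """Ground truth recorded by the synthetic-data generators."""

    planted_eqtls: list[PlantedEQTL] = field(default_factory=list)
    specific_genes: list[tuple[str, str, float]] = field(default_factory=list)
    causal_variants: dict[str, float] = field(default_factory=dict)
    causal_genes: dict[str, float] = field(default_factory=dict)
    target_rho2: Optional[float] = None
    latent_loadings: Optional[np.ndarray] = None
    annotation: Optional[pd.DataFrame] = None  # gene_id, chrom, tss, strand
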