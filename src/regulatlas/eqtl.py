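"""Per-gene, per-tissue eQTL mapping, cis/trans classification, LD-based
clustering of eQTLs across tissues, and cross-tissue effect comparison.

Each gene is scanned genome-wide with the EMMAX-style mixed model (latent
factors as fixed covariates, kinship as the random-effect covariance);
genes passing the genome-wide threshold are handed to the stepwise
conditional analysis to enumerate independent signals. Detected eQTLs from
all tissues are grouped into clusters by connected components over pairs
with LD r-squared > 0.2 within 500 kb on the same chromosome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, ProcessedExpression, RelationshipMatrix
from .lmm import MixedModelScanner

CIS_WINDOW = 1_000_000


def classify_cis_trans(
    records: pd.DataFrame, annotation: pd.DataFrame, window: int = CIS_WINDOW
) -> pd.DataFrame:
    """Set kind = cis iff same chromosome and |pos - TSS| <= window, else trans."""
    ann = annotation.set_index("gene_id")
    missing = set(records["gene_id"]) - set(ann.index)
    if missing:
        raise ValueError(f"genes absent from annotation: {sorted(missing)[:5]}")
    records = records.copy()
    tss = ann.loc[records["gene_id"], "tss"].to_numpy()
    gchrom = ann.loc[records["gene_id"], "chrom"].to_numpy()
    same = records["chrom"].to_numpy().astype(str) == gchrom.astype(str)
    close = np.abs(records["pos"].to_numpy() - tss) <= window
    records["kind"] = np.where(same & close, "cis", "trans")
    return records


def ld_r2(G: GenotypeMatrix, variant_a: str, variant_b: str) -> float:
    """Squared Pearson correlation of dosages over jointly called samples."""
    a = G.dosages[:, G.variant_index(variant_a)]
    b = G.dosages[:, G.variant_index(variant_b)]
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("LD undefined for a monomorphic variant")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def map_eqtls(
    processed: ProcessedExpression,
    genotypes: GenotypeMatrix,
    kinship: RelationshipMatrix,
    factors: dict[str, np.ndarray],
    threshold_p: float,
    annotation: pd.DataFrame,
    cis_window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Map independent eQTLs for every gene in every tissue.

    Expression sample ids are ``line:tissue``; genotypes and kinship are
    subset to each tissue's lines. Betas are in SD units of the
    standardized expression, hence comparable across tissues. Returns one
    record per independent signal with its conditional round.
    """
    ann_genes = set(annotation["gene_id"])
    out = []
    for tissue in processed.tissues:
        block = processed[tissue]
        missing = [g for g in block.gene_ids if g not in ann_genes]
        if missing:
            raise ValueError(
                f"cis/trans undecidable: gene {missing[0]!r} absent from annotation"
            )
        lines = [s.split(":")[0] for s in block.sample_ids]
        G = genotypes.subset_samples(lines)
        K = kinship.subset(lines)
        scanner = MixedModelScanner(
            G.dosages, K, predictor_ids=list(G.variants["variant_id"])
        )
        F = factors.get(tissue, np.empty((len(lines), 0)))
        C = np.column_stack([np.ones(len(lines)), F])
        for gi, gene in enumerate(block.gene_ids):
            y = block.values[:, gi]
            res = scanner.scan(y, C)
            if float(res["p"].min()) >= threshold_p:
                continue
            sel = scanner.conditional_scan(y, C, threshold_p, variant_meta=G.variants)
            for _, row in sel.iterrows():
                j = int(row["index"])
                out.append(
                    {
                        "gene_id": gene,
                        "tissue": tissue,
                        "variant_id": row["predictor_id"],
                        "chrom": G.variants["chrom"].iloc[j],
                        "pos": int(G.variants["pos"].iloc[j]),
                        "beta": row["beta"],
                        "se": row["se"],
                        "p": row["p"],
                        "conditional_round": int(row["conditional_round"]),
                    }
                )
    records = pd.DataFrame(
        out,
        columns=[
            "gene_id", "tissue", "variant_id", "chrom", "pos",
            "beta", "se", "p", "conditional_round",
        ],
    )
    if len(records):
        records = classify_cis_trans(records, annotation, window=cis_window)
    else:
        records["kind"] = pd.Series(dtype=str)
    return records


class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_eqtls(
    records: pd.DataFrame,
    G: GenotypeMatrix,
    r2_min: float = 0.2,
    max_dist: int = 500_000,
) -> pd.DataFrame:
    """Group eQTLs across tissues into clusters by LD and distance.

    Union-find over the unique top variants: an edge joins two variants iff
    they share a chromosome, their distance is strictly below ``max_dist``
    and dosage r-squared is strictly above ``r2_min``. The representative
    of a cluster is the member record with the smallest p (ties by position
    then variant id). Returns the records with ``cluster_id``,
    ``is_representative`` and the representative's variant annotated.
    """
    if len(records) == 0:
        raise ValueError("no eQTL records to cluster")
    uniq = (
        records[["variant_id", "chrom", "pos"]]
        .drop_duplicates(subset="variant_id")
        .sort_values(["chrom", "pos", "variant_id"])
        .reset_index(drop=True)
    )
    vidx = {v: i for i, v in enumerate(uniq["variant_id"])}
    dsu = _DSU(len(uniq))
    dos = G.imputed()
    gcol = {v: G.variant_index(v) for v in uniq["variant_id"]}
    for chrom, grp in uniq.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if pos[b] - pos[a] >= max_dist:
                    break
                xa = dos[:, gcol[grp["variant_id"].iloc[a]]]
                xb = dos[:, gcol[grp["variant_id"].iloc[b]]]
                if xa.std() == 0 or xb.std() == 0:
                    continue
                r = np.corrcoef(xa, xb)[0, 1]
                if r * r > r2_min:
                    dsu.union(idx[a], idx[b])
    comp = {i: dsu.find(i) for i in range(len(uniq))}
    roots = sorted(set(comp.values()))
    cluster_of_variant = {
        uniq["variant_id"].iloc[i]: f"c{roots.index(comp[i]):04d}" for i in range(len(uniq))
    }
    out = records.copy()
    out["cluster_id"] = out["variant_id"].map(cluster_of_variant)
    out = out.sort_values(
        ["cluster_id", "p", "pos", "variant_id"], kind="stable"
    ).reset_index(drop=True)
    out["is_representative"] = False
    rep_rows = out.groupby("cluster_id", sort=True).head(1).index
    out.loc[rep_rows, "is_representative"] = True
    return out


def cluster_representatives(clustered: pd.DataFrame) -> pd.DataFrame:
    """One row per cluster: the smallest-p member (ties by position, id)."""
    return (
        clustered[clustered["is_representative"]]
        .drop_duplicates(subset="cluster_id")
        .reset_index(drop=True)
    )


def cross_tissue_effects(clustered: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Paired effect sizes for eQTLs detected in two tissues.

    eQTLs are matched by (gene, cluster); for every tissue pair sharing a
    match the two betas are tabulated. Summary: Pearson correlation of the
    paired betas and the fraction with opposite signs; both are NaN flags
    when no pairs exist.
    """
    pairs = []
    for (gene, cluster), grp in clustered.groupby(["gene_id", "cluster_id"]):
        by_tissue = grp.sort_values("p").drop_duplicates(subset="tissue")
        tissues = by_tissue["tissue"].tolist()
        for i in range(len(tissues)):
            for j in range(i + 1, len(tissues)):
                b1 = float(by_tissue["beta"].iloc[i])
                b2 = float(by_tissue["beta"].iloc[j])
                pairs.append(
                    {
                        "gene_id": gene,
                        "cluster_id": cluster,
                        "tissue_1": tissues[i],
                        "tissue_2": tissues[j],
                        "beta_1": b1,
                        "beta_2": b2,
                    }
                )
    table = pd.DataFrame(
        pairs, columns=["gene_id", "cluster_id", "tissue_1", "tissue_2", "beta_1", "beta_2"]
    )
    if len(table) == 0:
        return table, {"pearson_r": np.nan, "sign_discordance": np.nan, "n_pairs": 0}
    r = (
        float(np.corrcoef(table["beta_1"], table["beta_2"])[0, 1])
        if len(table) > 1
        else np.nan
    )
    disc = float((table["beta_1"] * table["beta_2"] < 0).mean())
    return table, {"pearson_r": r, "sign_discordance": disc, "n_pairs": len(table)}
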