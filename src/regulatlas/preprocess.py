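"""Expression QC, latent-factor covariates, relatedness matrices and BLUPs.

These are the stages feeding every model: per-tissue gene filtering
(expressed in strictly more than half the tissue's samples), log2(count+1)
z-scoring, truncated-SVD latent factors standing in for Bayesian
expression-residual covariates, IBS/GRM kinship, PCA of a relationship
matrix, and REML line BLUPs from replicated multi-environment phenotypes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GenotypeMatrix,
    ProcessedExpression,
    RelationshipMatrix,
    TissueBlock,
)
from .lmm import reml_fit, spectral_decomposition


def filter_genes(expr: ExpressionMatrix, min_expressed_fraction: float = 0.5) -> ExpressionMatrix:
    """Keep, per tissue, genes expressed (count > 0) in strictly more than
    ``min_expressed_fraction`` of that tissue's samples.

    The returned matrix restricts columns to the union of per-tissue kept
    genes and records the per-tissue lists in ``kept_by_tissue``.
    """
    if not (0 < min_expressed_fraction <= 1):
        raise ValueError("min_expressed_fraction must lie in (0, 1]")
    kept_by_tissue: dict[str, list[str]] = {}
    union: set[str] = set()
    for t in expr.tissues:
        rows = expr.tissue_rows(t)
        if len(rows) == 0:
            raise ValueError(f"tissue {t!r} has no samples")
        frac = (expr.counts[rows] > 0).mean(axis=0)
        kept = [g for g, f in zip(expr.gene_ids, frac) if f > min_expressed_fraction]
        kept_by_tissue[t] = kept
        union.update(kept)
    keep_cols = [j for j, g in enumerate(expr.gene_ids) if g in union]
    return ExpressionMatrix(
        sample_ids=list(expr.sample_ids),
        tissue_labels=expr.tissue_labels.copy(),
        gene_ids=[expr.gene_ids[j] for j in keep_cols],
        counts=expr.counts[:, keep_cols],
        kept_by_tissue=kept_by_tissue,
    )


def log_standardize(expr: ExpressionMatrix) -> ProcessedExpression:
    """Per tissue: log2(count + 1), then z-score each gene column.

    Zero-variance genes within a tissue are flagged and excluded from that
    tissue's standardized block. When ``expr`` carries per-tissue kept-gene
    lists (from :func:`filter_genes`) each tissue uses its own list.
    """
    blocks: dict[str, TissueBlock] = {}
    gene_index = {g: j for j, g in enumerate(expr.gene_ids)}
    for t in expr.tissues:
        rows = expr.tissue_rows(t)
        genes = (
            expr.kept_by_tissue.get(t, expr.gene_ids)
            if expr.kept_by_tissue is not None
            else expr.gene_ids
        )
        cols = [gene_index[g] for g in genes]
        logx = np.log2(expr.counts[np.ix_(rows, cols)] + 1.0)
        sd = logx.std(axis=0, ddof=0)
        ok = sd > 0
        dropped = [g for g, keep in zip(genes, ok) if not keep]
        z = (logx[:, ok] - logx[:, ok].mean(axis=0)) / sd[ok]
        blocks[t] = TissueBlock(
            sample_ids=[expr.sample_ids[i] for i in rows],
            gene_ids=[g for g, keep in zip(genes, ok) if keep],
            values=z,
            dropped_zero_variance=dropped,
        )
    return ProcessedExpression(blocks=blocks)


def estimate_latent_factors(processed: ProcessedExpression, k: int = 25) -> dict[str, np.ndarray]:
    """Per-tissue latent covariates: first k left singular vectors, unit variance.

    A deterministic surrogate for Bayesian expression-residual factors used
    purely as nuisance covariates in the eQTL scans.
    """
    out: dict[str, np.ndarray] = {}
    for t, block in processed.blocks.items():
        n = block.values.shape[0]
        if k >= n:
            raise ValueError(f"k={k} must be smaller than {n} samples in tissue {t!r}")
        if k == 0:
            out[t] = np.empty((n, 0))
            continue
        U, s, _ = np.linalg.svd(block.values, full_matrices=False)
        F = U[:, :k]
        F = (F - F.mean(axis=0)) / F.std(axis=0, ddof=0)
        out[t] = F
    return out


def compute_kinship(G: GenotypeMatrix, kind: str = "GRM") -> RelationshipMatrix:
    """Genome-wide relatedness: IBS allele sharing or the centered-scaled GRM.

    IBS[i,j] = mean over variants of (2 - |d_i - d_j|) / 2, pairs with a
    missing call excluded per variant. GRM = Z Z' / m over columns
    standardized by 2p and sqrt(2p(1-p)) with mean-imputed missing calls;
    monomorphic variants are skipped with a warning.
    """
    if G.n_samples < 2 or G.n_variants < 1:
        raise ValueError("need at least 2 samples and 1 variant")
    D = G.dosages
    if kind.upper() == "IBS":
        obs = ~np.isnan(D)
        Dz = np.where(obs, D, 0.0)
        # sum_v |d_i - d_j| via dosage-category indicators
        sim = np.zeros((G.n_samples, G.n_samples))
        ind = [np.where(obs & (Dz == k_), 1.0, 0.0) for k_ in (0.0, 1.0, 2.0)]
        for a in range(3):
            for b in range(3):
                wgt = (2.0 - abs(a - b)) / 2.0
                if wgt:
                    sim += wgt * (ind[a] @ ind[b].T)
        pairs = obs.astype(float) @ obs.astype(float).T
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(pairs > 0, sim / pairs, 0.0)
        vals = (vals + vals.T) / 2.0
        return RelationshipMatrix(vals, "IBS", list(G.sample_ids))
    if kind.upper() == "GRM":
        X = G.imputed()
        p = X.mean(axis=0) / 2.0
        ok = (p > 0) & (p < 1)
        if not ok.all():
            warnings.warn(f"GRM: skipped {int((~ok).sum())} monomorphic variants")
        X = X[:, ok]
        p = p[ok]
        Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
        vals = Z @ Z.T / Z.shape[1]
        vals = (vals + vals.T) / 2.0
        return RelationshipMatrix(vals, "GRM", list(G.sample_ids))
    raise ValueError(f"unknown kinship kind {kind!r}")


def pca(R: RelationshipMatrix, n_pc: int) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates of a relationship matrix.

    The matrix is double-centered, eigendecomposed, and the top ``n_pc``
    scores (eigenvector x sqrt(eigenvalue)) returned together with the
    variance-explained fractions (eigenvalue / trace of the centered
    matrix), in descending order.
    """
    n = R.n
    if n_pc > n:
        raise ValueError("n_pc cannot exceed the number of samples")
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ R.values @ J
    lam, U = np.linalg.eigh(B)
    order = np.argsort(lam)[::-1]
    lam, U = np.clip(lam[order], 0.0, None), U[:, order]
    tr = lam.sum()
    frac = lam / tr if tr > 0 else np.zeros_like(lam)
    scores = U[:, :n_pc] * np.sqrt(lam[:n_pc])
    return scores, frac[:n_pc]


def compute_blups(phenotypes: pd.DataFrame) -> pd.Series:
    """Line BLUPs from replicated phenotypes (line random, env fixed, REML).

    ``phenotypes`` has columns line, env, value. Fits
    y = mu + env + line + e with the line effect random, via the REML core
    with R = Z Z' (Z the line-incidence matrix), then returns the BLUP
    deviation per line.
    """
    for col in ("line", "env", "value"):
        if col not in phenotypes.columns:
            raise ValueError(f"phenotypes lack column {col!r}")
    lines = sorted(phenotypes["line"].unique())
    envs = sorted(phenotypes["env"].unique())
    if len(lines) < 2:
        raise ValueError("need at least 2 lines")
    counts = phenotypes.groupby("line").size()
    if (counts <= 1).all():
        raise ValueError("one observation per line: line variance not estimable")
    li = {l: i for i, l in enumerate(lines)}
    ei = {e: i for i, e in enumerate(envs)}
    y = phenotypes["value"].to_numpy(dtype=float)
    nobs = len(y)
    Z = np.zeros((nobs, len(lines)))
    Z[np.arange(nobs), [li[l] for l in phenotypes["line"]]] = 1.0
    C = np.ones((nobs, 1))
    if len(envs) > 1:  # env fixed effects, first env as reference
        E = np.zeros((nobs, len(envs) - 1))
        for r, e in enumerate(phenotypes["env"]):
            if ei[e] > 0:
                E[r, ei[e] - 1] = 1.0
        C = np.column_stack([C, E])
    R = Z @ Z.T
    vc = reml_fit(y, C, R)
    if not vc.converged:
        raise ValueError("line variance not estimable (flat likelihood)")
    V = vc.sigma_u2 * R + vc.sigma_e2 * np.eye(nobs)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(C.T @ Vi @ C, C.T @ Vi @ y)
    u = vc.sigma_u2 * Z.T @ Vi @ (y - C @ beta)
    return pd.Series(u, index=lines, name="blup")
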