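"""Linking regulatory variation to traits.

Transcriptome variance partitioning (REML with an omics relationship
matrix), mixed-model TWAS, distance colocalization of trait QTLs with eQTL
clusters, summary-based Mendelian randomization with the HEIDI
heterogeneity test, enrichment-style comparisons against random gene/SNP
sets, and replication of gene-trait correlations in an independent panel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, RelationshipMatrix, TissueBlock
from .lmm import MixedModelScanner, VarianceComponents, reml_fit
from .preprocess import compute_kinship


# ---------------------------------------------------------------------------
# PVE via the omics relationship matrix
# ---------------------------------------------------------------------------

def compute_orm(block: TissueBlock) -> RelationshipMatrix:
    """Omics relationship matrix A = Z Z' / g over standardized gene columns."""
    g = block.values.shape[1]
    if g == 0:
        raise ValueError("no genes in block")
    A = block.values @ block.values.T / g
    A = (A + A.T) / 2.0
    return RelationshipMatrix(A, "ORM", list(block.sample_ids))


def transcriptome_pve(
    trait: pd.Series, orm: RelationshipMatrix
) -> VarianceComponents:
    """PVE by transcriptome variation: intraclass correlation from REML.

    ``trait`` is indexed by line; the ORM samples are matched by the line
    part of their ids. Delegates to the REML core with R = A.
    """
    lines = [s.split(":")[0] for s in orm.sample_ids]
    y = trait.loc[lines].to_numpy(dtype=float)
    C = np.ones((len(y), 1))
    return reml_fit(y, C, orm)


# ---------------------------------------------------------------------------
# TWAS
# ---------------------------------------------------------------------------

def twas_scan(
    trait: pd.Series, block: TissueBlock, orm: RelationshipMatrix
) -> tuple[pd.DataFrame, dict]:
    """Mixed-model TWAS: per-gene fixed effect with ORM random background.

    Variance components are fit once under the null (EMMAX-style) and every
    standardized gene column is tested by GLS. Returns the records plus the
    Bonferroni thresholds: strict 0.05/#genes and lenient 0.05/#associated
    (the realized count of genes passing the strict threshold; NaN when
    none pass).
    """
    lines = [s.split(":")[0] for s in block.sample_ids]
    y = trait.loc[lines].to_numpy(dtype=float)
    scanner = MixedModelScanner(block.values, orm, predictor_ids=block.gene_ids)
    C = np.ones((len(y), 1))
    res = scanner.scan(y, C)
    res = res.rename(columns={"predictor_id": "gene_id"})
    n_genes = int((~res["flagged"]).sum())
    strict = 0.05 / n_genes if n_genes else np.nan
    n_assoc = int((res.loc[~res["flagged"], "p"] < strict).sum()) if n_genes else 0
    lenient = 0.05 / n_assoc if n_assoc else np.nan
    thresholds = {
        "strict": strict,
        "lenient": lenient,
        "n_genes": n_genes,
        "n_associated": n_assoc,
    }
    return res, thresholds


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------

def colocalize(
    qtl_catalog: pd.DataFrame,
    cluster_reps: pd.DataFrame,
    max_dist: int = 100,
) -> pd.DataFrame:
    """Pair trait QTLs with eQTL clusters whose representative variant lies
    strictly within ``max_dist`` bp on the same chromosome."""
    out = []
    for _, qtl in qtl_catalog.iterrows():
        same = cluster_reps[cluster_reps["chrom"].astype(str) == str(qtl["chrom"])]
        if len(same) == 0:
            continue
        dist = np.abs(same["pos"].to_numpy() - int(qtl["pos"]))
        for k in np.where(dist < max_dist)[0]:
            rep = same.iloc[k]
            out.append(
                {
                    "trait": qtl["trait"],
                    "qtl_chrom": str(qtl["chrom"]),
                    "qtl_pos": int(qtl["pos"]),
                    "cluster_id": rep["cluster_id"],
                    "variant_id": rep["variant_id"],
                    "pos": int(rep["pos"]),
                    "distance": int(dist[k]),
                    "gene_id": rep["gene_id"],
                }
            )
    return pd.DataFrame(
        out,
        columns=[
            "trait", "qtl_chrom", "qtl_pos", "cluster_id", "variant_id",
            "pos", "distance", "gene_id",
        ],
    ).sort_values(["trait", "qtl_chrom", "qtl_pos", "cluster_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# SMR / HEIDI
# ---------------------------------------------------------------------------

def ols_summary_stats(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column marginal OLS effect and SE (summary statistics for SMR).

    Each predictor column is regressed on its own with an intercept;
    residual variance uses n-2 degrees of freedom.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx2 = (Xc**2).sum(axis=0)
    if (sx2 == 0).any():
        raise ValueError("monomorphic predictor column")
    beta = Xc.T @ yc / sx2
    rss = (yc**2).sum() - 2 * beta * (Xc.T @ yc) + beta**2 * sx2
    se = np.sqrt(rss / (n - 2) / sx2)
    return beta, se


def smr_test(b_gwas: float, se_gwas: float, b_eqtl: float, se_eqtl: float):
    """Summary-based Mendelian randomization at the top eQTL instrument.

    b_xy = b_GWAS / b_eQTL; the test statistic is
    T = z_gwas^2 z_eqtl^2 / (z_gwas^2 + z_eqtl^2), chi-square(1) under the
    null of no mediated effect; se_xy by the delta method.
    """
    if b_eqtl == 0 or se_eqtl <= 0 or se_gwas <= 0:
        raise ValueError("eQTL instrument effect/SE must be nonzero")
    z_g = b_gwas / se_gwas
    z_e = b_eqtl / se_eqtl
    if z_e == 0:
        raise ValueError("z_eqtl = 0: undefined SMR statistic")
    t_smr = (z_g**2 * z_e**2) / (z_g**2 + z_e**2)
    # keep p in (0, 1]: the chi-square tail underflows around T ~ 1500
    p_smr = max(float(stats.chi2.sf(t_smr, df=1)), 5e-324)
    b_xy = b_gwas / b_eqtl
    var_xy = (se_gwas**2 / b_eqtl**2) + (b_gwas**2 * se_eqtl**2 / b_eqtl**4)
    return b_xy, float(np.sqrt(var_xy)), p_smr


def _bxy_covariance(
    b_g: np.ndarray, se_g: np.ndarray, b_e: np.ndarray, se_e: np.ndarray, ld_r: np.ndarray
) -> np.ndarray:
    """Delta-method covariance of the per-SNP b_xy estimates.

    GWAS and eQTL samples are treated as independent, so effect-estimate
    covariances within each study are r_ij * se_i * se_j and cross-study
    terms vanish.
    """
    inv_be = 1.0 / b_e
    cov_g = ld_r * np.outer(se_g, se_g)
    cov_e = ld_r * np.outer(se_e, se_e)
    term1 = np.outer(inv_be, inv_be) * cov_g
    term2 = np.outer(b_g * inv_be**2, b_g * inv_be**2) * cov_e
    return term1 + term2


def heidi_test(
    b_gwas: np.ndarray,
    se_gwas: np.ndarray,
    b_eqtl: np.ndarray,
    se_eqtl: np.ndarray,
    ld_r: np.ndarray,
    top: int,
    p_eqtl_max: float = 1.6e-3,
    r2_window: tuple[float, float] = (0.05, 0.9),
    max_snps: int = 20,
):
    """HEIDI heterogeneity test around the top eQTL instrument.

    Eligible SNPs have eQTL p below ``p_eqtl_max`` and r-squared with the
    top SNP inside ``r2_window``; the ``max_snps`` most significant are
    kept. For each, d_i = b_xy(i) - b_xy(top); the covariance of d follows
    from the delta-method covariance of the b_xy estimates and the LD
    matrix. T = sum z_d^2 is referred to a weighted chi-square via
    Satterthwaite moment matching on the eigenvalues of the correlation of
    z_d. Returns (p_heidi, n_snps); p is None with fewer than 3 eligible
    SNPs.
    """
    b_gwas = np.asarray(b_gwas, float)
    se_gwas = np.asarray(se_gwas, float)
    b_eqtl = np.asarray(b_eqtl, float)
    se_eqtl = np.asarray(se_eqtl, float)
    ld_r = np.asarray(ld_r, float)
    m = len(b_gwas)
    z_e = b_eqtl / se_eqtl
    p_e = 2.0 * stats.norm.sf(np.abs(z_e))
    r2_top = ld_r[top] ** 2
    lo, hi = r2_window
    eligible = np.where(
        (np.arange(m) != top) & (p_e < p_eqtl_max) & (r2_top >= lo) & (r2_top <= hi)
    )[0]
    if len(eligible) > max_snps:
        eligible = eligible[np.argsort(p_e[eligible])[:max_snps]]
    n_snps = len(eligible)
    if n_snps < 3:
        return None, n_snps

    idx = np.concatenate([[top], eligible])
    cov_bxy = _bxy_covariance(
        b_gwas[idx], se_gwas[idx], b_eqtl[idx], se_eqtl[idx], ld_r[np.ix_(idx, idx)]
    )
    bxy = b_gwas[idx] / b_eqtl[idx]
    d = bxy[1:] - bxy[0]
    k = len(d)
    cov_d = (
        cov_bxy[1:, 1:]
        - cov_bxy[1:, [0]]
        - cov_bxy[[0], 1:]
        + cov_bxy[0, 0]
    )
    sd_d = np.sqrt(np.clip(np.diag(cov_d), 1e-300, None))
    z_d = d / sd_d
    corr_d = cov_d / np.outer(sd_d, sd_d)
    t_heidi = float(np.sum(z_d**2))
    lam = np.clip(np.linalg.eigvalsh(corr_d), 0.0, None)
    s1, s2 = lam.sum(), float(np.sum(lam**2))
    if s1 <= 0 or s2 <= 0:
        return 1.0, n_snps
    scale = s2 / s1
    df = s1**2 / s2
    p = max(float(stats.chi2.sf(t_heidi / scale, df=df)), 5e-324)
    return p, n_snps


# ---------------------------------------------------------------------------
# comparisons against random draws
# ---------------------------------------------------------------------------

def compare_coloc_vs_random(
    twas_records: pd.DataFrame,
    coloc_genes: list[str],
    n_draws: int = 1000,
    seed: int = 0,
) -> dict:
    """Are TWAS p-values of colocalized eGenes smaller than random genes'?

    Two-sided rank-sum (Mann-Whitney) comparison of -log10 p between the
    colocalized set and the remaining tested genes; the empirical p
    recomputes the statistic on size-matched random draws.
    """
    tested = twas_records.loc[~twas_records["flagged"]] if "flagged" in twas_records else twas_records
    genes = tested["gene_id"].tolist()
    neglog = -np.log10(np.clip(tested["p"].to_numpy(dtype=float), 1e-300, 1.0))
    coloc = [g for g in set(coloc_genes)]
    if not coloc:
        raise ValueError("empty colocalized gene set")
    if not set(coloc) <= set(genes):
        raise ValueError("colocalized set must be within TWAS-tested genes")
    is_coloc = np.isin(genes, coloc)
    x = neglog[is_coloc]
    rest = neglog[~is_coloc]
    u_obs, p_asym = stats.mannwhitneyu(x, rest, alternative="two-sided")
    result = {"u": float(u_obs), "p_asymptotic": float(p_asym), "p_empirical": np.nan}
    if n_draws > 0:
        rng = np.random.default_rng(seed)
        mu = len(x) * len(rest) / 2.0
        hits = 0
        for _ in range(n_draws):
            draw = rng.choice(len(genes), size=len(x), replace=False)
            mask = np.zeros(len(genes), dtype=bool)
            mask[draw] = True
            u, _ = stats.mannwhitneyu(
                neglog[mask], neglog[~mask], alternative="two-sided"
            )
            if abs(u - mu) >= abs(u_obs - mu):
                hits += 1
        result["p_empirical"] = (hits + 1) / (n_draws + 1)
    return result


def pve_snpset_vs_random(
    trait: pd.Series,
    genotypes: GenotypeMatrix,
    snp_set: list[str],
    n_draws: int = 100,
    seed: int = 0,
) -> dict:
    """PVE of a SNP set versus size-matched random variant sets.

    The set's PVE comes from REML on a GRM built from only those variants;
    the empirical p is the fraction of random sets whose PVE is at least
    the observed one.
    """
    if len(snp_set) < 2:
        raise ValueError("snp_set needs at least 2 variants")
    lines = list(trait.index)
    G = genotypes.subset_samples(lines)
    y = trait.to_numpy(dtype=float)
    C = np.ones((len(y), 1))

    def pve_of(cols: list[int]) -> float:
        sub = GenotypeMatrix(
            G.sample_ids, G.dosages[:, cols], G.variants.iloc[cols].reset_index(drop=True)
        )
        K = compute_kinship(sub, "GRM")
        vc = reml_fit(y, C, K)
        return vc.rho2 if vc.converged else np.nan

    cols = [G.variant_index(v) for v in snp_set]
    pve_obs = pve_of(cols)
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_draws):
        rnd = rng.choice(G.n_variants, size=len(cols), replace=False)
        draws.append(pve_of(list(rnd)))
    draws = np.asarray(draws, dtype=float)
    ok = np.isfinite(draws)
    p_emp = float(np.mean(draws[ok] >= pve_obs)) if ok.any() else np.nan
    return {"pve_set": pve_obs, "pve_random": draws, "p_empirical": p_emp}


def replication_correlation(
    expression: pd.DataFrame,
    traits: pd.DataFrame,
    pairs: list[tuple],
) -> tuple[pd.DataFrame, dict]:
    """Replicate gene-trait associations in an independent panel.

    ``expression`` is lines x genes, ``traits`` lines x traits; ``pairs``
    are (gene, trait) or (gene, trait, expected_sign). Pearson r and its
    two-sided p are computed on complete observations (pairs with fewer
    than 3 are skipped with a flag). Summary: fraction with p < 0.05 and,
    separately, the sign-agreement fraction where an expected sign was
    given.
    """
    lines = expression.index.intersection(traits.index)
    rows = []
    for pair in pairs:
        gene, trait = pair[0], pair[1]
        expected = pair[2] if len(pair) > 2 else None
        if gene not in expression.columns or trait not in traits.columns:
            rows.append({"gene_id": gene, "trait": trait, "r": np.nan, "p": np.nan,
                         "skipped": True, "sign_agrees": np.nan})
            continue
        x = expression.loc[lines, gene].to_numpy(dtype=float)
        y = traits.loc[lines, trait].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
            rows.append({"gene_id": gene, "trait": trait, "r": np.nan, "p": np.nan,
                         "skipped": True, "sign_agrees": np.nan})
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        agrees = np.nan if expected is None else float(np.sign(r) == np.sign(expected))
        rows.append({"gene_id": gene, "trait": trait, "r": float(r), "p": float(p),
                     "skipped": False, "sign_agrees": agrees})
    table = pd.DataFrame(rows)
    done = table[~table["skipped"]]
    summary = {
        "replicated_fraction": float((done["p"] < 0.05).mean()) if len(done) else np.nan,
        "sign_agreement": (
            float(done["sign_agrees"].dropna().mean())
            if done["sign_agrees"].notna().any()
            else np.nan
        ),
        "n_tested": int(len(done)),
        "n_skipped": int(table["skipped"].sum()),
    }
    return table, summary
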