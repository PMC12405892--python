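"""Synthetic genotypes, multi-tissue expression and traits with recorded truth.

The generators emulate the statistical structure of a population-scale
multi-tissue transcriptome study: LD-blocked biallelic genotypes with
subpopulation structure, log-normal counts with planted cis/trans regulatory
variants, tissue-specific genes and shared latent factors, and traits with a
mixed genetic + transcriptomic architecture. Every planted feature is
recorded in a :class:`~regulatlas.datatypes.SimTruth` so downstream stages
can be scored against ground truth.

One seed governs a whole scenario; per-component sub-streams are derived
deterministically from it via ``numpy`` seed sequences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GenotypeMatrix, PlantedEQTL, SimTruth


def _rng(seed, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def simulate_genotypes(
    n_samples: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    block_size: int = 50,
    switch_prob: float = 0.1,
    n_subpops: int = 1,
    fst: float = 0.1,
    spacing: int = 2000,
    chrom: str = "1",
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Generate LD-blocked biallelic dosages with population structure.

    Two haplotypes per sample are built by a copying process: within an LD
    block each variant copies the previous variant's allele on the same
    haplotype with probability ``1 - switch_prob`` and otherwise draws a
    fresh allele from the variant's (subpopulation-specific) frequency.
    ``switch_prob=0`` gives perfect LD within a block; ``switch_prob=1``
    gives independent variants. Subpopulation frequencies follow a
    Balding-Nichols model with divergence ``fst``.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if n_subpops > n_samples:
        raise ValueError("n_subpops cannot exceed n_samples")
    rng = _rng(seed, 0)
    p = rng.uniform(lo, hi, size=n_variants)
    if n_subpops > 1 and fst > 0:
        a = p * (1 - fst) / fst
        b = (1 - p) * (1 - fst) / fst
        p_sub = rng.beta(a, b, size=(n_subpops, n_variants))
        p_sub = np.clip(p_sub, 1e-3, 1 - 1e-3)
    else:
        p_sub = np.broadcast_to(p, (max(n_subpops, 1), n_variants))
    subpop = np.repeat(np.arange(max(n_subpops, 1)), -(-n_samples // max(n_subpops, 1)))[
        :n_samples
    ]

    haps = np.empty((2 * n_samples, n_variants), dtype=np.int8)
    freq_rows = p_sub[np.repeat(subpop, 2)]  # (2n, m)
    fresh = (rng.random((2 * n_samples, n_variants)) < freq_rows).astype(np.int8)
    copy = rng.random((2 * n_samples, n_variants)) < (1.0 - switch_prob)
    haps[:, 0] = fresh[:, 0]
    for v in range(1, n_variants):
        if v % block_size == 0:  # block boundary: always draw fresh
            haps[:, v] = fresh[:, v]
        else:
            haps[:, v] = np.where(copy[:, v], haps[:, v - 1], fresh[:, v])
    dosages = (haps[0::2] + haps[1::2]).astype(float)

    if missing_rate > 0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages[mask] = np.nan

    gaps = rng.integers(max(1, spacing // 2), spacing + spacing // 2, size=n_variants)
    pos = np.cumsum(gaps)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=0) / 2.0
    freq = np.where(np.isnan(freq), 0.0, freq)
    maf = np.minimum(freq, 1 - freq)
    miss = np.isnan(dosages).mean(axis=0)
    variants = pd.DataFrame(
        {
            "variant_id": [f"snp{v}" for v in range(n_variants)],
            "chrom": chrom,
            "pos": pos.astype(int),
            "ref": "A",
            "alt": "T",
            "maf": maf,
            "missing_rate": miss,
        }
    )
    sample_ids = [f"L{i:04d}" for i in range(n_samples)]
    return GenotypeMatrix(sample_ids, dosages, variants)


def _zscore_dosage(d: np.ndarray) -> np.ndarray:
    mu, sd = d.mean(), d.std()
    if sd == 0:
        raise ValueError("monomorphic variant cannot carry a planted effect")
    return (d - mu) / sd


def simulate_expression(
    genotypes: GenotypeMatrix,
    tissues: tuple[str, ...] = ("RT", "SH", "LB"),
    n_genes: int = 1000,
    cis_fraction: float = 0.3,
    effect_size: float = 1.0,
    trans_fraction: float = 0.0,
    discordant_fraction: float = 0.0,
    n_specific_per_tissue: int = 10,
    specific_fold: float = 8.0,
    n_factors: int = 5,
    factor_sd: float = 0.5,
    noise_sd: float = 1.0,
    base_mean: float = 5.0,
    base_sd: float = 1.5,
    cis_window: int = 1_000_000,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Generate multi-tissue log-normal counts with planted regulatory truth.

    Per tissue, log2-expression = gene baseline + planted eQTL effects on the
    z-scored dosage (in units of ``noise_sd``) + shared latent factors +
    Gaussian noise; counts = round(2^log2x) floored at 0. A ``cis_fraction``
    of genes receives one cis eQTL (variant within ``cis_window`` of the
    gene's TSS) shared across tissues; ``discordant_fraction`` of those flip
    sign in one tissue. Tissue-specific genes are multiplied by
    ``specific_fold`` in their tissue.
    """
    if len(tissues) < 2:
        raise ValueError("at least 2 tissues required")
    if genotypes.n_variants == 0 or genotypes.n_samples == 0:
        raise ValueError("genotypes must be non-empty")
    rng = _rng(seed, 1)
    n_lines = genotypes.n_samples
    m = genotypes.n_variants
    pos = genotypes.variants["pos"].to_numpy()
    chrom = genotypes.variants["chrom"].to_numpy()
    genome_chroms = pd.unique(chrom)

    gene_ids = [f"gene{g:04d}" for g in range(n_genes)]
    # TSS near a randomly chosen variant so cis windows are never empty
    anchor = rng.integers(0, m, size=n_genes)
    tss = np.maximum(1, pos[anchor] + rng.integers(-50_000, 50_000, size=n_genes))
    ann = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": chrom[anchor],
            "tss": tss.astype(int),
            "strand": rng.choice(["+", "-"], size=n_genes),
        }
    )

    truth = SimTruth(annotation=ann)
    dos = genotypes.imputed()

    n_cis = int(round(cis_fraction * n_genes))
    n_trans = int(round(trans_fraction * n_genes))
    carrier = rng.permutation(n_genes)
    cis_genes = carrier[:n_cis]
    trans_genes = carrier[n_cis : n_cis + n_trans]

    # per-gene planted effect matrices, built lazily as (gene -> list of (z, beta per tissue))
    planted: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}

    def plant(g: int, v: int, kind: str) -> None:
        sign = rng.choice([-1.0, 1.0])
        beta = np.full(len(tissues), sign * effect_size)
        if discordant_fraction > 0 and rng.random() < discordant_fraction:
            beta[rng.integers(0, len(tissues))] *= -1.0
        z = _zscore_dosage(dos[:, v])
        planted.setdefault(g, []).append((z, beta))
        for ti, t in enumerate(tissues):
            truth.planted_eqtls.append(
                PlantedEQTL(gene_ids[g], t, genotypes.variants["variant_id"].iloc[v], beta[ti], kind)
            )

    for g in cis_genes:
        window = np.where(
            (chrom == ann["chrom"].iloc[g]) & (np.abs(pos - ann["tss"].iloc[g]) <= cis_window)
        )[0]
        window = window[dos[:, window].std(axis=0) > 0]
        if len(window) == 0:
            raise ValueError(f"no polymorphic cis variant within window of {gene_ids[g]}")
        plant(g, int(rng.choice(window)), "cis")
    for g in trans_genes:
        far = np.where(
            (chrom != ann["chrom"].iloc[g]) | (np.abs(pos - ann["tss"].iloc[g]) > cis_window)
        )[0]
        far = far[dos[:, far].std(axis=0) > 0]
        if len(far) == 0:
            raise ValueError(f"no polymorphic trans variant available for {gene_ids[g]}")
        plant(g, int(rng.choice(far)), "trans")

    # tissue-specific genes: disjoint across tissues, disjoint from eQTL carriers
    free = [g for g in carrier[n_cis + n_trans :]]
    spec_assign: dict[int, int] = {}
    needed = n_specific_per_tissue * len(tissues)
    if needed > len(free):
        raise ValueError("not enough genes left for tissue-specific assignment")
    for ti in range(len(tissues)):
        for g in free[ti * n_specific_per_tissue : (ti + 1) * n_specific_per_tissue]:
            spec_assign[g] = ti
            truth.specific_genes.append((gene_ids[g], tissues[ti], specific_fold))

    baseline = rng.normal(base_mean, base_sd, size=n_genes)
    loadings = rng.normal(0.0, factor_sd, size=(n_genes, n_factors)) if n_factors else None
    truth.latent_loadings = loadings

    sample_ids: list[str] = []
    tissue_labels: list[str] = []
    counts = np.empty((n_lines * len(tissues), n_genes))
    for ti, t in enumerate(tissues):
        logx = np.tile(baseline, (n_lines, 1))
        for g, entries in planted.items():
            for z, beta in entries:
                logx[:, g] += beta[ti] * noise_sd * z
        if n_factors:
            factors = _rng(seed, 2, ti).standard_normal((n_lines, n_factors))
            logx += factors @ loadings.T
        logx += _rng(seed, 3, ti).normal(0.0, noise_sd, size=(n_lines, n_genes))
        for g, gi in spec_assign.items():
            if gi == ti:
                logx[:, g] += np.log2(specific_fold)
        counts[ti * n_lines : (ti + 1) * n_lines] = np.maximum(
            np.rint(np.exp2(logx)), 0.0
        )
        sample_ids.extend(f"{line}:{t}" for line in genotypes.sample_ids)
        tissue_labels.extend([t] * n_lines)

    expr = ExpressionMatrix(
        sample_ids=sample_ids,
        tissue_labels=np.asarray(tissue_labels, dtype=object),
        gene_ids=gene_ids,
        counts=counts,
    )
    return expr, truth


def simulate_trait(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    n_causal_variants: int = 0,
    n_causal_genes: int = 100,
    target_rho2: float = 0.5,
    genetic_share: float = 0.2,
    tissue: str | None = None,
    seed: int = 0,
) -> tuple[pd.Series, SimTruth]:
    """Generate a per-line trait with genetic + transcriptomic architecture.

    The transcriptomic part is a weighted sum of ``n_causal_genes`` randomly
    chosen genes' standardized log2 expression in one tissue; parts are
    rescaled so the realized transcriptome-explained variance fraction equals
    ``target_rho2`` (and the direct-genetic fraction ``genetic_share`` when
    causal variants are requested).
    """
    if not (0 <= target_rho2 < 1):
        raise ValueError("target_rho2 must lie in [0, 1)")
    rng = _rng(seed, 4)
    tissue = tissue or sorted(set(expression.tissue_labels))[0]
    rows = expression.tissue_rows(tissue)
    lines = [expression.sample_ids[i].split(":")[0] for i in rows]
    logx = np.log2(expression.counts[rows] + 1.0)
    sd = logx.std(axis=0)
    usable = np.where(sd > 0)[0]
    if n_causal_genes > len(usable):
        raise ValueError("more causal genes requested than usable genes")
    if n_causal_variants > genotypes.n_variants:
        raise ValueError("more causal variants requested than variants")
    z = (logx[:, usable] - logx[:, usable].mean(axis=0)) / sd[usable]

    truth = SimTruth(target_rho2=target_rho2)
    n = len(rows)
    x_part = np.zeros(n)
    if n_causal_genes:
        gi = rng.choice(len(usable), size=n_causal_genes, replace=False)
        w = rng.standard_normal(n_causal_genes)
        x_part = z[:, gi] @ w
        for k, idx in enumerate(gi):
            truth.causal_genes[expression.gene_ids[usable[idx]]] = float(w[k])
    g_part = np.zeros(n)
    g_share = genetic_share if n_causal_variants else 0.0
    if n_causal_variants:
        order = {s: i for i, s in enumerate(genotypes.sample_ids)}
        dos = genotypes.imputed()[[order[l] for l in lines]]
        poly = np.where(dos.std(axis=0) > 0)[0]
        vi = rng.choice(poly, size=n_causal_variants, replace=False)
        a = rng.standard_normal(n_causal_variants)
        zd = (dos[:, vi] - dos[:, vi].mean(axis=0)) / dos[:, vi].std(axis=0)
        g_part = zd @ a
        for k, idx in enumerate(vi):
            truth.causal_variants[genotypes.variants["variant_id"].iloc[idx]] = float(a[k])

    noise = rng.standard_normal(n)

    def scaled(v: np.ndarray, share: float) -> np.ndarray:
        s = v.std()
        return v * (np.sqrt(share) / s) if s > 0 and share > 0 else np.zeros(n)

    e_share = max(1.0 - target_rho2 - g_share, 0.0)
    y = scaled(x_part, target_rho2) + scaled(g_part, g_share) + scaled(noise, e_share)
    return pd.Series(y, index=lines, name="trait"), truth


def simulate_multienv_phenotypes(
    n_lines: int,
    n_envs: int,
    var_line: float = 1.0,
    var_env: float = 0.5,
    var_resid: float = 1.0,
    mu: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicated phenotypes ``y[line, env] = mu + line + env + resid``."""
    if n_envs < 1:
        raise ValueError("n_envs must be >= 1")
    if min(var_line, var_env, var_resid) < 0:
        raise ValueError("variances must be >= 0")
    rng = _rng(seed, 5)
    line_eff = rng.normal(0, np.sqrt(var_line), size=n_lines)
    env_eff = rng.normal(0, np.sqrt(var_env), size=n_envs)
    rows = []
    for i in range(n_lines):
        for j in range(n_envs):
            y = mu + line_eff[i] + env_eff[j] + rng.normal(0, np.sqrt(var_resid))
            rows.append((f"L{i:04d}", f"E{j}", y))
    df = pd.DataFrame(rows, columns=["line", "env", "value"])
    df.attrs["line_effects"] = line_eff
    return df
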