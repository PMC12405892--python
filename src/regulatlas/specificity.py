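"""Tissue-specific expression calling and generic gene-set enrichment.

Per gene and tissue a t-statistic is computed for the one-vs-rest tissue
contrast on pooled, scaled log2 counts (tested tissue coded +1, all other
tissues -1, with intercept); per tissue the top 5% of genes by t are
candidates and are kept if their median count fold change against the other
tissues is at least 2. Enrichment is the hypergeometric upper tail with
Benjamini-Hochberg FDR across sets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix


def specificity_tstats(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per gene x tissue t statistics for the one-vs-rest contrast.

    Expression is log2(count+1) scaled to mean 0, variance 1 per gene with
    all tissues pooled; the regression of the scaled vector on the +1/-1
    tissue dummy (with intercept) has a slope t identical to the pooled
    two-sample t for tissue-vs-rest, which is what is computed (vectorized
    across genes). Zero-variance genes get t = 0.
    """
    tissues = expr.tissues
    if len(tissues) < 2:
        raise ValueError("at least 2 tissues required")
    logx = np.log2(expr.counts + 1.0)
    sd = logx.std(axis=0, ddof=0)
    z = np.where(sd > 0, (logx - logx.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
    n = z.shape[0]
    out = {}
    for t in tissues:
        in_t = expr.tissue_labels == t
        n1 = int(in_t.sum())
        n0 = n - n1
        if n1 < 2 or n0 < 2:
            raise ValueError(f"tissue {t!r} needs >= 2 samples on both sides")
        m1 = z[in_t].mean(axis=0)
        m0 = z[~in_t].mean(axis=0)
        ss1 = ((z[in_t] - m1) ** 2).sum(axis=0)
        ss0 = ((z[~in_t] - m0) ** 2).sum(axis=0)
        sp2 = (ss1 + ss0) / (n - 2)
        denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
        with np.errstate(invalid="ignore", divide="ignore"):
            t_stat = np.where(denom > 0, (m1 - m0) / denom, 0.0)
        out[t] = t_stat
    return pd.DataFrame(out, index=expr.gene_ids)


def call_tissue_specific(
    t_stats: pd.DataFrame,
    expr: ExpressionMatrix,
    top_pct: float = 5.0,
    min_median_fc: float = 2.0,
    pseudocount: float = 1.0,
    fold_of_medians: bool = False,
) -> pd.DataFrame:
    """Call tissue-specific genes: top ``top_pct``% by t, then fold-change filter.

    Candidates per tissue are the top 5% of genes ranked by t (ties at the
    cutoff all retained). Each candidate's fold change against every other
    tissue is (median count in tissue + pseudocount) / (median count in
    other + pseudocount); the median over the other tissues must reach
    ``min_median_fc``. With ``fold_of_medians`` the fold is instead taken
    against the pooled median of all other tissues.
    """
    if top_pct <= 0 or min_median_fc <= 0:
        raise ValueError("thresholds must be positive")
    genes = list(t_stats.index)
    n_genes = len(genes)
    n_top = int(np.floor(top_pct / 100.0 * n_genes))
    if n_top == 0:
        warnings.warn(f"top {top_pct}% of {n_genes} genes is empty; no calls made")
        return pd.DataFrame(
            columns=["gene_id", "tissue", "t_stat", "rank_pct", "median_fc", "is_specific"]
        )
    tissues = list(t_stats.columns)
    medians = {
        t: np.median(expr.counts[expr.tissue_rows(t)], axis=0) for t in tissues
    }
    gene_col = {g: j for j, g in enumerate(expr.gene_ids)}
    rows = []
    for t in tissues:
        tvals = t_stats[t].to_numpy()
        order = np.argsort(-tvals, kind="stable")
        cutoff = tvals[order[n_top - 1]]
        candidates = np.where(tvals >= cutoff)[0]  # ties at the cutoff included
        rank_pct = pd.Series(-tvals).rank(method="min").to_numpy() / n_genes * 100.0
        others = [o for o in tissues if o != t]
        for gi in candidates:
            j = gene_col[genes[gi]]
            med_t = medians[t][j]
            if fold_of_medians:
                pooled = np.median(
                    expr.counts[np.isin(expr.tissue_labels, others), j]
                )
                fc = (med_t + pseudocount) / (pooled + pseudocount)
            else:
                fcs = [
                    (med_t + pseudocount) / (medians[o][j] + pseudocount) for o in others
                ]
                fc = float(np.median(fcs))
            rows.append(
                {
                    "gene_id": genes[gi],
                    "tissue": t,
                    "t_stat": float(tvals[gi]),
                    "rank_pct": float(rank_pct[gi]),
                    "median_fc": fc,
                    "is_specific": bool(fc >= min_median_fc),
                }
            )
    return pd.DataFrame(rows)


def enrich(
    query: list[str],
    gene_sets: dict[str, tuple[str, list[str]]],
    universe: list[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of a query gene list against a collection.

    Membership is intersected with the universe; p is the upper tail
    P(X >= k); FDR is Benjamini-Hochberg across sets; fold = (k/n)/(K/N).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    if not q <= uni:
        raise ValueError("query must be a subset of the universe")
    N, n = len(uni), len(q)
    rows = []
    for set_id, (_desc, members) in gene_sets.items():
        mem = set(members) & uni
        K = len(mem)
        k = len(mem & q)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        fold = (k / n) / (K / N) if (K and n) else 0.0
        rows.append({"set_id": set_id, "k": k, "K": K, "n": n, "N": N, "fold": fold, "p_hyper": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = multipletests(df["p_hyper"], method="fdr_bh")[1]
    else:
        df["fdr"] = []
    return df
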