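"""Mixed-model numeric core.

REML variance components for the single-random-effect model

    y = C a + u + e,   u ~ N(0, sigma_u^2 R),   e ~ N(0, sigma_e^2 I)

with an arbitrary PSD relationship matrix R (genomic kinship, IBS or a
transcriptomic relationship matrix), plus EMMAX-style association scans,
stepwise conditional analysis, the Li-Ji effective number of independent
markers, and Bonferroni thresholds.

The restricted likelihood is profiled over the intraclass correlation
h = sigma_u^2 / (sigma_u^2 + sigma_e^2) on (0, 1) after one spectral
decomposition R = U D U'; every likelihood evaluation is then O(n * p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import GenotypeMatrix, RelationshipMatrix

_H_EPS = 1e-6


@dataclass
class VarianceComponents:
    sigma_u2: float
    sigma_e2: float
    rho2: float
    se_rho2: float
    log_likelihood: float
    converged: bool

    def __post_init__(self) -> None:
        if self.converged:
            assert self.sigma_u2 >= 0 and self.sigma_e2 >= 0
            assert 0.0 <= self.rho2 <= 1.0


def spectral_decomposition(R: RelationshipMatrix | np.ndarray, tol: float = 1e-8):
    """Eigendecompose a relationship matrix, clipping tiny negative modes."""
    A = R.values if isinstance(R, RelationshipMatrix) else np.asarray(R, dtype=float)
    d, U = np.linalg.eigh(A)
    scale = max(abs(d[-1]), 1.0)
    if d[0] < -tol * scale:
        raise ValueError(f"relationship matrix not PSD: min eigenvalue {d[0]:.3g}")
    return U, np.clip(d, 0.0, None)


def _restricted_ll(h: float, d: np.ndarray, yt: np.ndarray, Ct: np.ndarray) -> float:
    """Profiled restricted log-likelihood at intraclass correlation h."""
    n, p = Ct.shape
    v = h * d + (1.0 - h)
    w = 1.0 / v
    CtW = Ct * w[:, None]
    XtWX = CtW.T @ Ct
    XtWy = CtW.T @ yt
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return -np.inf
    r = yt - Ct @ beta
    rwr = float(np.sum(w * r * r))
    if rwr <= 0:
        return -np.inf
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    sigma2 = rwr / (n - p)
    return -0.5 * (
        (n - p) * (np.log(2 * np.pi * sigma2) + 1.0)
        + float(np.sum(np.log(v)))
        + logdet_xwx
    )


def reml_fit(
    y: np.ndarray,
    C: np.ndarray,
    R: RelationshipMatrix | np.ndarray | None = None,
    *,
    eig=None,
    n_grid: int = 33,
) -> VarianceComponents:
    """REML fit of variance components with relationship matrix R.

    Either ``R`` or a precomputed ``eig = (U, d)`` must be given. The
    restricted likelihood is evaluated on a coarse grid in h and refined by
    bounded scalar optimization around the best grid point. When R is (a
    multiple of) the identity the likelihood is flat in h; the fit is then
    flagged unidentifiable (``converged=False``, ``rho2=nan``).
    """
    y = np.asarray(y, dtype=float).ravel()
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[0] != len(y):
        C = C.T
    if eig is None:
        if R is None:
            raise ValueError("provide R or a precomputed eigendecomposition")
        eig = spectral_decomposition(R)
    U, d = eig
    if len(y) != len(d):
        raise ValueError("y length does not match relationship matrix")
    yt = U.T @ y
    Ct = U.T @ C
    n, p = Ct.shape

    grid = np.linspace(_H_EPS, 1.0 - _H_EPS, n_grid)
    ll = np.array([_restricted_ll(h, d, yt, Ct) for h in grid])
    finite = np.isfinite(ll)
    if not finite.any():
        raise ValueError("restricted likelihood undefined everywhere")
    spread = ll[finite].max() - ll[finite].min()
    d_spread = (d.max() - d.min()) / max(d.max(), 1e-300)
    if spread < 1e-6 or d_spread < 1e-10:
        return VarianceComponents(
            sigma_u2=np.nan, sigma_e2=np.nan, rho2=np.nan, se_rho2=np.nan,
            log_likelihood=float(ll[finite].max()), converged=False,
        )
    i = int(np.nanargmax(np.where(finite, ll, -np.inf)))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda h: -_restricted_ll(h, d, yt, Ct),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    h = float(res.x)
    ll_max = -float(res.fun)

    # total variance at the optimum
    v = h * d + (1.0 - h)
    w = 1.0 / v
    CtW = Ct * w[:, None]
    beta = np.linalg.solve(CtW.T @ Ct, CtW.T @ yt)
    r = yt - Ct @ beta
    sigma2 = float(np.sum(w * r * r)) / (n - p)

    # information-based SE from the numeric curvature of the profiled ll
    eps = 1e-4
    h0, h1 = max(h - eps, _H_EPS), min(h + eps, 1.0 - _H_EPS)
    curv = (
        _restricted_ll(h1, d, yt, Ct)
        - 2.0 * ll_max
        + _restricted_ll(h0, d, yt, Ct)
    ) / ((h1 - h) * (h - h0) + 1e-300)
    se = float(1.0 / np.sqrt(-curv)) if curv < 0 else np.nan

    return VarianceComponents(
        sigma_u2=h * sigma2,
        sigma_e2=(1.0 - h) * sigma2,
        rho2=h,
        se_rho2=se,
        log_likelihood=ll_max,
        converged=True,
    )


# ---------------------------------------------------------------------------
# association scans
# ---------------------------------------------------------------------------

class MixedModelScanner:
    """EMMAX-style scan engine: rotate once, test many predictors.

    The relationship matrix is eigendecomposed once; predictor columns are
    rotated once. Per trait, the null variance components are fit by REML
    and every predictor is then tested by GLS with the fixed covariance
    V = sigma_u^2 R + sigma_e^2 I (two-sided Wald p, normal reference).
    """

    def __init__(self, X: np.ndarray, R: RelationshipMatrix | np.ndarray, predictor_ids=None):
        X = np.asarray(X, dtype=float)
        self.U, self.d = spectral_decomposition(R)
        if X.shape[0] != len(self.d):
            raise ValueError("predictor rows do not match relationship matrix")
        # mean-impute missing predictor values before rotation
        if np.isnan(X).any():
            X = X.copy()
            mask = np.isnan(X)
            with np.errstate(invalid="ignore"):
                mu = np.nanmean(X, axis=0)
            mu = np.where(np.isnan(mu), 0.0, mu)
            X[mask] = np.broadcast_to(mu, X.shape)[mask]
        self.mono = X.std(axis=0) == 0.0
        self.Xt = self.U.T @ X
        self.predictor_ids = (
            list(predictor_ids)
            if predictor_ids is not None
            else [f"x{j}" for j in range(X.shape[1])]
        )

    def null_fit(self, y: np.ndarray, C: np.ndarray) -> VarianceComponents:
        return reml_fit(y, C, eig=(self.U, self.d))

    def scan(
        self,
        y: np.ndarray,
        C: np.ndarray,
        vc: Optional[VarianceComponents] = None,
        mode: str = "emmax",
    ) -> pd.DataFrame:
        """Test every predictor; returns beta/se/z/p per predictor."""
        y = np.asarray(y, dtype=float).ravel()
        C = np.atleast_2d(np.asarray(C, dtype=float))
        if C.shape[0] != len(y):
            C = C.T
        if mode == "exact":
            return self._scan_exact(y, C)
        if vc is None:
            vc = self.null_fit(y, C)
        yt = self.U.T @ y
        Ct = self.U.T @ C
        if vc.converged:
            v = vc.sigma_u2 * self.d + vc.sigma_e2
        else:  # flat likelihood (R ~ identity): fall back to OLS variance
            resid = yt - Ct @ np.linalg.lstsq(Ct, yt, rcond=None)[0]
            v = np.full_like(self.d, float(resid @ resid) / max(len(yt) - Ct.shape[1], 1))
        sw = 1.0 / np.sqrt(v)
        Cw = Ct * sw[:, None]
        yw = yt * sw
        Q, _ = np.linalg.qr(Cw)
        yr = yw - Q @ (Q.T @ yw)
        Gw = self.Xt * sw[:, None]
        Gr = Gw - Q @ (Q.T @ Gw)
        xtx = np.einsum("ij,ij->j", Gr, Gr)
        xty = Gr.T @ yr
        ok = (xtx > 1e-12) & ~self.mono
        beta = np.zeros(len(xtx))
        se = np.full(len(xtx), np.inf)
        beta[ok] = xty[ok] / xtx[ok]
        se[ok] = 1.0 / np.sqrt(xtx[ok])
        z = np.where(np.isfinite(se), beta / se, 0.0)
        p = np.where(ok, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
        return pd.DataFrame(
            {
                "predictor_id": self.predictor_ids,
                "beta": beta,
                "se": se,
                "z": z,
                "p": p,
                "flagged": ~ok,
            }
        )

    def _scan_exact(self, y: np.ndarray, C: np.ndarray) -> pd.DataFrame:
        """Refit variance components per predictor (verification mode)."""
        rows = []
        X = self.U @ self.Xt  # back-rotate; exact mode is small-scale only
        for j in range(X.shape[1]):
            x = X[:, j]
            if self.mono[j] or x.std() == 0:
                rows.append((self.predictor_ids[j], 0.0, np.inf, 0.0, 1.0, True))
                continue
            Cx = np.column_stack([C, x])
            vc = reml_fit(y, Cx, eig=(self.U, self.d))
            yt, Ct = self.U.T @ y, self.U.T @ Cx
            if vc.converged:
                v = vc.sigma_u2 * self.d + vc.sigma_e2
            else:
                resid = yt - Ct @ np.linalg.lstsq(Ct, yt, rcond=None)[0]
                v = np.full_like(self.d, float(resid @ resid) / max(len(yt) - Ct.shape[1], 1))
            w = 1.0 / v
            XtWX = (Ct * w[:, None]).T @ Ct
            XtWy = (Ct * w[:, None]).T @ yt
            cov = np.linalg.inv(XtWX)
            bhat = cov @ XtWy
            beta = float(bhat[-1])
            se = float(np.sqrt(cov[-1, -1]))
            z = beta / se
            rows.append(
                (self.predictor_ids[j], beta, se, z, 2.0 * stats.norm.sf(abs(z)), False)
            )
        return pd.DataFrame(rows, columns=["predictor_id", "beta", "se", "z", "p", "flagged"])

    def conditional_scan(
        self,
        y: np.ndarray,
        C: np.ndarray,
        threshold_p: float,
        variant_meta: Optional[pd.DataFrame] = None,
        max_rounds: int = 50,
    ) -> pd.DataFrame:
        """Stepwise conditional analysis: repeatedly add the top variant.

        Scan; take the smallest-p predictor below ``threshold_p`` (ties
        broken by position then id when ``variant_meta`` carries ``pos``),
        append its dosage to the covariates and rescan; stop when nothing
        passes. Variance components from the initial null fit are reused
        across rounds. Predictors collinear with prior selections are
        skipped with a warning.
        """
        if not (0 < threshold_p < 1):
            raise ValueError("threshold_p must lie in (0, 1)")
        y = np.asarray(y, dtype=float).ravel()
        C = np.atleast_2d(np.asarray(C, dtype=float))
        if C.shape[0] != len(y):
            C = C.T
        vc = self.null_fit(y, C)
        X = self.U @ self.Xt
        selected: list[int] = []
        out = []
        Ccur = C
        pos = (
            variant_meta["pos"].to_numpy()
            if variant_meta is not None and "pos" in variant_meta
            else np.arange(self.Xt.shape[1])
        )
        base_degenerate = None
        for rnd in range(1, max_rounds + 1):
            res = self.scan(y, Ccur, vc=vc)
            degenerate = res["flagged"].to_numpy() & ~self.mono
            if base_degenerate is None:
                base_degenerate = degenerate.copy()
            newly = degenerate & ~base_degenerate
            newly[selected] = False
            if newly.any():
                names = [self.predictor_ids[j] for j in np.where(newly)[0][:3]]
                warnings.warn(
                    f"{int(newly.sum())} predictor(s) collinear with selected "
                    f"covariates were skipped (e.g. {names})"
                )
                base_degenerate |= newly
            res.loc[selected, "p"] = 1.0  # never reselect
            order = np.lexsort(
                (np.asarray(self.predictor_ids, dtype=str), pos, res["p"].to_numpy())
            )
            pick = None
            for j in order:
                if res["p"].iloc[j] >= threshold_p:
                    break
                x = X[:, j]
                # collinearity with current covariates (incl. prior selections)
                r = x - Ccur @ np.linalg.lstsq(Ccur, x, rcond=None)[0]
                if float(r @ r) < 1e-10 * float(x @ x):
                    warnings.warn(
                        f"skipping {self.predictor_ids[j]}: collinear with selected covariates"
                    )
                    continue
                pick = j
                break
            if pick is None:
                break
            out.append(
                {
                    "predictor_id": self.predictor_ids[pick],
                    "beta": float(res["beta"].iloc[pick]),
                    "se": float(res["se"].iloc[pick]),
                    "p": float(res["p"].iloc[pick]),
                    "conditional_round": rnd,
                    "index": pick,
                }
            )
            selected.append(pick)
            Ccur = np.column_stack([Ccur, X[:, pick]])
        return pd.DataFrame(
            out, columns=["predictor_id", "beta", "se", "p", "conditional_round", "index"]
        )


def mlm_scan(
    y,
    C,
    G: GenotypeMatrix | np.ndarray,
    R: RelationshipMatrix | np.ndarray,
    mode: str = "emmax",
) -> pd.DataFrame:
    """Mixed-model association scan of every variant in G (thin wrapper)."""
    if isinstance(G, GenotypeMatrix):
        X, ids = G.dosages, list(G.variants["variant_id"])
    else:
        X, ids = np.asarray(G, dtype=float), None
    return MixedModelScanner(X, R, predictor_ids=ids).scan(y, C, mode=mode)


def conditional_scan(y, C, G, R, threshold_p: float) -> pd.DataFrame:
    """Stepwise conditional analysis over a genotype matrix (thin wrapper)."""
    if isinstance(G, GenotypeMatrix):
        X, ids, meta = G.dosages, list(G.variants["variant_id"]), G.variants
    else:
        X, ids, meta = np.asarray(G, dtype=float), None, None
    sc = MixedModelScanner(X, R, predictor_ids=ids)
    return sc.conditional_scan(y, C, threshold_p, variant_meta=meta)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def _li_ji(block: np.ndarray) -> float:
    """Li-Ji effective-test count for one block of dosage columns."""
    keep = block.std(axis=0) > 0
    block = block[:, keep]
    m = block.shape[1]
    if m == 0:
        return 0.0
    if m == 1:
        return 1.0
    corr = np.corrcoef(block, rowvar=False)
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0.0, None)
    tol = 1e-7  # guard the floor() discontinuity at integer eigenvalues
    return float(np.sum((lam >= 1.0 - tol) + (lam - np.floor(lam + tol))))


def effective_marker_number(
    G: GenotypeMatrix | np.ndarray, window_size: int = 200, overlap: int = 50
) -> float:
    """Effective number of independent markers (Li-Ji rule, sliding windows).

    Each window's contribution is the Li-Ji sum over eigenvalues of the
    variant correlation matrix; overlapping segments between consecutive
    windows are counted once by subtracting the segment's own Li-Ji count
    (inclusion-exclusion). Monomorphic variants carry no test and contribute
    zero.
    """
    if not window_size > overlap >= 0:
        raise ValueError("require window_size > overlap >= 0")
    X = G.imputed() if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)
    m = X.shape[1]
    if m <= window_size:
        return _li_ji(X)
    step = window_size - overlap
    me = 0.0
    prev_end = None
    for start in range(0, m, step):
        end = min(start + window_size, m)
        me += _li_ji(X[:, start:end])
        if prev_end is not None and start < prev_end:
            me -= _li_ji(X[:, start:prev_end])
        prev_end = end
        if end == m:
            break
    return me


def bonferroni_threshold(alpha: float, n_tests: float) -> float:
    """Bonferroni-style threshold alpha / n_tests (n may be fractional Me)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
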