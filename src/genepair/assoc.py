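"""Covariate-adjusted single-SNP logistic GWAS and distributional diagnostics.

The logistic fitter is a Newton/IRLS maximizer written for exhaustive scans:
it must be fast, warm-startable, and fault tolerant (separation and rank
problems are flagged per fit, never allowed to abort a scan).  Wald p-values
are reported at this stage; the interaction stage uses likelihood-ratio tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import expit
from scipy.stats import chi2, norm

CHI2_1_MEDIAN = chi2.ppf(0.5, 1)  # 0.45493642...

QUANTITATIVE_DEFAULTS = ("age",)
CATEGORICAL_DEFAULTS = ("sex", "site", "platform")


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit: coefficients, SEs, log-likelihood."""

    params: np.ndarray
    se: np.ndarray
    llf: float
    converged: bool
    n_used: int
    n_iter: int = 0

    def wald_p(self, index: int) -> float:
        if not self.converged or not np.isfinite(self.se[index]) or self.se[index] <= 0:
            return np.nan
        z = self.params[index] / self.se[index]
        return float(2.0 * norm.sf(abs(z)))


def _check_rank(X: np.ndarray) -> None:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = d.max() * max(X.shape) * np.finfo(float).eps if d.size else 0.0
    bad = piv[np.flatnonzero(d <= tol)] if d.size else np.array([], int)
    if X.shape[1] > len(d):
        bad = np.concatenate([bad, piv[len(d):]])
    if bad.size:
        raise ValueError(f"design matrix is rank deficient; aliased columns: {sorted(bad.tolist())}")


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    start: np.ndarray | None = None,
    max_iter: int = 60,
    check_rank: bool = True,
) -> LogisticFit:
    """Newton/IRLS maximum likelihood for logit P(y=1) = X beta.

    Convergence: max |score| < 1e-8 or relative log-likelihood change < 1e-10.
    Quasi-separation (runaway coefficients) is returned flagged, not raised.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.min() == y.max():
        raise ValueError("phenotype has a single class; logistic model undefined")
    if check_rank:
        _check_rank(X)
    beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    eta = X @ beta
    mu = expit(eta)
    ll = _bernoulli_ll(y, mu)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < 1e-8:
            converged = True
            break
        H = (X * w[:, None]).T @ X
        try:
            step = linalg.solve(H, score, assume_a="pos")
        except linalg.LinAlgError:
            break
        # step halving keeps the ascent monotone
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            mu_c = expit(X @ cand)
            ll_c = _bernoulli_ll(y, mu_c)
            if ll_c >= ll - 1e-12:
                break
            lam *= 0.5
        beta, mu = cand, mu_c
        if abs(ll_c - ll) < 1e-10 * (abs(ll) + 1.0):
            ll = ll_c
            converged = np.max(np.abs(X.T @ (y - mu))) < 1e-4
            break
        ll = ll_c
        if np.max(np.abs(beta)) > 30.0:  # quasi-separation
            converged = False
            break
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    try:
        cov = linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except linalg.LinAlgError:
        se = np.full(p, np.nan)
    return LogisticFit(params=beta, se=se, llf=float(ll), converged=bool(converged),
                       n_used=n, n_iter=it)


def _bernoulli_ll(y: np.ndarray, mu: np.ndarray) -> float:
    eps = 1e-12
    mu = np.clip(mu, eps, 1 - eps)
    return float(y @ np.log(mu) + (1 - y) @ np.log1p(-mu))


# ---------------------------------------------------------------------------
# covariate handling
# ---------------------------------------------------------------------------

def covariate_design(
    S: pd.DataFrame,
    covariates: list[str] | None = None,
    pcs: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Numeric covariate block: quantitative columns centered, categoricals
    one-hot encoded with the first level as reference, optional PC columns.

    No intercept column is included (model builders add it explicitly).
    """
    if covariates is None:
        covariates = [c for c in (*QUANTITATIVE_DEFAULTS, *CATEGORICAL_DEFAULTS) if c in S.columns]
        covariates += [c for c in S.columns if c.startswith("axis")]
    blocks, names = [], []
    for c in covariates:
        col = S[c]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            if dummies.shape[1]:
                blocks.append(dummies.to_numpy())
                names.extend(dummies.columns.tolist())
        else:
            v = col.to_numpy(dtype=float)
            blocks.append((v - v.mean())[:, None])
            names.append(c)
    if pcs is not None:
        pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
        if pcs.shape[0] != len(S):
            pcs = pcs.T
        blocks.append(pcs)
        names.extend(f"PC{i + 1}" for i in range(pcs.shape[1]))
    if not blocks:
        return np.empty((len(S), 0)), []
    return np.column_stack(blocks), names


def compute_pcs(G, k: int) -> np.ndarray:
    """Top-k principal component scores of the standardized dosage matrix.

    Each SNP column is centered by 2*p and scaled by sqrt(2*p*(1-p)) (p the
    sample allele frequency); missing dosages contribute 0 after centering.
    Column signs are fixed so each score vector's largest-magnitude entry is
    positive (PCs are otherwise sign-arbitrary).
    """
    dos = G.dosages
    if not 0 < k < min(dos.shape):
        raise ValueError(f"k must satisfy 0 < k < min(n, m) = {min(dos.shape)}")
    p = np.nanmean(dos, axis=0) / 2.0
    denom = np.sqrt(2.0 * p * (1.0 - p))
    ok = denom > 0
    if not ok.any():
        raise ValueError("all variants monomorphic; PCA undefined")
    Xs = (dos[:, ok] - 2.0 * p[ok]) / denom[ok]
    Xs = np.nan_to_num(Xs, nan=0.0)
    if not np.any(Xs):
        raise ValueError("standardized genotype matrix is identically zero")
    U, s, _ = np.linalg.svd(Xs, full_matrices=False)
    scores = U[:, :k] * s[:k]
    for j in range(k):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] *= -1
    return scores


# ---------------------------------------------------------------------------
# GWAS scan
# ---------------------------------------------------------------------------

def gwas_scan(
    G,
    S: pd.DataFrame,
    covariates: list[str] | None = None,
    pcs: np.ndarray | None = None,
    dosage_matrix: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant covariate-adjusted logistic association scan.

    Model: logit P(y=1) = b0 + b_g * g + covariates; the reported p-value is
    the two-sided Wald test on b_g.  Non-converged fits carry NaN p and are
    flagged.  ``dosage_matrix`` lets callers pass a pre-encoded matrix
    (mean-imputed by default).
    """
    from .io import encode_additive

    y = S["phenotype"].to_numpy(dtype=float)
    C, _ = covariate_design(S, covariates, pcs)
    dos = dosage_matrix if dosage_matrix is not None else encode_additive(G)
    n = len(y)
    base = np.column_stack([np.ones(n), C])
    base_fit = fit_logistic(y, base)
    warm = np.insert(base_fit.params, 1, 0.0)

    rows = []
    X = np.column_stack([np.ones(n), np.zeros(n), C])
    for j in range(G.n_variants):
        g = dos[:, j]
        X[:, 1] = g
        rec = G.variants.iloc[j]
        try:
            if g.std() == 0:
                raise ValueError("monomorphic")
            fit = fit_logistic(y, X, start=warm, check_rank=False)
            beta, se = fit.params[1], fit.se[1]
            p = fit.wald_p(1)
            conv = fit.converged and np.isfinite(p)
        except (ValueError, linalg.LinAlgError):
            beta, se, p, conv = np.nan, np.nan, np.nan, False
        rows.append((rec["snp_id"], rec["chrom"], rec["pos"], rec["maf"],
                     beta, se, np.exp(beta) if np.isfinite(beta) else np.nan, p, conv))
    return pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "maf", "beta", "se", "odds_ratio", "p", "converged"]
    )


def select_candidates(results: pd.DataFrame, p_max: float = 0.01) -> list[str]:
    """SNP ids with association p strictly below ``p_max`` (converged fits only)."""
    if results.empty:
        raise ValueError("empty association results")
    ok = results["converged"] & (results["p"] < p_max)
    ids = results.loc[ok, "snp_id"].tolist()
    if not ids:
        warnings.warn(f"no candidates at p < {p_max}", stacklevel=2)
    return ids


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def genomic_lambda(p_values) -> float:
    """Median-based genomic inflation factor.

    lambda = median(chi^2_1 quantiles of the observed p) / 0.4549364
    (1.0 for a perfectly calibrated scan; the usual GWAS QC diagnostic).
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    stats = chi2.isf(p, 1)
    return float(np.median(stats) / CHI2_1_MEDIAN)


def qq_points(p_values) -> pd.DataFrame:
    """Expected vs observed -log10(p) pairs for a QQ plot.

    Expected quantiles are i/(n+1); both columns are sorted jointly so each is
    monotone nondecreasing.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    expected = np.arange(n, 0, -1) / (n + 1.0)
    observed = np.sort(p)[::-1]
    return pd.DataFrame(
        {"expected": -np.log10(expected), "observed": -np.log10(observed)}
    )
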