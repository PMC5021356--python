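"""Exhaustive pairwise SNP-SNP interaction testing with likelihood-ratio tests.

For each unordered SNP pair the full model

    logit P(y=1) = b0 + b1*g1 + b2*g2 + b3*(g1*g2) + covariates

is compared against the reduced model without the product term; the statistic
2*(ll_full - ll_reduced) is referred to chi-square with 1 degree of freedom
(one product term under the additive x additive encoding).  Negative
statistics from numerical noise are clamped to zero and counted.

LD pruning precedes the scan so only one SNP per high-r^2 clique is tested:
greedy walk down a priority order (ascending main-effect p), keeping a SNP iff
its genotype-correlation r^2 with every already-kept SNP stays at or below the
cutoff.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import chi2, kstest

from .assoc import fit_logistic

LRT_CLAMP_FLOOR = -1e-8


@dataclass
class InteractionResult:
    """One SNP-pair interaction model (pair stored lexicographically)."""

    snp1: str
    snp2: str
    beta1: float = np.nan
    beta2: float = np.nan
    beta_int: float = np.nan
    ll_full: float = np.nan
    ll_reduced: float = np.nan
    lrt_stat: float = np.nan
    lrt_p: float = np.nan
    converged: bool = False
    testable: bool = True
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.snp2 < self.snp1:
            self.snp1, self.snp2 = self.snp2, self.snp1
            self.beta1, self.beta2 = self.beta2, self.beta1

    @property
    def pair(self) -> tuple[str, str]:
        return (self.snp1, self.snp2)


@dataclass
class PruneResult:
    kept: list[str] = field(default_factory=list)
    removed: list[str] = field(default_factory=list)
    removed_because: dict[str, tuple[str, float]] = field(default_factory=dict)  # snp -> (kept partner, r2)


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over samples non-missing in both; either vector constant on that
    subset is an error (correlation undefined).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape or g1.ndim != 1:
        raise ValueError("dosage vectors must be 1-D and equal length")
    ok = ~(np.isnan(g1) | np.isnan(g2))
    if ok.sum() < 3:
        raise ValueError("fewer than 3 jointly observed samples")
    a, b = g1[ok], g2[ok]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("constant dosage vector; r^2 undefined")
    r = ((a - a.mean()) @ (b - b.mean())) / (len(a) * sa * sb)
    return float(r * r)


def ld_prune(G, snp_ids: list[str], r2_max: float = 0.6) -> PruneResult:
    """Greedy LD pruning over a priority-ordered candidate list.

    Walk ``snp_ids`` in order (callers sort by ascending main-effect p so the
    strongest signal of each LD clique survives); keep a SNP iff its r^2 with
    every kept SNP is <= ``r2_max``.
    """
    idx = G.variant_index(snp_ids)
    dos = G.dosages[:, idx]
    # mean-impute for the pruning correlations; pairwise-complete would differ
    # only under heavy missingness, which QC has already bounded
    means = np.nanmean(dos, axis=0)
    miss = np.where(np.isnan(dos))
    if miss[0].size:
        dos = dos.copy()
        dos[miss] = means[miss[1]]
    centered = dos - dos.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    result = PruneResult()
    kept_cols: list[int] = []
    for j, snp in enumerate(snp_ids):
        if norms[j] == 0:
            result.removed.append(snp)
            result.removed_because[snp] = ("", np.nan)  # monomorphic, untestable
            continue
        if kept_cols:
            K = centered[:, kept_cols]
            r = (K.T @ centered[:, j]) / (norms[kept_cols] * norms[j])
            r2 = r * r
            worst = int(np.argmax(r2))
            if r2[worst] > r2_max:
                result.removed.append(snp)
                result.removed_because[snp] = (snp_ids[kept_cols[worst]], float(r2[worst]))
                continue
        result.kept.append(snp)
        kept_cols.append(j)
    return result


def _is_collinear(X: np.ndarray, v: np.ndarray) -> bool:
    """True when v lies (numerically) in the column span of X."""
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    resid = v - X @ coef
    scale = max(float(v @ v), 1e-30)
    return float(resid @ resid) / scale < 1e-10


def interaction_lrt(
    y: np.ndarray,
    g1: np.ndarray,
    g2: np.ndarray,
    covariates: np.ndarray | None = None,
    snp1: str = "snp1",
    snp2: str = "snp2",
    start: np.ndarray | None = None,
) -> InteractionResult:
    """Likelihood-ratio test of one SNP-SNP interaction beyond its main effects.

    The reduced model keeps both main effects and all covariates; only the
    product term is dropped, so the LRT has 1 degree of freedom.  A product
    term collinear with the reduced design is flagged non-testable.
    """
    y = np.asarray(y, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    n = len(y)
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, dtype=float)
    res = InteractionResult(snp1=snp1, snp2=snp2)
    swap = res.snp1 != snp1  # canonicalization may have swapped the inputs
    if swap:
        g1, g2 = g2, g1
    prod = g1 * g2
    Xred = np.column_stack([np.ones(n), g1, g2, C])
    if g1.std() == 0 or g2.std() == 0 or _is_collinear(Xred, prod):
        res.testable = False
        return res
    try:
        red = fit_logistic(y, Xred, start=start, check_rank=False)
        full = fit_logistic(
            y,
            np.column_stack([np.ones(n), g1, g2, prod, C]),
            start=np.insert(red.params, 3, 0.0),
            check_rank=False,
        )
    except (ValueError, linalg.LinAlgError):
        res.testable = False
        return res
    res.beta1, res.beta2, res.beta_int = full.params[1], full.params[2], full.params[3]
    res.ll_full, res.ll_reduced = full.llf, red.llf
    stat = 2.0 * (full.llf - red.llf)
    if stat < 0:
        res.clamped = stat < LRT_CLAMP_FLOOR
        stat = 0.0
    res.lrt_stat = float(stat)
    res.lrt_p = float(chi2.sf(stat, 1))
    res.converged = bool(full.converged and red.converged)
    return res


def pairwise_scan(
    G,
    snp_ids: list[str],
    S: pd.DataFrame,
    covariates: np.ndarray | None = None,
    pairs: list[tuple[str, str]] | None = None,
    out_path: str | None = None,
) -> list[InteractionResult]:
    """Test all C(k, 2) unordered pairs (or an explicit pair list).

    ``covariates`` is a pre-built numeric covariate block (no intercept).
    Failures are flagged per pair; the scan never aborts.  When ``out_path``
    is given, results are streamed to a TSV as they are produced.
    """
    from .io import encode_additive

    if pairs is None:
        if len(snp_ids) < 2:
            raise ValueError("need at least 2 SNPs for a pairwise scan")
        pairs = list(itertools.combinations(snp_ids, 2))
    y = S["phenotype"].to_numpy(dtype=float)
    sub = G.select_snps(snp_ids)
    dos = encode_additive(sub)
    col = {s: j for j, s in enumerate(snp_ids)}
    # warm start every reduced fit from the covariate-only optimum
    n = len(y)
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, dtype=float)
    base_fit = fit_logistic(y, np.column_stack([np.ones(n), C]))
    warm = np.insert(base_fit.params, [1, 1], 0.0)
    results: list[InteractionResult] = []
    fh = open(out_path, "w") if out_path else None
    if fh:
        fh.write("snp1\tsnp2\tbeta1\tbeta2\tbeta_int\tll_full\tll_red\tlrt_stat\tlrt_p\tstatus\n")
    try:
        for s1, s2 in pairs:
            r = interaction_lrt(y, dos[:, col[s1]], dos[:, col[s2]], covariates,
                                snp1=s1, snp2=s2, start=warm)
            results.append(r)
            if fh:
                status = "ok" if (r.testable and r.converged) else ("nontestable" if not r.testable else "nonconverged")
                fh.write(
                    f"{r.snp1}\t{r.snp2}\t{r.beta1:.6g}\t{r.beta2:.6g}\t{r.beta_int:.6g}\t"
                    f"{r.ll_full:.8g}\t{r.ll_reduced:.8g}\t{r.lrt_stat:.8g}\t{r.lrt_p:.6g}\t{status}\n"
                )
    finally:
        if fh:
            fh.close()
    return results


def top_models(results: list[InteractionResult], p_max: float = 1e-05) -> list[InteractionResult]:
    """Converged, testable models with LRT p strictly below ``p_max``, best first."""
    hits = [r for r in results if r.testable and r.converged and np.isfinite(r.lrt_p) and r.lrt_p < p_max]
    return sorted(hits, key=lambda r: (r.lrt_p, r.pair))


def ks_uniformity(
    p_values,
    lower_cut: float = 1e-05,
    conditional: bool = True,
) -> tuple[float, float]:
    """Kolmogorov-Smirnov uniformity check of the p-values above a cutoff.

    With ``conditional`` (default) the surviving p-values are rescaled to
    (0, 1) via u = (p - lower_cut)/(1 - lower_cut) before the one-sample KS
    test against Uniform(0,1) — the null that everything above the discovery
    threshold behaves like noise.  ``conditional=False`` tests the raw values.
    Returns (D statistic, KS p-value).
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    u = p[p > lower_cut]
    if u.size < 10:
        raise ValueError(f"need >= 10 p-values above {lower_cut}, have {u.size}")
    if conditional:
        u = (u - lower_cut) / (1.0 - lower_cut)
    stat, ks_p = kstest(u, "uniform")
    return float(stat), float(ks_p)


def results_to_frame(results: list[InteractionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp1": [r.snp1 for r in results],
            "snp2": [r.snp2 for r in results],
            "beta1": [r.beta1 for r in results],
            "beta2": [r.beta2 for r in results],
            "beta_int": [r.beta_int for r in results],
            "ll_full": [r.ll_full for r in results],
            "ll_reduced": [r.ll_reduced for r in results],
            "lrt_stat": [r.lrt_stat for r in results],
            "lrt_p": [r.lrt_p for r in results],
            "converged": [r.converged for r in results],
            "testable": [r.testable for r in results],
        }
    )
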