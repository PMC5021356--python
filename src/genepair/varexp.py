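"""Variance explained by a SNP set: GRM + single-component REML (GREML).

The genetic relationship matrix follows the standard standardized-dosage
cross-product: A_jk = (1/M) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)).
A binary phenotype is analyzed on the observed 0/1 scale and the resulting
variance ratio transformed to the liability scale with population prevalence K
and sample case proportion P (ascertainment-corrected).

REML maximizes the restricted likelihood of y = Xb + g + e with
Var(y) = A sg^2 + I se^2 by average-information updates with an EM fallback
and non-negativity projection.  All linear algebra runs in the eigenbasis of
A (one symmetric eigendecomposition up front), which makes every likelihood,
score and AI evaluation O(n) afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm


@dataclass
class GRM:
    values: np.ndarray  # (n, n) symmetric
    M: int  # number of SNPs used
    samples: list[str]

    def write_gcta(self, prefix: str) -> None:
        """GCTA-compatible triplet text (``<prefix>.grm`` + ``<prefix>.grm.id``)."""
        n = len(self.samples)
        with open(f"{prefix}.grm", "w") as fh:
            for i in range(n):
                for j in range(i + 1):
                    fh.write(f"{i + 1}\t{j + 1}\t{self.M}\t{self.values[i, j]:.8g}\n")
        with open(f"{prefix}.grm.id", "w") as fh:
            for s in self.samples:
                fh.write(f"{s}\t{s}\n")


@dataclass
class H2Estimate:
    sigma2_g: float
    sigma2_e: float
    h2_observed: float
    converged: bool
    degenerate: bool = False
    h2_liability: float | None = None
    K: float | None = None
    P: float | None = None
    n_iter: int = 0
    loglik: float = np.nan


def compute_grm(G, snp_subset: list[str]) -> GRM:
    """GRM from the named SNP subset; missing dosages contribute 0 (mean-centered)."""
    if len(snp_subset) < 1:
        raise ValueError("snp_subset must contain at least one SNP")
    sub = G.select_snps(snp_subset)
    dos = sub.dosages
    p = np.nanmean(dos, axis=0) / 2.0
    mono = (p <= 0) | (p >= 1)
    if mono.any():
        bad = sub.variants.loc[mono, "snp_id"].tolist()
        raise ValueError(f"monomorphic SNPs in GRM subset: {bad[:5]}")
    Z = (dos - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    Z = np.nan_to_num(Z, nan=0.0)
    A = (Z @ Z.T) / Z.shape[1]
    return GRM(values=A, M=Z.shape[1], samples=list(G.samples))


def reml_fit(
    y: np.ndarray,
    covariates: np.ndarray | None,
    grm: GRM,
    prevalence: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> H2Estimate:
    """Single-component AI-REML of Var(y) = A sg^2 + I se^2.

    ``covariates`` is a numeric block (an intercept is always added).  When the
    GRM is numerically a multiple of the identity the two components are
    aliased; this is detected and reported as degenerate rather than fitted.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 50:
        raise ValueError("REML needs n >= 50")
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)]
    )
    # drop columns aliased with earlier ones (e.g. a constant duplicating the
    # intercept) — they change nothing about the fixed-effect projection
    from scipy.linalg import qr as _qr

    _, r, piv = _qr(X, mode="economic", pivoting=True)
    dr = np.abs(np.diag(r))
    rank = int((dr > dr.max() * max(X.shape) * np.finfo(float).eps).sum())
    if rank < X.shape[1]:
        X = X[:, np.sort(piv[:rank])]
    A = grm.values
    d, U = np.linalg.eigh(A)
    d = np.clip(d, 0.0, None)  # PSD within tolerance
    if d.max() - d.min() < 1e-8 * max(1.0, d.max()):
        return H2Estimate(np.nan, np.nan, np.nan, converged=False, degenerate=True)
    yt = U.T @ y
    Xt = U.T @ X
    vary = y.var()
    floor = 1e-8 * vary

    def _parts(sg, se):
        v = sg * d + se
        vinv = 1.0 / v
        XtV = Xt * vinv[:, None]
        B = Xt.T @ XtV  # X' V^-1 X
        Bc = np.linalg.cholesky(B)
        rhs = XtV.T @ yt
        beta = np.linalg.solve(B, rhs)
        w = vinv * (yt - Xt @ beta)  # P y in rotated space
        logdetV = np.log(v).sum()
        logdetB = 2.0 * np.log(np.diag(Bc)).sum()
        ll = -0.5 * (logdetV + logdetB + yt @ w)
        return v, vinv, XtV, B, w, ll

    def _Pz(z, vinv, XtV, B):
        return vinv * z - XtV @ np.linalg.solve(B, XtV.T @ z)

    sg = se = 0.5 * vary
    v, vinv, XtV, B, w, ll = _parts(sg, se)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # tr(P Q_j) = sum(q_j / v) - tr(B^-1 X'V^-1 Q_j V^-1 X)
        Binv_Xv = np.linalg.solve(B, XtV.T)
        trP_g = (d * vinv).sum() - np.einsum("ij,ji->", Binv_Xv * d[None, :], XtV)
        trP_e = vinv.sum() - np.einsum("ij,ji->", Binv_Xv, XtV)
        s_g = -0.5 * (trP_g - w @ (d * w))
        s_e = -0.5 * (trP_e - w @ w)
        score = np.array([s_g, s_e])
        qw_g, qw_e = d * w, w
        P_qg = _Pz(qw_g, vinv, XtV, B)
        P_qe = _Pz(qw_e, vinv, XtV, B)
        AI = 0.5 * np.array(
            [[qw_g @ P_qg, qw_g @ P_qe], [qw_e @ P_qg, qw_e @ P_qe]]
        )
        stepped = False
        try:
            delta = np.linalg.solve(AI, score)
            cand = np.maximum([sg + delta[0], se + delta[1]], floor)
            v2, vinv2, XtV2, B2, w2, ll2 = _parts(*cand)
            if np.isfinite(ll2) and ll2 >= ll - 1e-10:
                stepped = True
        except np.linalg.LinAlgError:
            pass
        if not stepped:
            # EM fallback: guaranteed ascent, slow but safe
            cand = np.maximum(
                [sg + (sg**2 / n) * (w @ (d * w) - trP_g),
                 se + (se**2 / n) * (w @ w - trP_e)],
                floor,
            )
            v2, vinv2, XtV2, B2, w2, ll2 = _parts(*cand)
        dll = abs(ll2 - ll)
        sg, se = cand
        v, vinv, XtV, B, w, ll = v2, vinv2, XtV2, B2, w2, ll2
        if dll < tol:
            converged = True
            break
    h2 = sg / (sg + se)
    est = H2Estimate(float(sg), float(se), float(h2), converged=converged,
                     n_iter=it, loglik=float(ll))
    if prevalence is not None:
        P = float(np.mean(y))
        est.K, est.P = prevalence, P
        est.h2_liability = h2_liability(est.h2_observed, prevalence, P)
    return est


def h2_liability(h2_obs: float, K: float, P: float) -> float:
    """Observed-scale to liability-scale transform with case-control ascertainment.

    h2_liab = h2_obs * K^2 (1-K)^2 / (P (1-P) z^2), z the standard normal
    density at the liability threshold Phi^-1(1-K).
    """
    for name, v in (("K", K), ("P", P)):
        if not 0 < v < 1:
            raise ValueError(f"{name} must be in (0, 1)")
    z = norm.pdf(norm.ppf(1.0 - K))
    return float(h2_obs * K**2 * (1.0 - K) ** 2 / (P * (1.0 - P) * z**2))


@dataclass
class VarianceGain:
    base: H2Estimate
    combined: H2Estimate
    delta_observed: float
    delta_liability: float | None


def variance_gain(
    y: np.ndarray,
    covariates: np.ndarray | None,
    G,
    base_snps: list[str],
    added_snps: list[str],
    prevalence: float | None = None,
) -> VarianceGain:
    """Variance explained before/after adding SNPs to the GRM.

    Two REML runs: GRM from ``base_snps`` and from ``base ∪ added`` (order
    preserved); the gain is the difference of the h^2 estimates.
    """
    base_fit = reml_fit(y, covariates, compute_grm(G, base_snps), prevalence=prevalence)
    extra = [s for s in added_snps if s not in set(base_snps)]
    if not extra:
        combined_fit = base_fit
    else:
        combined_fit = reml_fit(
            y, covariates, compute_grm(G, list(base_snps) + extra), prevalence=prevalence
        )
    delta_obs = combined_fit.h2_observed - base_fit.h2_observed
    delta_liab = None
    if prevalence is not None and base_fit.h2_liability is not None:
        delta_liab = combined_fit.h2_liability - base_fit.h2_liability
    return VarianceGain(base_fit, combined_fit, float(delta_obs), delta_liab)
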