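"""Synthetic case-control cohorts with the structure the epistasis pipeline assumes.

The generator produces genotype dosages under Hardy-Weinberg equilibrium with
block-wise linkage disequilibrium, covariate and ancestry confounding, and a
logistic liability with main and pairwise-interaction genetic effects.  A pair
of cohorts can share causal *genes* while drawing different causal *SNPs* per
cohort, emulating the locus heterogeneity that motivates gene-based (rather
than exact-SNP) replication of interaction models.

LD model: within each block of ``ld_block_size`` adjacent SNPs, the two
haplotypes of each individual are thresholded equicorrelated latent Gaussians
(correlation ``ld_rho``), so adjacent-SNP genotype r^2 rises monotonically with
``ld_rho`` while each SNP individually stays in HWE at its drawn allele
frequency.

Ancestry confounding: each confounding axis shifts per-SNP allele frequencies
through random per-SNP loadings *and* enters the phenotype model, so principal
component adjustment in the association stage is load-bearing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .matrix import GenotypeMatrix

__all__ = [
    "CausalEffect",
    "CovariateSpec",
    "SimConfig",
    "Cohort",
    "simulate_gene_map",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_cohort",
    "simulate_cohort_pair",
    "inject_missingness",
]

_COLUMN_CHUNK = 512  # bound latent-Gaussian memory for large panels


@dataclass(frozen=True)
class CausalEffect:
    """A planted genetic effect on the liability scale.

    kind : 'main' (one gene) or 'interaction' (two distinct genes)
    genes : gene name(s) hosting the causal SNP(s)
    beta : log-odds effect size (per allele; for interactions, per allele-product)
    cohort_specific_snps : if True, each cohort of a simulated pair draws a
        different causal SNP inside the same gene(s) — locus heterogeneity.
    """

    kind: str
    genes: tuple[str, ...]
    beta: float
    cohort_specific_snps: bool = False

    def __post_init__(self) -> None:
        genes = tuple(self.genes) if not isinstance(self.genes, tuple) else self.genes
        object.__setattr__(self, "genes", genes)
        if self.kind == "main":
            if len(self.genes) != 1:
                raise ValueError("main effect names exactly one gene")
        elif self.kind == "interaction":
            if len(self.genes) != 2 or self.genes[0] == self.genes[1]:
                raise ValueError("interaction effect names exactly two distinct genes")
        else:
            raise ValueError(f"unknown effect kind {self.kind!r}")


@dataclass(frozen=True)
class CovariateSpec:
    """Covariate and confounder effect sizes on the log-odds scale.

    Ages are drawn N(60, 10) years (a glaucoma-study age range); ``beta_age``
    is per standard deviation of age.  Site and platform act through per-level
    log-odds offsets drawn N(0, beta_site^2) / N(0, beta_platform^2).
    ``n_axes`` ancestry axes (standard normal per sample) shift allele
    frequencies with per-SNP loadings of scale ``axis_maf_shift`` and enter the
    phenotype with coefficient ``beta_axis``.
    """

    beta_age: float = 0.2
    beta_sex: float = 0.3
    n_sites: int = 3
    beta_site: float = 0.2
    n_platforms: int = 2
    beta_platform: float = 0.2
    n_axes: int = 2
    beta_axis: float = 0.4
    axis_maf_shift: float = 0.05


@dataclass(frozen=True)
class SimConfig:
    """Full recipe for one synthetic cohort; ``seed`` determines every output."""

    n_samples: int = 2000
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.1, 0.4)
    ld_block_size: int = 1
    ld_rho: float = 0.0
    gene_count: int = 10
    snps_per_gene: int = 5
    gene_window_bp: int = 10_000
    spacing_bp: int = 20_000
    causal_spec: tuple[CausalEffect, ...] = ()
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    target_prevalence: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "causal_spec", tuple(self.causal_spec))
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must be in (0, 1)")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")

    def causal_genes(self) -> list[str]:
        seen: list[str] = []
        for eff in self.causal_spec:
            for g in eff.genes:
                if g not in seen:
                    seen.append(g)
        return seen


@dataclass
class Cohort:
    """One simulated cohort plus the record of what was planted."""

    genotypes: GenotypeMatrix
    samples: pd.DataFrame
    gene_map: pd.DataFrame
    truth: dict

    @property
    def phenotype(self) -> np.ndarray:
        return self.samples["phenotype"].to_numpy()


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, stream])


def _snp_positions(config: SimConfig) -> np.ndarray:
    return config.spacing_bp * (1 + np.arange(config.n_snps))


def gene_name(i: int) -> str:
    return f"G{i + 1:03d}"


def simulate_gene_map(config: SimConfig) -> pd.DataFrame:
    """Lay out non-overlapping gene intervals over the simulated SNP grid.

    Genes are evenly spaced runs of ``snps_per_gene`` consecutive SNPs; the
    interval is 1-based inclusive from the first to the last member SNP.
    Returns a DataFrame with columns ``gene, chrom, start, end``.
    """
    if config.gene_count < 1:
        raise ValueError(
            "gene_count must be >= 1"
            + (" (causal_spec requires genes)" if config.causal_spec else "")
        )
    stride = config.n_snps // config.gene_count
    if stride < config.snps_per_gene or config.snps_per_gene < 1:
        raise ValueError(
            f"infeasible gene layout: {config.gene_count} genes of "
            f"{config.snps_per_gene} SNPs do not fit in {config.n_snps} SNPs"
        )
    pos = _snp_positions(config)
    rows = []
    for g in range(config.gene_count):
        first = g * stride
        last = first + config.snps_per_gene - 1
        rows.append((gene_name(g), "1", int(pos[first]), int(pos[last])))
    gm = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])
    known = set(gm["gene"])
    missing = [g for g in config.causal_genes() if g not in known]
    if missing:
        raise ValueError(f"causal genes absent from gene map: {missing}")
    if config.causal_spec and config.snps_per_gene < 2:
        raise ValueError("causal genes must contain >= 2 SNPs")
    return gm


def _draw_mafs(config: SimConfig) -> np.ndarray:
    rng = _rng(config, 1)
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.n_snps)


def _axes(config: SimConfig) -> np.ndarray:
    """Ancestry axes, drawn from a dedicated stream so the genotype and
    phenotype generators see identical values."""
    rng = _rng(config, 7)
    return rng.standard_normal((config.n_samples, config.covariates.n_axes))


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """HWE genotypes with block LD and ancestry-shifted allele frequencies."""
    rng = _rng(config, 2)
    n, m = config.n_samples, config.n_snps
    mafs = _draw_mafs(config)
    axes = _axes(config)
    loadings = rng.normal(0.0, config.covariates.axis_maf_shift, size=(m, config.covariates.n_axes))
    # per-sample, per-SNP allele frequencies (confounded by ancestry)
    rho = config.ld_rho
    dos = np.empty((n, m))
    block_ids = np.arange(m) // config.ld_block_size

    start = 0
    while start < m:
        stop = min(start + _COLUMN_CHUNK, m)
        # keep blocks intact within a chunk
        while stop < m and block_ids[stop] == block_ids[stop - 1]:
            stop += 1
        cols = slice(start, stop)
        k = stop - start
        p_eff = np.clip(mafs[cols] + axes @ loadings[cols].T, 0.02, 0.98)
        thresh = ndtri(p_eff)
        geno = np.zeros((n, k))
        for hap in range(2):
            eps = rng.standard_normal((n, k))
            if rho > 0:
                # one shared latent factor per LD block and haplotype
                blocks_here = block_ids[cols] - block_ids[start]
                u = rng.standard_normal((n, blocks_here[-1] + 1))
                z = np.sqrt(rho) * u[:, blocks_here] + np.sqrt(1 - rho) * eps
            else:
                z = eps
            geno += (z < thresh).astype(float)
        dos[:, cols] = geno
        start = stop

    pos = _snp_positions(config)
    variants = pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1:05d}" for i in range(m)],
            "chrom": "1",
            "pos": pos,
            "ref": "A",
            "alt": "B",
            "info_score": 1.0,
            "true_maf": mafs,
        }
    )
    G = GenotypeMatrix(dos, [f"S{i + 1:05d}" for i in range(n)], variants)
    G.refresh_metadata()
    return G


def gene_snp_ids(G: GenotypeMatrix, gene_map: pd.DataFrame, gene: str) -> list[str]:
    row = gene_map.loc[gene_map["gene"] == gene]
    if row.empty:
        raise KeyError(f"gene {gene!r} not in gene map")
    start, end, chrom = int(row["start"].iloc[0]), int(row["end"].iloc[0]), row["chrom"].iloc[0]
    v = G.variants
    mask = (v["chrom"] == chrom) & (v["pos"] >= start) & (v["pos"] <= end)
    return v.loc[mask, "snp_id"].tolist()


def _resolve_causal_snps(
    G: GenotypeMatrix,
    gene_map: pd.DataFrame,
    config: SimConfig,
    relative_picks: dict[int, tuple[int, ...]] | None = None,
) -> list[tuple[str, ...]]:
    """Resolve each causal effect to concrete SNP ids.

    ``relative_picks`` maps effect index -> within-gene SNP ranks; when absent
    the middle SNP of each gene is used, so two cohorts with the same layout
    share causal positions by default.
    """
    resolved = []
    for i, eff in enumerate(config.causal_spec):
        ids = []
        for j, gene in enumerate(eff.genes):
            members = gene_snp_ids(G, gene_map, gene)
            if not members:
                raise ValueError(f"causal gene {gene} contains no SNPs")
            if relative_picks and i in relative_picks:
                rank = relative_picks[i][j] % len(members)
            else:
                rank = len(members) // 2
            ids.append(members[rank])
        resolved.append(tuple(ids))
    return resolved


def _covariate_frame(config: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw covariates and return (frame, log-odds contribution)."""
    cs = config.covariates
    n = config.n_samples
    age = rng.normal(60.0, 10.0, size=n)
    sex = rng.choice(["M", "F"], size=n)
    site = rng.choice([f"S{i + 1}" for i in range(cs.n_sites)], size=n)
    platform = rng.choice([f"P{i + 1}" for i in range(cs.n_platforms)], size=n)
    site_off = dict(zip([f"S{i + 1}" for i in range(cs.n_sites)],
                        rng.normal(0.0, cs.beta_site, size=cs.n_sites)))
    plat_off = dict(zip([f"P{i + 1}" for i in range(cs.n_platforms)],
                        rng.normal(0.0, cs.beta_platform, size=cs.n_platforms)))
    axes = _axes(config)
    eta = (
        cs.beta_age * (age - 60.0) / 10.0
        + cs.beta_sex * (sex == "F")
        + np.array([site_off[s] for s in site])
        + np.array([plat_off[p] for p in platform])
        + cs.beta_axis * axes.sum(axis=1)
    )
    frame = pd.DataFrame({"age": age, "sex": sex, "site": site, "platform": platform})
    for k in range(axes.shape[1]):
        frame[f"axis{k + 1}"] = axes[:, k]
    return frame, eta


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Bisection on the expected case fraction E[sigmoid(b0 + eta)] = K."""
    lo, hi = -50.0, 50.0
    f = lambda b0: expit(b0 + eta).mean() - prevalence
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            f"cannot calibrate prevalence {prevalence}: linear predictor range "
            f"[{eta.min():.2f}, {eta.max():.2f}] does not bracket it"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_phenotype(
    G: GenotypeMatrix,
    gene_map: pd.DataFrame,
    config: SimConfig,
    causal_snps: list[tuple[str, ...]] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw binary phenotypes from the logistic liability model.

    logit P(y=1) = b0 + sum main beta*g + sum interaction beta*g1*g2 + covariates,
    with b0 calibrated by bisection so the expected case fraction equals
    ``target_prevalence``.  Returns ``(sample_table, truth)`` where the truth
    record lists the resolved causal SNPs, betas and the calibrated intercept.
    """
    rng = _rng(config, 3)
    if causal_snps is None:
        causal_snps = _resolve_causal_snps(G, gene_map, config)
    frame, eta = _covariate_frame(config, rng)
    effects = []
    for eff, ids in zip(config.causal_spec, causal_snps):
        if eff.kind == "main":
            g = np.nan_to_num(G.dosage(ids[0]), nan=0.0)
            eta = eta + eff.beta * g
        else:
            g1 = np.nan_to_num(G.dosage(ids[0]), nan=0.0)
            g2 = np.nan_to_num(G.dosage(ids[1]), nan=0.0)
            eta = eta + eff.beta * g1 * g2
        effects.append(
            {"kind": eff.kind, "genes": list(eff.genes), "snps": list(ids),
             "beta": eff.beta, "cohort_specific_snps": eff.cohort_specific_snps}
        )
    b0 = _calibrate_intercept(eta, config.target_prevalence)
    y = (rng.uniform(size=config.n_samples) < expit(b0 + eta)).astype(int)
    table = pd.DataFrame({"sample_id": G.samples, "phenotype": y})
    table = pd.concat([table, frame], axis=1)
    truth = {
        "seed": config.seed,
        "intercept": b0,
        "target_prevalence": config.target_prevalence,
        "effects": effects,
        "causal_genes": config.causal_genes(),
    }
    return table, truth


def simulate_cohort(
    config: SimConfig,
    causal_snps: list[tuple[str, ...]] | None = None,
) -> Cohort:
    gm = simulate_gene_map(config) if config.gene_count >= 1 else pd.DataFrame(
        columns=["gene", "chrom", "start", "end"]
    )
    G = simulate_genotypes(config)
    table, truth = simulate_phenotype(G, gm, config, causal_snps=causal_snps)
    return Cohort(G, table, gm, truth)


def simulate_cohort_pair(
    config_discovery: SimConfig,
    config_replication: SimConfig,
) -> tuple[Cohort, Cohort]:
    """Two independent cohorts sharing causal genes.

    For effects with ``cohort_specific_snps`` the two cohorts receive distinct
    within-gene SNP ranks (locus heterogeneity); otherwise both use the same
    rank, giving identical causal positions when the layouts match.
    """
    genes_d = [e.genes for e in config_discovery.causal_spec]
    genes_r = [e.genes for e in config_replication.causal_spec]
    if genes_d != genes_r:
        raise ValueError("cohort configs must share causal gene names, in order")
    pair_rng = np.random.default_rng(
        [config_discovery.seed & 0x7FFFFFFF, config_replication.seed & 0x7FFFFFFF, 11]
    )
    picks_d: dict[int, tuple[int, ...]] = {}
    picks_r: dict[int, tuple[int, ...]] = {}
    n_per_gene = min(config_discovery.snps_per_gene, config_replication.snps_per_gene)
    for i, eff in enumerate(config_discovery.causal_spec):
        if not eff.cohort_specific_snps:
            continue
        if n_per_gene < 2:
            raise ValueError(
                f"gene(s) {eff.genes} have <2 SNPs: cannot host cohort-specific causal SNPs"
            )
        pd_, pr_ = [], []
        for _ in eff.genes:
            a, b = pair_rng.choice(n_per_gene, size=2, replace=False)
            pd_.append(int(a))
            pr_.append(int(b))
        picks_d[i] = tuple(pd_)
        picks_r[i] = tuple(pr_)

    def build(cfg: SimConfig, picks: dict[int, tuple[int, ...]]) -> Cohort:
        gm = simulate_gene_map(cfg)
        G = simulate_genotypes(cfg)
        resolved = _resolve_causal_snps(G, gm, cfg, relative_picks=picks or None)
        table, truth = simulate_phenotype(G, gm, cfg, causal_snps=resolved)
        return Cohort(G, table, gm, truth)

    return build(config_discovery, picks_d), build(config_replication, picks_r)


def inject_missingness(
    G: GenotypeMatrix,
    snp_missing_rate: float,
    low_info_fraction: float,
    seed: int,
) -> GenotypeMatrix:
    """MCAR genotype masking plus synthetic low info-score labels.

    Each genotype is masked independently with probability ``snp_missing_rate``;
    a random ``low_info_fraction`` of variants is assigned an info score drawn
    uniformly in [0.2, 0.7) (below the usual 0.7 imputation-quality cutoff).
    Call-rate and MAF metadata are recomputed.
    """
    for name, r in (("snp_missing_rate", snp_missing_rate), ("low_info_fraction", low_info_fraction)):
        if not 0 <= r < 1:
            raise ValueError(f"{name} must be in [0, 1)")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    dos = G.dosages.copy()
    if snp_missing_rate > 0:
        dos[rng.uniform(size=dos.shape) < snp_missing_rate] = np.nan
    variants = G.variants.copy()
    if low_info_fraction > 0:
        k = int(np.floor(low_info_fraction * G.n_variants))
        idx = rng.choice(G.n_variants, size=k, replace=False)
        variants.loc[variants.index[idx], "info_score"] = rng.uniform(0.2, 0.7, size=k)
    out = GenotypeMatrix(dos, list(G.samples), variants)
    out.refresh_metadata()
    return out


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["causal_spec"] = [asdict(e) for e in config.causal_spec]
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    d["causal_spec"] = tuple(
        CausalEffect(kind=e["kind"], genes=tuple(e["genes"]), beta=e["beta"],
                     cohort_specific_snps=e.get("cohort_specific_snps", False))
        for e in d.get("causal_spec", [])
    )
    if "covariates" in d and isinstance(d["covariates"], dict):
        d["covariates"] = CovariateSpec(**d["covariates"])
    if "maf_range" in d:
        d["maf_range"] = tuple(d["maf_range"])
    return SimConfig(**d)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=int(seed))


def truth_to_json(truth: dict) -> str:
    return json.dumps(truth, indent=2, sort_keys=True)
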