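"""SNP-to-gene annotation and gene-based replication of interaction models.

A discovery SNP-pair interaction is considered replicated when *any* SNP pair
spanning the same two genes (gene bodies padded by a +/-10 kb window) reaches
significance in an independent cohort.  This accommodates locus heterogeneity:
different tag or causal SNPs in the same gene pair across cohorts.

Multiple testing at the replication stage is controlled per unordered gene
pair: with G candidate genes the Bonferroni threshold is alpha / C(G, 2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epistasis import InteractionResult, pairwise_scan


@dataclass(frozen=True)
class BonferroniSpec:
    """Family-wise threshold over all unordered gene pairs."""

    n_genes: int
    alpha: float
    n_tests: int
    threshold: float

    def display(self) -> str:
        return f"{self.threshold:.1E}"


@dataclass
class GenePairSummary:
    """Best SNP-pair model for one unordered gene pair in one cohort."""

    gene1: str
    gene2: str
    min_lrt_p: float
    best_snp_pair: tuple[str, str]
    n_models: int

    def __post_init__(self) -> None:
        if self.gene2 < self.gene1:
            self.gene1, self.gene2 = self.gene2, self.gene1

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene1, self.gene2)


def map_snps_to_genes(
    variants: pd.DataFrame,
    gene_map: pd.DataFrame,
    window_bp: int = 10_000,
) -> dict[str, set[str]]:
    """Assign each SNP to every gene whose padded interval contains it.

    A SNP at position ``pos`` on chromosome ``c`` maps to gene ``g`` iff
    ``g.start - window_bp <= pos <= g.end + window_bp`` and ``g.chrom == c``
    (1-based inclusive on both boundaries).  SNPs in no window map to the
    empty set.
    """
    from .io import validate_gene_map

    gm = validate_gene_map(gene_map)
    ann: dict[str, set[str]] = {s: set() for s in variants["snp_id"]}
    pos = variants["pos"].to_numpy()
    chrom = variants["chrom"].astype(str).to_numpy()
    ids = variants["snp_id"].to_numpy()
    for _, g in gm.iterrows():
        lo, hi = g["start"] - window_bp, g["end"] + window_bp
        mask = (chrom == str(g["chrom"])) & (pos >= lo) & (pos <= hi)
        for s in ids[mask]:
            ann[s].add(g["gene"])
    return ann


def genes_from_models(
    models: list[InteractionResult],
    annotation: dict[str, set[str]],
) -> tuple[set[str], int]:
    """Union of gene assignments over all SNPs in the models.

    Returns (gene set, number of unmapped SNPs dropped); a model with one
    unmapped SNP still contributes the mapped side.
    """
    genes: set[str] = set()
    unmapped = 0
    seen: set[str] = set()
    for m in models:
        for s in (m.snp1, m.snp2):
            if s in seen:
                continue
            seen.add(s)
            gs = annotation.get(s, set())
            if gs:
                genes |= gs
            else:
                unmapped += 1
    return genes, unmapped


def expand_gene_targets(
    genes: set[str],
    G_replication,
    annotation_replication: dict[str, set[str]],
) -> list[str]:
    """All replication-cohort SNPs annotating to any target gene."""
    hits_per_gene = {g: 0 for g in genes}
    out = []
    for snp in G_replication.variants["snp_id"]:
        gs = annotation_replication.get(snp, set()) & genes
        if gs:
            out.append(snp)
            for g in gs:
                hits_per_gene[g] += 1
    empty = sorted(g for g, k in hits_per_gene.items() if k == 0)
    if empty:
        warnings.warn(f"target genes with no replication SNPs: {empty}", stacklevel=2)
    return out


def gene_pair_labels(
    snp1: str, snp2: str, annotation: dict[str, set[str]]
) -> set[tuple[str, str]]:
    """All unordered cross-gene pairs implied by the two SNPs' annotations."""
    out = set()
    for a in annotation.get(snp1, set()):
        for b in annotation.get(snp2, set()):
            if a != b:
                out.add((a, b) if a < b else (b, a))
    return out


def replication_scan(
    G_rep,
    snp_set: list[str],
    S_rep: pd.DataFrame,
    covariates: np.ndarray | None,
    annotation: dict[str, set[str]],
    cross_gene_only: bool = False,
    out_path: str | None = None,
) -> list[InteractionResult]:
    """Pairwise interaction scan over the gene-expanded replication SNP set.

    With ``cross_gene_only`` pairs whose SNPs imply no cross-gene label are
    skipped (e.g. both SNPs annotate only to the same gene).
    """
    pairs = None
    if cross_gene_only:
        import itertools

        pairs = [
            (s1, s2)
            for s1, s2 in itertools.combinations(snp_set, 2)
            if gene_pair_labels(s1, s2, annotation)
        ]
    return pairwise_scan(G_rep, snp_set, S_rep, covariates, pairs=pairs, out_path=out_path)


def bonferroni_threshold(n_genes: int, alpha: float = 0.05) -> BonferroniSpec:
    """Per-gene-pair Bonferroni: alpha over C(n_genes, 2) unordered pairs."""
    if n_genes < 2:
        raise ValueError("need at least 2 genes for a gene-pair threshold")
    n_tests = math.comb(n_genes, 2)
    return BonferroniSpec(n_genes=n_genes, alpha=alpha, n_tests=n_tests,
                          threshold=alpha / n_tests)


def collapse_to_gene_pairs(
    results: list[InteractionResult],
    annotation: dict[str, set[str]],
) -> list[GenePairSummary]:
    """Group SNP-pair models into unordered gene pairs, keeping the minimum p.

    A model whose SNPs carry multiple gene annotations contributes to every
    implied cross-gene pair.  Non-testable / non-converged models are skipped.
    """
    best: dict[tuple[str, str], GenePairSummary] = {}
    for r in results:
        if not (r.testable and r.converged and np.isfinite(r.lrt_p)):
            continue
        for pair in gene_pair_labels(r.snp1, r.snp2, annotation):
            cur = best.get(pair)
            if cur is None:
                best[pair] = GenePairSummary(pair[0], pair[1], r.lrt_p, r.pair, 1)
            else:
                cur.n_models += 1
                if r.lrt_p < cur.min_lrt_p:
                    cur.min_lrt_p = r.lrt_p
                    cur.best_snp_pair = r.pair
    return sorted(best.values(), key=lambda s: (s.min_lrt_p, s.pair))


def replicated_models(
    discovery_summaries: list[GenePairSummary],
    replication_summaries: list[GenePairSummary],
    p_marginal: float = 0.01,
    p_top: float = 0.001,
    bonferroni: BonferroniSpec | None = None,
) -> pd.DataFrame:
    """Join gene-pair summaries across cohorts and tier them by replication p.

    Tiers (on the replication cohort's min LRT p): ``marginal`` (< p_marginal),
    ``top`` (< p_top) and ``bonferroni`` (< alpha / C(n_genes, 2)) — each tier
    implies the ones above it.  One row per gene pair present in both cohorts.
    """
    rep = {s.pair: s for s in replication_summaries}
    rows = []
    for d in discovery_summaries:
        r = rep.get(d.pair)
        if r is None:
            continue
        rows.append(
            {
                "gene1": d.gene1,
                "gene2": d.gene2,
                "disc_snp1": d.best_snp_pair[0],
                "disc_snp2": d.best_snp_pair[1],
                "disc_min_p": d.min_lrt_p,
                "disc_n_models": d.n_models,
                "rep_snp1": r.best_snp_pair[0],
                "rep_snp2": r.best_snp_pair[1],
                "rep_min_p": r.min_lrt_p,
                "rep_n_models": r.n_models,
                "marginal": r.min_lrt_p < p_marginal,
                "top": r.min_lrt_p < p_top,
                "bonferroni": (r.min_lrt_p < bonferroni.threshold) if bonferroni else False,
            }
        )
    if not rows:
        warnings.warn("no gene pair present in both cohorts", stacklevel=2)
        return pd.DataFrame(
            columns=["gene1", "gene2", "disc_snp1", "disc_snp2", "disc_min_p", "disc_n_models",
                     "rep_snp1", "rep_snp2", "rep_min_p", "rep_n_models",
                     "marginal", "top", "bonferroni"]
        )
    return pd.DataFrame(rows).sort_values("rep_min_p").reset_index(drop=True)


def annotation_to_frame(annotation: dict[str, set[str]]) -> pd.DataFrame:
    return pd.DataFrame(
        {"snp_id": list(annotation), "genes": [";".join(sorted(v)) for v in annotation.values()]}
    )
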