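"""End-to-end orchestration of the two-stage gene-based epistasis workflow.

Stage order (the discovery -> replication flow):

1. load or simulate two cohorts, 2. QC both, 3. PCs + covariate-adjusted GWAS
in discovery, 4. candidate selection (p < 0.01) and LD pruning (r^2 > 0.6),
5. exhaustive pairwise interaction LRT scan, 6. diagnostics (inflation factor,
KS uniformity above the discovery threshold), 7. top models (LRT p < 1e-05)
-> gene mapping (+/-10 kb), 8. gene-based expansion and interaction scan in
replication, 9. collapse to unique gene pairs and tiered replication calls
(marginal 0.01 / top 0.001 / Bonferroni alpha over gene pairs), 10. optional
GREML variance-explained accounting.

Every stage appends its counts to a manifest and writes a TSV/JSON artifact;
a run with the same config and seed is byte-reproducible apart from
timestamps.  With ``resume=True`` the expensive scan stages reload their
artifacts instead of recomputing.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, epistasis, generep, io, varexp
from .matrix import GenotypeMatrix
from .simulate import Cohort, SimConfig, config_from_dict, config_to_dict, simulate_cohort_pair


@dataclass
class PipelineConfig:
    """All thresholds default to the standard two-stage procedure's values."""

    sim_discovery: SimConfig | None = None
    sim_replication: SimConfig | None = None
    # file-based inputs (used when sim configs are absent)
    discovery_geno: str | None = None
    discovery_pheno: str | None = None
    replication_geno: str | None = None
    replication_pheno: str | None = None
    gene_map: str | None = None
    geno_format: str = "vcf"

    gwas_p: float = 0.01
    prune_r2: float = 0.6
    discovery_lrt_p: float = 1e-05
    rep_marginal_p: float = 0.01
    rep_top_p: float = 0.001
    alpha: float = 0.05
    window_bp: int = 10_000
    maf_min: float = 0.05
    call_rate_min: float = 0.99
    info_min: float = 0.7
    n_pcs: int = 6
    prevalence: float = 0.0186
    run_h2: bool = True
    h2_n_base_snps: int = 17
    seed: int = 0
    out_dir: str = "genepair_run"

    def validate(self) -> None:
        for name in ("gwas_p", "prune_r2", "rep_marginal_p", "rep_top_p", "alpha",
                     "maf_min", "call_rate_min", "info_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0 <= self.discovery_lrt_p <= 1:
            raise ValueError("discovery_lrt_p outside [0, 1]")
        simulated = self.sim_discovery is not None and self.sim_replication is not None
        file_based = all(
            getattr(self, a) for a in
            ("discovery_geno", "discovery_pheno", "replication_geno", "replication_pheno", "gene_map")
        )
        if not (simulated or file_based):
            raise ValueError("config must provide either two SimConfigs or full file paths")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("sim_discovery", "sim_replication"):
            if getattr(self, k) is not None:
                d[k] = config_to_dict(getattr(self, k))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for k in ("sim_discovery", "sim_replication"):
            if d.get(k):
                d[k] = config_from_dict(d[k])
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _load_cohort(cfg: PipelineConfig, which: str) -> Cohort:
    G = io.read_genotypes(getattr(cfg, f"{which}_geno"), format=cfg.geno_format)
    S = io.read_sample_table(getattr(cfg, f"{which}_pheno"))
    gm = io.read_gene_map(cfg.gene_map)
    return Cohort(G, S, gm, truth={})


def _covariates(S: pd.DataFrame, pcs: np.ndarray | None) -> np.ndarray:
    C, _ = assoc.covariate_design(S, None, pcs)
    return C


def _pcs(G: GenotypeMatrix, k: int) -> np.ndarray | None:
    k = min(k, min(G.n_samples, G.n_variants) - 1)
    if k < 1:
        return None
    return assoc.compute_pcs(G, k)


def _prepare(cohort: Cohort, cfg: PipelineConfig, manifest: dict, tag: str):
    Gq, qc = io.qc_filter(cohort.genotypes, cfg.maf_min, cfg.call_rate_min, cfg.info_min)
    Gq, S = io.align_samples(Gq, cohort.samples)
    pcs = _pcs(Gq, cfg.n_pcs)
    manifest["counts"][f"{tag}_samples"] = Gq.n_samples
    manifest["counts"][f"{tag}_variants_pre_qc"] = qc.n_variants_in
    manifest["counts"][f"{tag}_variants_post_qc"] = Gq.n_variants
    return Gq, S, pcs


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute the full workflow; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "counts": {},
        "values": {},
        "stages": [],
        "stopped_at": None,
    }

    def _save(name: str) -> None:
        manifest["stages"].append(name)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    # -- stage: cohorts ---------------------------------------------------
    if config.sim_discovery is not None:
        disc, rep = simulate_cohort_pair(config.sim_discovery, config.sim_replication)
        io.write_truth(disc.truth, out / "truth_discovery.json")
        io.write_truth(rep.truth, out / "truth_replication.json")
    else:
        disc, rep = _load_cohort(config, "discovery"), _load_cohort(config, "replication")
    gene_map = disc.gene_map
    _save("cohorts")

    # -- stage: QC + covariates -------------------------------------------
    Gd, Sd, pcs_d = _prepare(disc, config, manifest, "discovery")
    Gr, Sr, pcs_r = _prepare(rep, config, manifest, "replication")
    Cd = _covariates(Sd, pcs_d)
    Cr = _covariates(Sr, pcs_r)
    _save("qc")

    # -- stage: discovery GWAS --------------------------------------------
    gwas_path = out / "gwas_discovery.tsv"
    if resume and gwas_path.exists():
        gwas = pd.read_csv(gwas_path, sep="\t")
    else:
        gwas = assoc.gwas_scan(Gd, Sd, pcs=pcs_d)
        gwas.to_csv(gwas_path, sep="\t", index=False)
    lam = assoc.genomic_lambda(gwas.loc[gwas["converged"], "p"].clip(lower=1e-300))
    manifest["values"]["gwas_lambda"] = lam
    assoc.qq_points(gwas.loc[gwas["converged"], "p"]).to_csv(
        out / "qq_gwas.tsv", sep="\t", index=False
    )
    manifest["counts"]["gwas_tests"] = int(gwas["converged"].sum())
    _save("gwas")

    # -- stage: candidates + pruning --------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        candidates = assoc.select_candidates(gwas, config.gwas_p)
    manifest["counts"]["candidates"] = len(candidates)
    if len(candidates) < 2:
        manifest["stopped_at"] = "epistasis"
        manifest["message"] = (
            f"only {len(candidates)} candidate SNP(s) at p < {config.gwas_p}; "
            "pairwise interaction scan needs >= 2"
        )
        _save("candidates")
        return manifest
    order = gwas.set_index("snp_id").loc[candidates, "p"].sort_values().index.tolist()
    prune = epistasis.ld_prune(Gd, order, config.prune_r2)
    manifest["counts"]["candidates_pruned"] = len(prune.kept)
    _save("candidates")

    if len(prune.kept) < 2:
        manifest["stopped_at"] = "epistasis"
        manifest["message"] = "fewer than 2 SNPs survive LD pruning"
        _save("prune")
        return manifest

    # -- stage: discovery interaction scan ---------------------------------
    scan_path = out / "interactions_discovery.tsv"
    results_d = epistasis.pairwise_scan(Gd, prune.kept, Sd, Cd, out_path=str(scan_path))
    ok_p = [r.lrt_p for r in results_d if r.testable and r.converged and np.isfinite(r.lrt_p)]
    manifest["counts"]["discovery_pairs_tested"] = len(results_d)
    manifest["counts"]["discovery_pairs_converged"] = len(ok_p)
    if ok_p:
        manifest["values"]["interaction_lambda"] = assoc.genomic_lambda(
            np.clip(ok_p, 1e-300, 1.0)
        )
        try:
            D, ks_p = epistasis.ks_uniformity(ok_p, config.discovery_lrt_p)
            manifest["values"]["ks_D"] = D
            manifest["values"]["ks_p"] = ks_p
        except ValueError as e:
            manifest["values"]["ks_p"] = None
            manifest["values"]["ks_note"] = str(e)
    top = epistasis.top_models(results_d, config.discovery_lrt_p)
    manifest["counts"]["top_models"] = len(top)
    _save("epistasis")

    if not top:
        manifest["stopped_at"] = "gene_mapping"
        manifest["message"] = f"no discovery model at LRT p < {config.discovery_lrt_p}"
        _save("gene_mapping")
        return manifest

    # -- stage: gene mapping ------------------------------------------------
    ann_d = generep.map_snps_to_genes(Gd.variants, gene_map, config.window_bp)
    genes, unmapped = generep.genes_from_models(top, ann_d)
    manifest["counts"]["genes"] = len(genes)
    manifest["counts"]["unmapped_top_snps"] = unmapped
    generep.annotation_to_frame(ann_d).to_csv(out / "annotation_discovery.tsv", sep="\t", index=False)
    if len(genes) >= 2:
        bonf = generep.bonferroni_threshold(len(genes), config.alpha)
        manifest["values"]["bonferroni"] = asdict(bonf)
    else:
        bonf = None
    _save("gene_mapping")

    if not genes:
        manifest["stopped_at"] = "replication"
        manifest["message"] = "no top-model SNP maps to a gene"
        _save("replication")
        return manifest

    # -- stage: replication -------------------------------------------------
    ann_r = generep.map_snps_to_genes(Gr.variants, rep.gene_map, config.window_bp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        targets = generep.expand_gene_targets(genes, Gr, ann_r)
    manifest["counts"]["replication_target_snps"] = len(targets)
    if len(targets) < 2:
        manifest["stopped_at"] = "replication"
        manifest["message"] = "fewer than 2 replication SNPs map to the target genes"
        _save("replication")
        return manifest
    # prune the replication set with main-effect p as priority
    rep_gwas = assoc.gwas_scan(Gr.select_snps(targets), Sr, pcs=pcs_r)
    rep_order = rep_gwas.sort_values("p")["snp_id"].tolist()
    rep_prune = epistasis.ld_prune(Gr, rep_order, config.prune_r2)
    manifest["counts"]["replication_snps_pruned"] = len(rep_prune.kept)
    results_r = generep.replication_scan(
        Gr, rep_prune.kept, Sr, Cr, ann_r, out_path=str(out / "interactions_replication.tsv")
    )
    manifest["counts"]["replication_pairs_tested"] = len(results_r)
    _save("replication")

    # -- stage: gene-pair collapse + tiers -----------------------------------
    disc_pairs = generep.collapse_to_gene_pairs(top, ann_d)
    rep_pairs = generep.collapse_to_gene_pairs(results_r, ann_r)
    manifest["counts"]["gene_pairs_discovery"] = len(disc_pairs)
    manifest["counts"]["gene_pairs_replication"] = len(rep_pairs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = generep.replicated_models(
            disc_pairs, rep_pairs, config.rep_marginal_p, config.rep_top_p, bonf
        )
    table.to_csv(out / "replicated_gene_pairs.tsv", sep="\t", index=False)
    manifest["counts"]["replicated_marginal"] = int(table["marginal"].sum()) if len(table) else 0
    manifest["counts"]["replicated_top"] = int(table["top"].sum()) if len(table) else 0
    manifest["counts"]["replicated_bonferroni"] = int(table["bonferroni"].sum()) if len(table) else 0
    manifest["replicated_gene_pairs"] = table.to_dict(orient="records")
    _save("gene_pairs")

    # -- stage: variance explained -------------------------------------------
    if config.run_h2:
        try:
            base = gwas.loc[gwas["converged"]].nsmallest(config.h2_n_base_snps, "p")["snp_id"].tolist()
            added = sorted(
                {s for _, row in table.iterrows() if row["top"]
                 for s in (row["disc_snp1"], row["disc_snp2"])}
            )
            gain = varexp.variance_gain(
                Sd["phenotype"].to_numpy(float), Cd, Gd, base, added, prevalence=config.prevalence
            )
            manifest["values"]["h2"] = {
                "base_observed": gain.base.h2_observed,
                "base_liability": gain.base.h2_liability,
                "combined_observed": gain.combined.h2_observed,
                "combined_liability": gain.combined.h2_liability,
                "delta_observed": gain.delta_observed,
                "delta_liability": gain.delta_liability,
                "n_base_snps": len(base),
                "n_added_snps": len(added),
            }
        except ValueError as e:
            manifest["values"]["h2"] = {"error": str(e)}
        _save("h2")

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    _save("done")
    report_text = report(manifest)
    (out / "report.md").write_text(report_text)
    return manifest


def report(manifest: dict) -> str:
    """Human-readable summary; every number is read from the manifest."""
    c, v = manifest.get("counts", {}), manifest.get("values", {})
    lines = ["# Gene-based SNP-SNP interaction analysis report", ""]
    lines.append("## Filter counts")
    lines.append("| stage | count |")
    lines.append("|---|---|")
    for key in [
        "discovery_samples", "discovery_variants_pre_qc", "discovery_variants_post_qc",
        "gwas_tests", "candidates", "candidates_pruned",
        "discovery_pairs_tested", "top_models", "genes",
        "replication_samples", "replication_variants_pre_qc", "replication_variants_post_qc",
        "replication_target_snps", "replication_snps_pruned", "replication_pairs_tested",
        "gene_pairs_discovery", "gene_pairs_replication",
    ]:
        if key in c:
            lines.append(f"| {key} | {c[key]} |")
    lines.append("")
    if "gwas_lambda" in v:
        lines.append(f"Genomic inflation factor (GWAS): lambda = {v['gwas_lambda']:.3f}")
    if "interaction_lambda" in v:
        lines.append(f"Genomic inflation factor (interaction scan): lambda = {v['interaction_lambda']:.3f}")
    if v.get("ks_p") is not None:
        lines.append(f"KS uniformity above discovery threshold: D = {v['ks_D']:.4f}, p = {v['ks_p']:.3f}")
    if "bonferroni" in v:
        b = v["bonferroni"]
        lines.append(
            f"Bonferroni: {b['n_genes']} genes -> {b['n_tests']} gene-pair tests, "
            f"threshold {b['alpha']}/{b['n_tests']} = {b['threshold']:.4E}"
        )
    lines.append("")
    lines.append("## Replicated gene pairs")
    pairs = manifest.get("replicated_gene_pairs", [])
    n_top = c.get("replicated_top", 0)
    if not pairs or n_top == 0:
        lines.append("0 replicated gene pairs at the top-tier threshold.")
    if pairs:
        lines.append("| gene1 | gene2 | disc best pair | disc min p | rep best pair | rep min p | tier |")
        lines.append("|---|---|---|---|---|---|---|")
        for r in pairs:
            tier = "bonferroni" if r["bonferroni"] else ("top" if r["top"] else ("marginal" if r["marginal"] else "-"))
            lines.append(
                f"| {r['gene1']} | {r['gene2']} | {r['disc_snp1']},{r['disc_snp2']} | "
                f"{r['disc_min_p']:.3g} | {r['rep_snp1']},{r['rep_snp2']} | {r['rep_min_p']:.3g} | {tier} |"
            )
    if "h2" in v and "error" not in v["h2"]:
        h = v["h2"]
        lines.append("")
        lines.append("## Variance explained (GREML, liability scale)")
        lines.append(
            f"base ({h['n_base_snps']} SNPs): {_fmt(h['base_liability'])}; "
            f"base + interaction SNPs ({h['n_added_snps']} added): {_fmt(h['combined_liability'])}; "
            f"gain: {_fmt(h['delta_liability'])}"
        )
    if manifest.get("stopped_at"):
        lines.append("")
        lines.append(f"Pipeline stopped early at stage '{manifest['stopped_at']}': "
                     f"{manifest.get('message', '')}")
    return "\n".join(lines) + "\n"


def _fmt(x) -> str:
    return "n/a" if x is None else f"{100 * x:.1f}%"
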