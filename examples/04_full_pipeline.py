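"""The complete discovery -> replication workflow from one config object.

Simulates two cohorts sharing a causal gene pair with cohort-specific causal
SNPs, runs GWAS -> candidates -> pruning -> interaction scan -> gene mapping
-> gene-based replication -> tiered calls, and prints the report.
"""

import numpy as np

import genepair as gp

spec = (gp.CausalEffect("interaction", ("G002", "G007"), np.log(2.5),
                        cohort_specific_snps=True),)
cfg_d = gp.SimConfig(n_samples=1200, n_snps=50, gene_count=10, snps_per_gene=4,
                     seed=4001, causal_spec=spec)
config = gp.PipelineConfig(
    sim_discovery=cfg_d,
    sim_replication=gp.simulate.with_seed(cfg_d, 4002),
    gwas_p=0.5,            # permissive candidate filter for this small panel
    discovery_lrt_p=1e-3,  # discovery threshold scaled to 1225 tests
    n_pcs=2,
    out_dir="pipeline_demo",
)
manifest = gp.run_pipeline(config)
print(gp.pipeline.report(manifest))
print("The planted gene pair (G002, G007) appears in the table above; its")
print("per-cohort best SNP pairs differ because the causal SNPs differ, and at")
print("1200 samples/cohort it typically lands in the marginal replication tier.")
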