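"""Gene-window annotation, gene-based expansion, Bonferroni, gene-pair collapse."""

import numpy as np
import pandas as pd
import pytest

from genepair.epistasis import InteractionResult
from genepair.generep import (
    bonferroni_threshold,
    collapse_to_gene_pairs,
    expand_gene_targets,
    gene_pair_labels,
    genes_from_models,
    map_snps_to_genes,
    replicated_models,
    replication_scan,
)
from genepair.generep import GenePairSummary


def variants(pos_ids, chrom="1"):
    return pd.DataFrame(
        {"snp_id": [s for s, _ in pos_ids], "chrom": chrom, "pos": [p for _, p in pos_ids]}
    )


GENES = pd.DataFrame(
    {"gene": ["A", "B"], "chrom": "1", "start": [50_000, 200_000], "end": [60_000, 250_000]}
)


class TestMapping:
    def test_window_boundaries_inclusive(self):
        v = variants([("in", 40_000), ("out", 39_999), ("tail", 70_000), ("far", 70_001)])
        ann = map_snps_to_genes(v, GENES, window_bp=10_000)
        assert ann["in"] == {"A"}
        assert ann["out"] == set()
        assert ann["tail"] == {"A"}
        assert ann["far"] == set()

    def test_overlapping_windows_multi_assign(self):
        genes = pd.DataFrame(
            {"gene": ["A", "B"], "chrom": "1", "start": [100, 180], "end": [150, 250]}
        )
        ann = map_snps_to_genes(variants([("s", 170)]), genes, window_bp=30)
        assert ann["s"] == {"A", "B"}

    def test_chromosome_must_match(self):
        v = variants([("s", 55_000)], chrom="2")
        ann = map_snps_to_genes(v, GENES, window_bp=10_000)
        assert ann["s"] == set()

    def test_duplicate_genes_rejected(self):
        dup = pd.concat([GENES, GENES.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate gene names"):
            map_snps_to_genes(variants([("s", 1)]), dup)

    def test_brute_force_interval_oracle(self):
        rng = np.random.default_rng(0)
        pos = rng.integers(1, 1_000_000, 200)
        v = variants([(f"s{i}", int(p)) for i, p in enumerate(pos)])
        starts = rng.integers(1, 900_000, 20)
        genes = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(20)], "chrom": "1",
             "start": starts, "end": starts + rng.integers(1_000, 50_000, 20)}
        )
        w = 10_000
        ann = map_snps_to_genes(v, genes, w)
        for i, p in enumerate(pos):
            expect = {
                row["gene"] for _, row in genes.iterrows()
                if row["start"] - w <= p <= row["end"] + w
            }
            assert ann[f"s{i}"] == expect


class TestGenesFromModels:
    def test_single_and_union(self):
        ann = {"s1": {"A"}, "s2": {"A"}, "s3": {"B"}, "s4": {"C"}, "s5": set()}
        one = [InteractionResult("s1", "s2")]
        assert genes_from_models(one, ann) == ({"A"}, 0)
        many = [InteractionResult("s1", "s3"), InteractionResult("s3", "s4"),
                InteractionResult("s5", "s1")]
        genes, unmapped = genes_from_models(many, ann)
        assert genes == {"A", "B", "C"}
        assert unmapped == 1


class TestExpandTargets:
    def test_selects_all_window_snps_and_warns_on_empty_gene(self, matrix_factory):
        dos = np.tile([0.0, 1.0, 2.0, 1.0], (8, 1)).T[:, :5][:4]
        dos = np.random.default_rng(1).binomial(2, 0.3, (20, 5)).astype(float)
        G = matrix_factory(dos, pos=[10, 20, 30, 500, 600])
        ann = {"s1": {"A"}, "s2": {"A"}, "s3": {"A"}, "s4": set(), "s5": set()}
        with pytest.warns(UserWarning, match="ZZ"):
            got = expand_gene_targets({"A", "ZZ"}, G, ann)
        assert got == ["s1", "s2", "s3"]

    def test_annotation_inversion_oracle(self, matrix_factory):
        rng = np.random.default_rng(2)
        G = matrix_factory(rng.binomial(2, 0.3, (10, 30)).astype(float))
        genes = ["A", "B", "C"]
        ann = {s: {g for g in genes if rng.uniform() < 0.3} for s in G.snp_ids}
        targets = {"A", "C"}
        got = expand_gene_targets(targets, G, ann)
        expect = [s for s in G.snp_ids if ann[s] & targets]
        assert got == expect


class TestReplicationScan:
    def test_cross_gene_only_counting(self, matrix_factory):
        rng = np.random.default_rng(3)
        n = 400
        dos = rng.binomial(2, 0.3, (n, 4)).astype(float)
        G = matrix_factory(dos)
        S = pd.DataFrame({"sample_id": G.samples,
                          "phenotype": rng.integers(0, 2, n)})
        ann = {"s1": {"A"}, "s2": {"A"}, "s3": {"B"}, "s4": {"B"}}
        cross = replication_scan(G, G.snp_ids, S, None, ann, cross_gene_only=True)
        assert len(cross) == 4
        assert all(gene_pair_labels(r.snp1, r.snp2, ann) == {("A", "B")} for r in cross)
        full = replication_scan(G, G.snp_ids, S, None, ann, cross_gene_only=False)
        assert len(full) == 6


class TestBonferroni:
    def test_91_genes_matches_published_arithmetic(self):
        spec = bonferroni_threshold(91, 0.05)
        assert spec.n_tests == 4095
        assert spec.threshold == 0.05 / 4095  # 1.221e-05, printed as 1.2E-05
        assert spec.display() == "1.2E-05"
        assert spec.threshold * spec.n_tests == pytest.approx(0.05, abs=1e-15)

    def test_two_genes_is_alpha(self):
        assert bonferroni_threshold(2, 0.05).threshold == 0.05

    def test_33_genes_hand_arithmetic(self):
        spec = bonferroni_threshold(33, 0.05)
        assert spec.n_tests == 33 * 32 // 2 == 528
        assert spec.threshold == pytest.approx(9.4697e-05, rel=1e-4)

    def test_fewer_than_two_errors(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(1)


class TestCollapse:
    def test_group_min_and_count(self):
        ann = {"s1": {"A"}, "s2": {"B"}, "s3": {"A"}, "s4": {"B"}}
        rows = [
            InteractionResult("s1", "s2", lrt_p=1e-6, converged=True),
            InteractionResult("s3", "s4", lrt_p=5e-6, converged=True),
        ]
        out = collapse_to_gene_pairs(rows, ann)
        assert len(out) == 1
        s = out[0]
        assert s.pair == ("A", "B")
        assert s.min_lrt_p == 1e-6
        assert s.best_snp_pair == ("s1", "s2")
        assert s.n_models == 2

    def test_canonical_gene_order(self):
        ann = {"x": {"Z"}, "y": {"A"}}
        out = collapse_to_gene_pairs([InteractionResult("x", "y", lrt_p=0.01, converged=True)], ann)
        assert out[0].pair == ("A", "Z")

    def test_group_by_min_oracle(self):
        rng = np.random.default_rng(4)
        genes = ["A", "B", "C", "D"]
        snps = [f"s{i}" for i in range(12)]
        ann = {s: {rng.choice(genes)} for s in snps}
        rows = []
        for _ in range(60):
            s1, s2 = rng.choice(snps, 2, replace=False)
            rows.append(InteractionResult(s1, s2, lrt_p=float(rng.uniform()), converged=True))
        out = {s.pair: s for s in collapse_to_gene_pairs(rows, ann)}
        # brute-force group-by
        expect: dict[tuple, list] = {}
        for r in rows:
            for pair in gene_pair_labels(r.snp1, r.snp2, ann):
                expect.setdefault(pair, []).append(r)
        assert set(out) == set(expect)
        for pair, models in expect.items():
            assert out[pair].min_lrt_p == min(m.lrt_p for m in models)
            assert out[pair].n_models == len(models)

    def test_model_count_bound(self):
        ann = {"s1": {"A", "B"}, "s2": {"C"}}
        rows = [InteractionResult("s1", "s2", lrt_p=0.5, converged=True)]
        out = collapse_to_gene_pairs(rows, ann)
        assert {s.pair for s in out} == {("A", "C"), ("B", "C")}


class TestReplicatedModels:
    def test_inner_join_and_tiers(self):
        disc = [GenePairSummary("A", "B", 1e-7, ("s1", "s2"), 3),
                GenePairSummary("C", "D", 1e-6, ("s3", "s4"), 1)]
        rep = [GenePairSummary("A", "B", 1e-6, ("t1", "t2"), 2),
               GenePairSummary("E", "F", 1e-9, ("t3", "t4"), 1)]
        bonf = bonferroni_threshold(91, 0.05)
        out = replicated_models(disc, rep, bonferroni=bonf)
        assert len(out) == 1  # C,D and E,F absent from the join
        row = out.iloc[0]
        assert (row["gene1"], row["gene2"]) == ("A", "B")
        assert row["marginal"] and row["top"] and row["bonferroni"]
        assert row["rep_snp1"] == "t1"

    def test_bonferroni_tier_uses_published_threshold(self):
        disc = [GenePairSummary("A", "B", 1e-7, ("s1", "s2"), 1)]
        bonf = bonferroni_threshold(91, 0.05)
        near = [GenePairSummary("A", "B", 1.3e-5, ("t1", "t2"), 1)]
        out = replicated_models(disc, near, bonferroni=bonf)
        assert not out.iloc[0]["bonferroni"]  # 1.3e-5 > 1.22e-5
        under = [GenePairSummary("A", "B", 1e-6, ("t1", "t2"), 1)]
        out2 = replicated_models(disc, under, bonferroni=bonf)
        assert out2.iloc[0]["bonferroni"]

    def test_empty_join_warns(self):
        with pytest.warns(UserWarning, match="no gene pair"):
            out = replicated_models(
                [GenePairSummary("A", "B", 0.1, ("s", "t"), 1)],
                [GenePairSummary("C", "D", 0.1, ("u", "v"), 1)],
            )
        assert out.empty
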