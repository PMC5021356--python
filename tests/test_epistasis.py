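"""LD pruning, the pairwise interaction LRT, and the discovery diagnostics."""

import itertools

import numpy as np
import pytest
from scipy import optimize
from scipy.special import expit
from scipy.stats import kstest

from genepair.assoc import covariate_design, genomic_lambda
from genepair.epistasis import (
    InteractionResult,
    interaction_lrt,
    ks_uniformity,
    ld_prune,
    ld_r2,
    pairwise_scan,
    top_models,
)


def nll(beta, y, X):
    eta = X @ beta
    # stable log(1 + exp(eta)) - y*eta
    return float(np.logaddexp(0.0, eta).sum() - y @ eta)


def optimizer_ll(y, X):
    """Maximum log-likelihood from a general-purpose optimizer (oracle)."""
    grad = lambda b, y, X: X.T @ (expit(X @ b) - y)
    hess = lambda b, y, X: (X * (expit(X @ b) * (1 - expit(X @ b)))[:, None]).T @ X
    res = optimize.minimize(
        nll, np.zeros(X.shape[1]), args=(y, X), jac=grad, hess=hess,
        method="trust-exact", options={"gtol": 1e-10},
    )
    return -res.fun


def simulate_pair_dataset(rng, n=1000, beta_int=0.0, n_covar=3):
    g1 = rng.binomial(2, 0.3, n).astype(float)
    g2 = rng.binomial(2, 0.4, n).astype(float)
    C = rng.standard_normal((n, n_covar))
    eta = -1.0 + 0.1 * g1 - 0.1 * g2 + beta_int * g1 * g2 + C @ np.full(n_covar, 0.2)
    y = (rng.uniform(size=n) < expit(eta)).astype(float)
    return y, g1, g2, C


class TestLdR2:
    def test_identity_and_flip(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.3, 100).astype(float)
        assert ld_r2(g, g) == pytest.approx(1.0)
        assert ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        g1 = rng.binomial(2, 0.3, 50).astype(float)
        g2 = rng.binomial(2, 0.4, 50).astype(float)
        cov = np.mean((g1 - g1.mean()) * (g2 - g2.mean()))
        direct = cov**2 / (g1.var() * g2.var())
        assert ld_r2(g1, g2) == pytest.approx(direct, abs=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            ld_r2(np.zeros(10), np.arange(10.0) % 3)

    def test_missing_handled_pairwise(self):
        rng = np.random.default_rng(2)
        g1 = rng.binomial(2, 0.3, 60).astype(float)
        g2 = rng.binomial(2, 0.4, 60).astype(float)
        g1m = g1.copy()
        g1m[:10] = np.nan
        assert ld_r2(g1m, g2) == pytest.approx(ld_r2(g1[10:], g2[10:]))


class TestLdPrune:
    def test_duplicate_keeps_first_in_priority(self, matrix_factory):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.3, 200).astype(float)
        G = matrix_factory(np.column_stack([g, g, rng.binomial(2, 0.3, 200)]))
        res = ld_prune(G, ["s2", "s1", "s3"], 0.6)  # s2 has priority
        assert res.kept == ["s2", "s3"]
        assert res.removed == ["s1"]
        assert res.removed_because["s1"][0] == "s2"

    def test_independent_snps_all_kept(self, null_cohort):
        G = null_cohort.genotypes
        res = ld_prune(G, G.snp_ids, 0.6)
        assert res.kept == G.snp_ids

    def test_posthoc_oracle_on_random_fixture(self, matrix_factory):
        # 30 SNPs with planted correlation structure
        rng = np.random.default_rng(4)
        n = 300
        base = rng.binomial(2, 0.3, (n, 10)).astype(float)
        cols = [base[:, i % 10] if i < 20 else rng.binomial(2, 0.3, n).astype(float)
                for i in range(30)]
        # jitter duplicated columns so r2 varies around the threshold
        dos = np.column_stack(
            [np.clip(c + (rng.uniform(size=n) < 0.15) * rng.choice([-1, 1], n), 0, 2)
             for c in cols]
        )
        G = matrix_factory(dos)
        order = list(rng.permutation(G.snp_ids))
        res = ld_prune(G, order, 0.6)
        assert sorted(res.kept + res.removed) == sorted(order)
        lookup = {s: G.dosage(s) for s in order}
        for a, b in itertools.combinations(res.kept, 2):
            assert ld_r2(lookup[a], lookup[b]) <= 0.6
        for s in res.removed:
            partner, r2 = res.removed_because[s]
            assert r2 > 0.6
            assert partner in res.kept
            assert ld_r2(lookup[s], lookup[partner]) == pytest.approx(r2)


class TestInteractionLrt:
    def test_degenerate_constant_snp_flagged(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 100).astype(float)
        g1 = rng.binomial(2, 0.3, 100).astype(float)
        res = interaction_lrt(y, g1, np.zeros(100))
        assert not res.testable

    def test_pair_symmetry_exact(self):
        rng = np.random.default_rng(6)
        y, g1, g2, C = simulate_pair_dataset(rng, n=500, beta_int=0.3)
        a = interaction_lrt(y, g1, g2, C, snp1="aa", snp2="bb")
        b = interaction_lrt(y, g2, g1, C, snp1="bb", snp2="aa")
        assert a.pair == b.pair == ("aa", "bb")
        assert a.lrt_stat == b.lrt_stat
        assert (a.beta1, a.beta2) == (b.beta1, b.beta2)

    def test_statistic_matches_independent_optimizer(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            y, g1, g2, C = simulate_pair_dataset(rng, n=800, beta_int=0.25)
            res = interaction_lrt(y, g1, g2, C)
            n = len(y)
            Xr = np.column_stack([np.ones(n), g1, g2, C])
            Xf = np.column_stack([np.ones(n), g1, g2, g1 * g2, C])
            oracle = 2 * (optimizer_ll(y, Xf) - optimizer_ll(y, Xr))
            assert res.lrt_stat == pytest.approx(oracle, abs=1e-6)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(300):
            y, g1, g2, C = simulate_pair_dataset(rng, n=400, beta_int=0.0, n_covar=2)
            r = interaction_lrt(y, g1, g2, C)
            if r.testable and r.converged:
                ps.append(r.lrt_p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_nonnegative_statistic(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            y, g1, g2, C = simulate_pair_dataset(rng, n=300)
            r = interaction_lrt(y, g1, g2, C)
            if r.testable:
                assert r.lrt_stat >= 0.0


class TestPairwiseScan:
    def test_three_snps_three_pairs(self, null_cohort):
        G, S = null_cohort.genotypes, null_cohort.samples
        res = pairwise_scan(G, G.snp_ids[:3], S)
        assert len(res) == 3
        assert {r.pair for r in res} == set(itertools.combinations(sorted(G.snp_ids[:3]), 2))

    def test_planted_pair_is_scan_minimum(self, interaction_cohort):
        cohort = interaction_cohort
        G, S = cohort.genotypes, cohort.samples
        C, _ = covariate_design(S)
        snps = G.snp_ids
        res = pairwise_scan(G, snps, S, C)
        best = min((r for r in res if r.testable), key=lambda r: r.lrt_p)
        assert set(best.pair) == set(cohort.truth["effects"][0]["snps"])

    def test_needs_two_snps(self, null_cohort):
        with pytest.raises(ValueError, match="at least 2"):
            pairwise_scan(null_cohort.genotypes, ["snp00001"], null_cohort.samples)

    def test_streaming_tsv(self, tmp_path, null_cohort):
        G, S = null_cohort.genotypes, null_cohort.samples
        out = tmp_path / "scan.tsv"
        res = pairwise_scan(G, G.snp_ids[:4], S, out_path=str(out))
        import pandas as pd
        df = pd.read_csv(out, sep="\t")
        assert len(df) == len(res) == 6
        assert np.allclose(df["lrt_stat"], [r.lrt_stat for r in res], atol=1e-6)


class TestTopModels:
    def test_empty_and_boundary(self):
        assert top_models([]) == []
        rows = [
            InteractionResult("a", "b", lrt_p=2e-6, converged=True),
            InteractionResult("c", "d", lrt_p=1e-5, converged=True),
            InteractionResult("e", "f", lrt_p=0.3, converged=True),
        ]
        out = top_models(rows, 1e-5)
        assert [r.pair for r in out] == [("a", "b")]

    def test_matches_comprehension_oracle(self):
        rng = np.random.default_rng(10)
        rows = [
            InteractionResult(f"s{i}", f"t{i}", lrt_p=float(p), converged=bool(c),
                              testable=bool(t))
            for i, (p, c, t) in enumerate(
                zip(rng.uniform(size=100), rng.integers(0, 2, 100), rng.integers(0, 2, 100))
            )
        ]
        got = top_models(rows, 0.3)
        expect = sorted(
            [r for r in rows if r.testable and r.converged and r.lrt_p < 0.3],
            key=lambda r: (r.lrt_p, r.pair),
        )
        assert got == expect


class TestKsUniformity:
    def test_analytic_grid(self):
        n = 50
        cut = 1e-5
        u = (np.arange(1, n + 1) - 0.5) / n
        p = cut + u * (1 - cut)  # rescales back to the (i-0.5)/n grid
        D, _ = ks_uniformity(p, cut)
        assert D == pytest.approx(1 / (2 * n), abs=1e-12)

    def test_degenerate_point_mass(self):
        _, p = ks_uniformity([0.999] * 50, 1e-5)
        assert p < 1e-10

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError, match=">= 10"):
            ks_uniformity([0.5] * 5, 1e-5)

    def test_calibrated_on_uniform(self):
        rng = np.random.default_rng(11)
        rejected = sum(
            ks_uniformity(rng.uniform(size=500), 1e-5)[1] < 0.05 for _ in range(200)
        )
        # rejection rate ~ Binomial(200, 0.05): 99% CI roughly [2, 19]
        assert 1 <= rejected <= 20


class TestInteractionInflation:
    def test_null_scan_lambda_near_one(self, null_cohort):
        G, S = null_cohort.genotypes, null_cohort.samples
        C, _ = covariate_design(S)
        res = pairwise_scan(G, G.snp_ids, S, C)
        ps = [r.lrt_p for r in res if r.testable and r.converged]
        lam = genomic_lambda(ps)
        assert 0.85 < lam < 1.15  # wider band than the 1e4-test criterion: 780 tests
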