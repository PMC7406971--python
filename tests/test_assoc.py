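"""Association scans: correlation, partial correlation, LMM, group tests."""

import numpy as np
import pandas as pd
import pytest

from hexagwas import assoc
from hexagwas import genotypes as gt
from hexagwas import relatedness as rel
from hexagwas import simulate as sim
from conftest import ad_from_pop, filtered_diploidized


def quant_from(geno):
    geno = np.asarray(geno, dtype=float)
    mk = pd.DataFrame({"chrom": ["c"] * geno.shape[0], "pos": range(1, geno.shape[0] + 1)})
    return gt.QuantGenotypeMatrix(mk, [f"i{j}" for j in range(geno.shape[1])], geno)


class TestBonferroni:
    def test_printed_thresholds(self):
        assert f"{assoc.bonferroni_threshold(0.1, 40111):.2f}" == "5.60"
        assert f"{assoc.bonferroni_threshold(0.1, 95639):.2f}" == "5.98"
        assert f"{assoc.bonferroni_threshold(0.1, 1):.2f}" == "1.00"

    def test_monotonicity(self):
        ts = [assoc.bonferroni_threshold(0.1, n) for n in (10, 100, 1000)]
        assert ts[0] < ts[1] < ts[2]
        assert assoc.bonferroni_threshold(0.05, 100) > assoc.bonferroni_threshold(0.1, 100)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            assoc.bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            assoc.bonferroni_threshold(0.1, 0)


class TestCorrelationScan:
    def test_phenotype_equal_to_marker_attains_max_r(self):
        rng = np.random.default_rng(0)
        G = rng.uniform(0, 1, (40, 50))
        y = G[7].copy()
        res = assoc.correlation_scan(quant_from(G), y)
        top = res.table.loc[res.table["stat"].abs().idxmax()]
        assert top["pos"] == 8
        assert abs(top["stat"]) == pytest.approx(1.0)

    def test_constant_marker_skipped(self):
        rng = np.random.default_rng(1)
        G = rng.uniform(0, 1, (5, 30))
        G[2] = 0.5
        res = assoc.correlation_scan(quant_from(G), rng.normal(size=30))
        assert res.n_tests == 4
        assert 3 not in list(res.table["pos"])

    def test_empirical_calibration_under_null(self):
        # empirical standardization forces ~5% of |z| beyond 1.96
        rng = np.random.default_rng(2)
        G = rng.uniform(0, 1, (2000, 100))
        res = assoc.correlation_scan(quant_from(G), rng.normal(size=100))
        assert (res.table["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.015)

    def test_fisher_mode_on_independent_data(self):
        rng = np.random.default_rng(3)
        G = rng.uniform(0, 1, (2000, 100))
        res = assoc.correlation_scan(quant_from(G), rng.normal(size=100), mode="fisher")
        assert (res.table["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.02)


class TestPartialCorrelation:
    def test_reduces_to_plain_r_when_covariate_orthogonal(self):
        rng = np.random.default_rng(4)
        n = 60
        y = rng.normal(size=n)
        G = rng.uniform(0, 1, (20, n))
        O = rng.normal(size=n)
        # orthogonalize O against y and every genotype row (exact zero r)
        basis = np.linalg.qr(np.column_stack([np.ones(n), y, G.T]))[0]
        O = O - basis @ (basis.T @ O)
        plain = assoc.correlation_scan(quant_from(G), y)
        part = assoc.partial_correlation_scan(quant_from(G), y, O)
        assert np.allclose(plain.table["stat"], part.table["stat"], atol=1e-10)

    def test_matches_residual_regression_identity(self):
        # partial r == corr(resid(y|O), resid(g|O)) to 1e-10
        rng = np.random.default_rng(5)
        n = 80
        O = rng.normal(size=n)
        y = 0.6 * O + rng.normal(size=n)
        G = 0.4 * O[None, :] + rng.uniform(0, 1, (30, n))
        res = assoc.partial_correlation_scan(quant_from(G), y, O)

        X = np.column_stack([np.ones(n), O])
        H = X @ np.linalg.pinv(X)
        ry = y - H @ y
        for i, pr in enumerate(res.table["stat"]):
            rg = G[i] - H @ G[i]
            oracle = np.corrcoef(ry, rg)[0, 1]
            assert pr == pytest.approx(oracle, abs=1e-10)

    def test_collinear_marker_skipped(self):
        rng = np.random.default_rng(6)
        n = 40
        O = rng.normal(size=n)
        G = rng.uniform(0, 1, (3, n))
        G[1] = 0.1 * O + 0.5  # |r_ab| = 1
        res = assoc.partial_correlation_scan(quant_from(G), rng.normal(size=n), O)
        assert 2 not in list(res.table["pos"])

    def test_incomplete_covariate_rejected(self):
        G = np.random.default_rng(7).uniform(0, 1, (2, 20))
        O = np.full(20, 1.0)
        O[3] = np.nan
        with pytest.raises(ValueError, match="complete"):
            assoc.partial_correlation_scan(quant_from(G), np.ones(20), O)


class TestLMM:
    def test_identity_kinship_collapses_to_ols(self):
        rng = np.random.default_rng(8)
        n = 50
        y, O = rng.normal(size=n), rng.normal(size=n)
        S = rng.integers(0, 3, (8, n)).astype(float)
        mk = pd.DataFrame({"chrom": ["c"] * 8, "pos": range(1, 9)})
        dip = gt.DiploidizedMatrix(mk, [f"i{j}" for j in range(n)], S)
        res = assoc.lmm_scan(dip, y, np.eye(n), O=O)
        for i in range(8):
            X = np.column_stack([np.ones(n), O, S[i]])
            b = np.linalg.lstsq(X, y, rcond=None)[0]
            assert res.table["stat"][i] == pytest.approx(b[2], abs=1e-8)

    def test_null_fit_covariate_effect_matches_ols_under_identity(self):
        rng = np.random.default_rng(9)
        n = 60
        y, O = rng.normal(size=n), rng.normal(size=n)
        vc = assoc.lmm_null_fit(y, np.eye(n), O=O)
        X = np.column_stack([np.ones(n), O])
        b = np.linalg.lstsq(X, y, rcond=None)[0]
        assert vc.beta[1] == pytest.approx(b[1], abs=1e-8)

    def test_null_covariate_t_statistic_small(self):
        tvals = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 80
            y, O = rng.normal(size=n), rng.normal(size=n)
            vc = assoc.lmm_null_fit(y, np.eye(n), O=O)
            tvals.append(abs(vc.beta[1] / vc.beta_se[1]))
        assert np.mean(np.array(tvals) < 2) >= 0.8

    def test_constant_marker_skipped(self, small_pop):
        dip, _ = filtered_diploidized(small_pop)
        y = small_pop.phenotypes["latent"].to_numpy()
        K = rel.grm(dip)
        g2 = dip.geno.copy()
        g2[0] = 1.0
        dip2 = gt.DiploidizedMatrix(dip.markers, dip.individuals, g2)
        res = assoc.lmm_scan(dip2, y, K)
        pos0 = dip.markers["pos"].iloc[0]
        assert pos0 not in list(res.table[res.table["chrom"] == dip.markers["chrom"].iloc[0]]["pos"])

    def test_p3d_close_to_exact_per_marker_reml(self):
        cross = sim.random_cross(n_progeny=80, n_markers_per_chrom=50, seed=42)
        pop = sim.simulate_population(cross, pheno_model=sim.PhenoModel(seed=1))
        y = pop.phenotypes["latent"].to_numpy()
        dip, _ = filtered_diploidized(pop)
        K = rel.grm(dip)
        O = pop.dosage[cross.marker_index(*cross.sex_locus)].astype(float)
        sub = gt.DiploidizedMatrix(
            dip.markers.iloc[:50].reset_index(drop=True), dip.individuals, dip.geno[:50]
        )
        p3d = assoc.lmm_scan(sub, y, K, O=O, method="p3d")
        exact = assoc.lmm_scan(sub, y, K, O=O, method="exact")
        m = p3d.table.merge(exact.table, on=["chrom", "pos"], suffixes=("_a", "_b"))
        assert len(m) >= 20
        assert (m["neglog10p_a"] - m["neglog10p_b"]).abs().max() < 0.2

    def test_variance_recovery_with_covariate(self):
        errs = []
        for seed in range(6):
            cross = sim.random_cross(n_progeny=300, n_markers_per_chrom=300,
                                     sex_locus=None, seed=600 + seed)
            pop = sim.simulate_population(
                cross,
                pheno_model=sim.PhenoModel(beta_ogi=0, h2_poly=0.4, noise_sd=1.0, seed=seed),
            )
            dip, _ = filtered_diploidized(pop)
            K = rel.grm(dip)
            vc = assoc.lmm_null_fit(pop.phenotypes["latent"].to_numpy(), K)
            true_sg2 = 1.0 * 0.4 / 0.6  # noise_sd^2 * h2/(1-h2)
            errs.append(vc.sigma_g2 / true_sg2)
        assert 0.5 < np.mean(errs) < 1.5


class TestGroupAndRegression:
    def test_duplex_exceeds_simplex_by_construction(self):
        hits = 0
        for seed in range(10):
            cross = sim.random_cross(n_progeny=120, n_markers_per_chrom=30, seed=800 + seed)
            pop = sim.simulate_population(
                cross, pheno_model=sim.PhenoModel(beta_ogi=1.5, h2_poly=0, noise_sd=0.4,
                                                  intercept=0.0, seed=seed),
            )
            O = pop.dosage[cross.marker_index(*cross.sex_locus)].astype(float)
            out = assoc.dosage_group_test(pop.phenotypes["rate_cumulative"].to_numpy(), O)
            hits += out["means"][1] > out["means"][0]
        assert hits >= 9

    def test_permutation_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=60)
        O = np.array([1] * 30 + [2] * 30, dtype=float)
        ps = []
        for _ in range(300):
            ps.append(assoc.dosage_group_test(rng.permutation(y), O)["p"])
        frac = np.mean(np.array(ps) < 0.05)
        assert 0.01 <= frac <= 0.12

    def test_degenerate_groups_flagged(self):
        y = np.array([1.0] * 10 + [1.0] * 10)
        O = np.array([1] * 10 + [2] * 10, dtype=float)
        out = assoc.dosage_group_test(y, O)
        assert out["degenerate"]

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            assoc.dosage_group_test(np.arange(5.0), np.array([1, 1, 1, 1, 2.0]))

    def test_r2_exact_fit(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(50, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 3
        assert assoc.multi_locus_r2(y, X)["r2"] == pytest.approx(1.0)

    def test_r2_null_expectation(self):
        # E[r2] = k/(n-1) for k independent predictors under the null
        rng = np.random.default_rng(12)
        n, k = 83, 4
        r2s = [assoc.multi_locus_r2(rng.normal(size=n), rng.normal(size=(n, k)))["r2"]
               for _ in range(300)]
        assert np.mean(r2s) == pytest.approx(k / (n - 1), abs=0.015)

    def test_adding_covariate_never_decreases_r2(self):
        rng = np.random.default_rng(13)
        n = 60
        X = rng.normal(size=(n, 3))
        O = rng.normal(size=n)
        y = X[:, 0] + 0.5 * O + rng.normal(size=n)
        base = assoc.multi_locus_r2(y, X)["r2"]
        comp = assoc.multi_locus_r2(y, X, O=O, compensate=True)["r2"]
        assert comp >= base - 1e-12

    def test_too_many_predictors_rejected(self):
        rng = np.random.default_rng(14)
        with pytest.raises(ValueError):
            assoc.multi_locus_r2(rng.normal(size=30), rng.normal(size=(30, 11)))

    def test_rank_deficiency_flagged(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(40, 2))
        X = np.column_stack([X, X[:, 0]])
        out = assoc.multi_locus_r2(rng.normal(size=40), X)
        assert out["rank_deficient"]
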