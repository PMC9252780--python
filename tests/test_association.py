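"""Nested-model association tests against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from pcphewas import (
    CovariateSet,
    GeneAssociation,
    PhenotypeDefinition,
    SimulationConfig,
    compute_gene_pcs,
    f_statistic,
    run_phewas,
    simulate_genotypes,
    simulate_phenotype,
)
from pcphewas.association import test_gene_binary as binary_test
from pcphewas.association import test_gene_continuous as continuous_test


def make_inputs(seed, n=300, k=2, binary=False, signal=0.0):
    """Scores, phenotype and covariates with an optional PC1 signal."""
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"S{i}" for i in range(n)], name="sample_id")
    scores = pd.DataFrame(rng.standard_normal((n, k)),
                          index=idx, columns=[f"PC{j+1}" for j in range(k)])
    cov = CovariateSet(pd.DataFrame(
        {"age": rng.normal(55, 8, n), "sex": rng.integers(0, 2, n).astype(float)},
        index=idx))
    lin = 0.01 * cov.data["age"] + signal * scores["PC1"]
    if binary:
        prob = 1 / (1 + np.exp(-(lin - lin.mean())))
        y = (rng.random(n) < prob).astype(float)
        pheno = PhenotypeDefinition("d", "binary", pd.Series(y, index=idx))
    else:
        y = lin + rng.standard_normal(n)
        pheno = PhenotypeDefinition("y", "continuous", pd.Series(y, index=idx))
    return scores, pheno, cov


class TestFStatistic:
    def test_no_improvement_gives_zero(self):
        F, df1, df2 = f_statistic(50, 50, 3, 8, 108)
        assert (F, df1, df2) == (0.0, 5, 100)

    def test_direct_arithmetic(self):
        F, df1, df2 = f_statistic(100, 50, 3, 8, 108)
        assert F == pytest.approx(20.0)
        assert (df1, df2) == (5, 100)

    def test_perfect_fit_is_infinite(self):
        F, _, _ = f_statistic(10, 0, 1, 3, 50)
        assert math.isinf(F)

    def test_saturated_model_rejected(self):
        with pytest.raises(ValueError, match="saturated"):
            f_statistic(10, 5, 2, 50, 50)

    def test_matches_normal_equations_oracle(self):
        """Fit both nested models from scratch by the normal equations."""
        rng = np.random.default_rng(4)
        n, p_cov, k = 120, 3, 4
        X0 = np.column_stack([np.ones(n), rng.standard_normal((n, p_cov))])
        X1 = np.column_stack([X0, rng.standard_normal((n, k))])
        y = rng.standard_normal(n)

        def rss(X):
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            r = y - X @ beta
            return float(r @ r)

        rss1, rss2 = rss(X0), rss(X1)
        F, df1, df2 = f_statistic(rss1, rss2, X0.shape[1], X1.shape[1], n)
        F_oracle = ((rss1 - rss2) / k) / (rss2 / (n - X1.shape[1]))
        assert F == pytest.approx(F_oracle, rel=1e-10)
        assert (df1, df2) == (k, n - X1.shape[1])


class TestContinuous:
    def test_k1_equals_squared_t(self):
        """With one PC, the F-test p equals the coefficient's t-test p."""
        scores, pheno, cov = make_inputs(8, k=1, signal=0.2)
        res = continuous_test(scores, pheno, cov)
        X = np.column_stack([np.ones(len(scores)), cov.data.to_numpy(),
                             scores.to_numpy()])
        fit = sm.OLS(pheno.values.to_numpy(), X).fit()
        assert res.statistic == pytest.approx(fit.tvalues[-1] ** 2, rel=1e-8)
        assert res.p == pytest.approx(fit.pvalues[-1], rel=1e-8)

    def test_perfect_signal(self):
        scores, pheno, cov = make_inputs(3, k=2)
        exact = PhenotypeDefinition(
            "exact", "continuous", 2.0 * scores["PC1"])
        res = continuous_test(scores, exact, cov)
        assert res.p < 1e-100 or math.isinf(res.statistic)

    def test_null_pvalues_uniform(self):
        """Under the global null the F-test p-values are Uniform(0,1)."""
        pvals = []
        rng = np.random.default_rng(100)
        scores, _, cov = make_inputs(0, n=150, k=2)
        idx = scores.index
        for _ in range(400):
            y = pd.Series(rng.standard_normal(len(idx)), index=idx)
            pheno = PhenotypeDefinition("y", "continuous", y)
            pvals.append(continuous_test(scores, pheno, cov).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_collinear_design_reported(self):
        scores, pheno, cov = make_inputs(5, k=1)
        cov2 = CovariateSet(cov.data.assign(age2=cov.data["age"] * 2.0))
        with pytest.raises(ValueError, match="collinear.*age2"):
            continuous_test(scores, pheno, cov2)

    def test_monotone_rss_with_noise_pcs(self):
        """Adding pure-noise PCs cannot worsen the full-model fit."""
        rng = np.random.default_rng(12)
        scores, pheno, cov = make_inputs(6, k=1, signal=0.3)
        wide = scores.assign(PC2=rng.standard_normal(len(scores)))
        res1 = continuous_test(scores, pheno, cov)
        res2 = continuous_test(wide, pheno, cov)
        assert math.isfinite(res2.statistic) and res2.statistic >= 0
        assert res2.df1 == 2 and res1.df1 == 1


class TestBinary:
    def test_deviance_equals_twice_loglik_gain(self):
        """Likelihood oracle: statistic = 2 (ll_full - ll_null) with the
        Bernoulli log-likelihood evaluated directly."""
        scores, pheno, cov = make_inputs(9, n=400, k=2, binary=True,
                                         signal=0.4)
        res = binary_test(scores, pheno, cov)
        y = pheno.values.to_numpy()
        X0 = np.column_stack([np.ones(len(y)), cov.data.to_numpy()])
        X1 = np.column_stack([X0, scores.to_numpy()])

        def loglik(X):
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            mu = fit.fittedvalues
            return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))

        oracle = 2.0 * (loglik(X1) - loglik(X0))
        assert res.statistic == pytest.approx(oracle, abs=1e-8)

    def test_null_statistic_near_chi2_mean(self):
        rng = np.random.default_rng(44)
        scores, _, cov = make_inputs(1, n=300, k=3)
        idx = scores.index
        stats_ = []
        for _ in range(150):
            y = pd.Series((rng.random(len(idx)) < 0.3).astype(float),
                          index=idx)
            pheno = PhenotypeDefinition("d", "binary", y)
            stats_.append(binary_test(scores, pheno, cov).statistic)
        # mean of chi2_3 is 3; allow Monte-Carlo spread
        assert np.mean(stats_) == pytest.approx(3.0, abs=0.6)

    def test_single_class_rejected(self):
        scores, _, cov = make_inputs(2, n=100, k=1)
        values = pd.Series(np.zeros(100), index=scores.index)
        values.iloc[0] = 1.0  # pass construction, then drop the lone case
        pheno = PhenotypeDefinition("d", "binary", values)
        pheno.values.iloc[0] = np.nan
        with pytest.raises(ValueError, match="degenerate"):
            binary_test(scores, pheno, cov)

    def test_separation_flagged(self):
        scores, _, cov = make_inputs(7, n=200, k=1)
        y = (scores["PC1"] > 0).astype(float)
        pheno = PhenotypeDefinition("d", "binary", y)
        res = binary_test(scores, pheno, cov)
        assert not res.converged
        assert math.isnan(res.p)


class TestPhewasScan:
    def _study(self, seed=31, n=400):
        cfg = SimulationConfig(seed=seed, n_samples=n, n_variants=10,
                               ld_rho=0.3, heritability=0.3)
        dm = simulate_genotypes(cfg)
        pcs = compute_gene_pcs(dm, gene_id="G1")
        pheno, cov, truth = simulate_phenotype(dm, cfg, "continuous")
        return dm, pcs, pheno, cov

    def test_cardinality(self):
        dm, pcs, pheno, cov = self._study()
        pcs2 = compute_gene_pcs(dm.take_variants(np.arange(5)), gene_id="G2")
        others = [
            PhenotypeDefinition(f"p{i}", "continuous", pheno.values * 0.0
                                + np.random.default_rng(i).standard_normal(
                                    len(pheno.values)))
            for i in range(2)
        ]
        results = run_phewas([pcs, pcs2], [pheno] + others, cov)
        assert len(results) == 6

    def test_planted_signal_has_smallest_p(self):
        cfg = SimulationConfig(seed=77, n_samples=600, n_variants=10,
                               ld_rho=0.3, heritability=0.4)
        dm = simulate_genotypes(cfg)
        causal_pcs = compute_gene_pcs(dm, gene_id="causal")
        pheno, cov, _ = simulate_phenotype(dm, cfg, "continuous")
        null_dm = simulate_genotypes(SimulationConfig(
            seed=78, n_samples=600, n_variants=10, ld_rho=0.3))
        null_dm = type(null_dm)(dm.sample_ids, null_dm.variants,
                                null_dm.dosages)
        null_pcs = compute_gene_pcs(null_dm, gene_id="null_gene")
        results = run_phewas([causal_pcs, null_pcs], [pheno], cov)
        best = min(results, key=lambda r: r.p)
        assert best.gene_id == "causal"

    def test_sex_strata_drop_sex_and_filter(self):
        dm, pcs, pheno, cov = self._study()
        combined = run_phewas([pcs], [pheno], cov, sex_stratum="combined")
        female = run_phewas([pcs], [pheno], cov, sex_stratum="female")
        n_female = int((cov.data["sex"] == 0).sum())
        assert female[0].n == n_female
        assert female[0].stratum == "female"
        assert combined[0].n == dm.n_samples

    def test_binary_min_case_skip(self, caplog):
        dm, pcs, _, cov = self._study()
        y = pd.Series(np.zeros(dm.n_samples), index=cov.data.index)
        y.iloc[:10] = 1.0  # 10 cases < default 50
        rare = PhenotypeDefinition("rare", "binary", y)
        with caplog.at_level("INFO"):
            results = run_phewas([pcs], [rare], cov)
        assert results == []

    def test_power_increases_with_effect_size(self):
        """Power ordering at three planted heritabilities."""
        rejections = []
        for h2 in (0.005, 0.05, 0.3):
            hits = 0
            for rep in range(30):
                cfg = SimulationConfig(
                    seed=1000 + rep, n_samples=250, n_variants=6,
                    ld_rho=0.2, heritability=h2)
                dm = simulate_genotypes(cfg)
                pcs = compute_gene_pcs(dm)
                pheno, cov, _ = simulate_phenotype(dm, cfg, "continuous")
                res = GeneAssociation.from_gene_pcs(pcs, pheno, cov).fit()
                hits += res.p < 0.05
            rejections.append(hits)
        assert rejections[0] <= rejections[1] <= rejections[2]
        assert rejections[2] > rejections[0]
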