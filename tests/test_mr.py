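"""IVW estimator, relevance filtering and cis-MR scenario recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pcphewas import (
    CisMR,
    InstrumentEffect,
    SimulationConfig,
    compute_gene_pcs,
    filter_relevance,
    instrument_effects,
    ivw,
    run_cis_mr,
    simulate_mr_scenario,
)


def eff(pc, bx, by, sx=0.1, sy=0.1, px=0.001, py=0.5):
    return InstrumentEffect(pc, bx, sx, px, by, sy, py)


class TestIVW:
    def test_single_instrument_is_wald_ratio(self):
        beta, _, _ = ivw([eff(1, 0.5, 0.25)])
        assert beta == pytest.approx(0.5)

    def test_two_equal_precision_instruments(self):
        beta, _, _ = ivw([eff(1, 1.0, 0.2), eff(2, 1.0, 0.4)])
        assert beta == pytest.approx(0.3)

    def test_matches_weighted_through_origin_regression(self):
        """Oracle: WLS slope of beta_y on beta_x with weights se_y^-2."""
        rng = np.random.default_rng(3)
        effects = [
            eff(i + 1, float(rng.normal(0.5, 0.2)), float(rng.normal(0.2, 0.1)),
                sy=float(rng.uniform(0.05, 0.3)))
            for i in range(6)
        ]
        bx = np.array([e.beta_x for e in effects])
        by = np.array([e.beta_y for e in effects])
        w = np.array([e.se_y for e in effects]) ** -2
        slope = np.sum(w * bx * by) / np.sum(w * bx * bx)
        beta, se, p = ivw(effects)
        assert beta == pytest.approx(slope, rel=1e-12)
        assert se == pytest.approx(np.sum(w * bx * bx) ** -0.5, rel=1e-12)

    def test_precision_weighted_wald_mean_identity(self):
        """IVW = mean of Wald ratios weighted by beta_x^2 / se_y^2."""
        effects = [eff(1, 0.8, 0.3, sy=0.1), eff(2, 0.4, -0.1, sy=0.2),
                   eff(3, 1.2, 0.5, sy=0.15)]
        w = np.array([e.beta_x**2 / e.se_y**2 for e in effects])
        wald = np.array([e.wald_ratio for e in effects])
        beta, _, _ = ivw(effects)
        assert beta == pytest.approx(np.sum(w * wald) / np.sum(w), rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ivw([])


class TestRelevanceFilter:
    def test_threshold_partition(self):
        effects = [eff(1, 0.5, 0.1, px=0.04), eff(2, 0.5, 0.1, px=0.2)]
        kept, excluded = filter_relevance(effects)
        assert [e.pc_index for e in kept] == [1]
        assert excluded == [2]

    def test_exact_threshold_is_kept(self):
        kept, excluded = filter_relevance([eff(1, 0.5, 0.1, px=0.05)])
        assert len(kept) == 1 and excluded == []

    def test_no_relevant_instruments_raises(self):
        with pytest.raises(ValueError, match="no relevant instruments"):
            filter_relevance([eff(1, 0.5, 0.1, px=0.9)])


class TestInstrumentEffects:
    def _setup(self, seed=1, n=4000):
        scen = simulate_mr_scenario(SimulationConfig(
            seed=seed, n_samples=n, n_variants=6, ld_rho=0.0,
            first_stage_h2=0.15, causal_beta=0.5))
        pcs = compute_gene_pcs(scen.dosages, gene_id="G")
        scores = pd.DataFrame(
            pcs.scores, index=pd.Index(pcs.sample_ids, name="sample_id"),
            columns=[f"PC{i+1}" for i in range(pcs.k)])
        return scen, scores

    def test_cardinality_and_planted_first_stage(self):
        scen, scores = self._setup()
        effects = instrument_effects(scores, scen.exposure, scen.outcome,
                                     scen.covariates)
        assert len(effects) == scores.shape[1]
        # construct an exposure that is exactly 0.5 * PC1 + noise
        rng = np.random.default_rng(0)
        expo = scen.exposure
        vals = 0.5 * scores["PC1"] + rng.standard_normal(len(scores))
        expo2 = type(expo)("e2", "continuous", vals)
        effects2 = instrument_effects(scores, expo2, scen.outcome,
                                      scen.covariates)
        e1 = effects2[0]
        assert abs(e1.beta_x - 0.5) < 2.58 * e1.se_x

    def test_null_pc_p_uniform(self):
        """PCs with no exposure effect give uniform first-stage p-values."""
        rng = np.random.default_rng(5)
        pvals = []
        scen, scores = self._setup(seed=2, n=800)
        for rep in range(200):
            vals = pd.Series(rng.standard_normal(len(scores)),
                             index=scores.index)
            expo = type(scen.exposure)("e", "continuous", vals)
            effects = instrument_effects(scores[["PC1"]], expo, scen.outcome,
                                         scen.covariates)
            pvals.append(effects[0].p_x)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestCisMR:
    def test_recovers_causal_effect(self):
        scen = simulate_mr_scenario(SimulationConfig(
            seed=11, n_samples=5000, n_variants=3, ld_rho=0.0,
            first_stage_h2=0.2, causal_beta=0.5))
        pcs = compute_gene_pcs(scen.dosages, gene_id="G")
        res = run_cis_mr(pcs, scen.exposure, scen.outcome, scen.covariates)
        lo, hi = res.conf_int()
        assert lo <= 0.5 <= hi
        assert res.gene_exposure_p < 1e-10
        assert res.n_instruments_used + len(res.excluded_pcs) == \
            res.n_instruments_total

    def test_binary_outcome_sign(self):
        scen = simulate_mr_scenario(
            SimulationConfig(seed=13, n_samples=6000, n_variants=3,
                             ld_rho=0.0, first_stage_h2=0.2,
                             causal_beta=0.7, prevalence=0.3),
            binary_outcome=True)
        pcs = compute_gene_pcs(scen.dosages, gene_id="G")
        res = run_cis_mr(pcs, scen.exposure, scen.outcome, scen.covariates)
        assert res.beta_ivw > 0
        assert res.p_ivw < 0.01

    def test_scale_equivariance_and_sign_antisymmetry(self):
        scen = simulate_mr_scenario(SimulationConfig(
            seed=17, n_samples=3000, n_variants=4, ld_rho=0.0,
            first_stage_h2=0.15, causal_beta=0.4))
        pcs = compute_gene_pcs(scen.dosages, gene_id="G")
        base = run_cis_mr(pcs, scen.exposure, scen.outcome, scen.covariates)
        scaled = type(scen.exposure)(
            "e", "continuous", scen.exposure.values * 2.0)
        res2 = run_cis_mr(pcs, scaled, scen.outcome, scen.covariates)
        assert res2.beta_ivw == pytest.approx(base.beta_ivw / 2.0, rel=1e-6)
        negated = type(scen.exposure)(
            "e", "continuous", -scen.exposure.values)
        res3 = run_cis_mr(pcs, negated, scen.outcome, scen.covariates)
        assert res3.beta_ivw == pytest.approx(-base.beta_ivw, rel=1e-6)

    def test_pleiotropy_increases_bias(self):
        """Exclusion-restriction violation: bias grows with the direct
        variant -> outcome path."""
        biases = []
        for pleio in (0.0, 0.3, 0.9):
            est = []
            for rep in range(10):
                scen = simulate_mr_scenario(SimulationConfig(
                    seed=500 + rep, n_samples=2000, n_variants=3,
                    ld_rho=0.0, first_stage_h2=0.2, causal_beta=0.5,
                    pleiotropy=pleio))
                pcs = compute_gene_pcs(scen.dosages, gene_id="G")
                res = run_cis_mr(pcs, scen.exposure, scen.outcome,
                                 scen.covariates)
                est.append(res.beta_ivw)
            biases.append(abs(np.mean(est) - 0.5))
        assert biases[0] < biases[2]
        assert biases[1] < biases[2]

    def test_summary_mentions_instrument_counts(self):
        scen = simulate_mr_scenario(SimulationConfig(
            seed=19, n_samples=2000, n_variants=3, ld_rho=0.0,
            first_stage_h2=0.2, causal_beta=0.5))
        pcs = compute_gene_pcs(scen.dosages, gene_id="G")
        res = CisMR(pcs, scen.exposure, scen.outcome, scen.covariates).fit()
        text = res.summary()
        assert "beta_IVW" in text and "instruments" in text
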