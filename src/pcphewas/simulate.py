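"""Synthetic data with known ground truth for every pipeline stage.

Genotypes are simulated from a latent-Gaussian AR(1) haplotype model: each
haplotype is a thresholded stationary Gaussian autoregressive process, so
adjacent variants are correlated (one interpretable LD knob, ``ld_rho``)
without the cost of a coalescent simulation.  Dosages are the sum of two
haplotypes; an optional imputation-noise step shrinks dosages toward their
expectation, which defines a synthetic info score (the ratio of the
empirical dosage variance to the binomial expectation 2 maf (1 - maf)).

Phenotypes are generated with controlled heritability (continuous),
prevalence (binary, via liability thresholding), and covariate confounding.
MR scenarios wire variants -> exposure -> outcome with a known causal
effect and an optional direct-pleiotropy knob for assumption-violation
studies.  Every generator is bit-reproducible given its seed and returns
its ground truth explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import CovariateSet, PhenotypeDefinition
from .genotypes import DosageMatrix, KinshipPair, VariantRecord


@dataclass
class SimulationConfig:
    """Knobs for the synthetic generators (seed is mandatory)."""

    seed: int
    n_samples: int = 1000
    n_variants: int = 20
    maf_min: float = 0.01
    maf_max: float = 0.5
    ld_rho: float = 0.4            # adjacent-haplotype latent correlation
    heritability: float = 0.1      # fraction of phenotypic variance, genetic
    prevalence: float = 0.1        # binary phenotypes
    n_causal: int = 3
    causal_beta: float = 0.5       # MR: causal effect of exposure on outcome
    first_stage_h2: float = 0.1    # MR: variance of exposure from variants
    pleiotropy: float = 0.0        # MR: direct variant -> outcome effect scale
    dosage_noise: float = 0.0      # in [0, 1): imputation-style shrinkage scale
    missing_rate: float = 0.0      # fraction of entries set missing
    covariate_confounding: float = 0.0  # covariate effect scale on phenotypes

    def __post_init__(self) -> None:
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0 <= self.heritability < 1:
            raise ValueError("heritability must be in [0, 1)")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0 <= self.dosage_noise < 1:
            raise ValueError("dosage_noise must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:06d}" for i in range(1, n + 1)]


def _simulate_haplotypes(
    rng: np.random.Generator, n_hap: int, mafs: np.ndarray, rho: float
) -> np.ndarray:
    """Thresholded latent Gaussian AR(1) haplotypes (n_hap x m in {0, 1})."""
    m = mafs.size
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        eps = rng.standard_normal((n_hap, m - 1))
        scale = np.sqrt(1.0 - rho ** 2)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + scale * eps[:, j - 1]
    thresholds = stats.norm.ppf(mafs)
    return (z < thresholds).astype(float)


def simulate_genotypes(config: SimulationConfig) -> DosageMatrix:
    """LD-structured diploid dosages with per-variant MAF/info metadata."""
    rng = np.random.default_rng(config.seed)
    m, n = config.n_variants, config.n_samples
    mafs = rng.uniform(config.maf_min, config.maf_max, size=m)
    h1 = _simulate_haplotypes(rng, n, mafs, config.ld_rho)
    h2 = _simulate_haplotypes(rng, n, mafs, config.ld_rho)
    dosages = h1 + h2

    if config.dosage_noise > 0:
        # shrink toward the expectation 2*maf, emulating imputation; the
        # per-variant shrinkage factor lam gives info ~ lam^2
        lam = rng.uniform(1.0 - config.dosage_noise, 1.0, size=m)
        dosages = 2 * mafs + lam * (dosages - 2 * mafs)
        dosages = np.clip(dosages, 0.0, 2.0)

    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages = np.where(mask, np.nan, dosages)

    variants = []
    for j in range(m):
        col = dosages[:, j]
        obs = col[~np.isnan(col)]
        af = float(obs.mean() / 2) if obs.size else 0.0
        maf = min(af, 1.0 - af)
        expected_var = 2 * maf * (1 - maf)
        info = float(np.clip(obs.var() / expected_var, 0.0, 1.0)) \
            if expected_var > 0 and obs.size else 0.0
        variants.append(VariantRecord(
            variant_id=f"var{j + 1}", chrom="1", pos=10_000 + 100 * j,
            ref="A", alt="G", maf=maf, info=info,
            missing_rate=float(np.isnan(col).mean()),
        ))
    return DosageMatrix(_sample_ids(n), variants, dosages)


def _covariates(rng: np.random.Generator, index: pd.Index) -> pd.DataFrame:
    n = len(index)
    return pd.DataFrame(
        {
            "age": rng.normal(55.0, 8.0, size=n),
            "sex": rng.integers(0, 2, size=n).astype(float),
        },
        index=index,
    )


def simulate_phenotype(
    dm: DosageMatrix,
    config: SimulationConfig,
    kind: str = "continuous",
    name: str | None = None,
) -> tuple[PhenotypeDefinition, CovariateSet, dict]:
    """Phenotype with target heritability (continuous) or prevalence (binary).

    Continuous: y = covariate effects + genetic value + Gaussian noise, with
    the noise scaled so the genetic value explains ``heritability`` of the
    non-covariate variance.  Binary: the same liability is thresholded at
    the (1 - prevalence) quantile.  Returns the phenotype, a CovariateSet
    (age- and sex-like columns, confounded when configured) and the ground
    truth (causal variant indices and effects).
    """
    rng = np.random.default_rng(config.seed + 1)
    index = pd.Index(dm.sample_ids, name="sample_id")
    cov = _covariates(rng, index)
    n = dm.n_samples

    X = np.nan_to_num(dm.dosages, nan=0.0)
    n_causal = min(config.n_causal, dm.n_variants)
    causal_idx = rng.choice(dm.n_variants, size=n_causal, replace=False)
    betas = rng.normal(0.0, 1.0, size=n_causal)
    g = X[:, causal_idx] @ betas if config.heritability > 0 else np.zeros(n)

    h2 = config.heritability
    var_g = g.var()
    if h2 > 0 and var_g > 0:
        noise_sd = np.sqrt(var_g * (1 - h2) / h2)
    else:
        g = np.zeros(n)
        noise_sd = 1.0
    c = config.covariate_confounding
    cov_effect = c * ((cov["age"].to_numpy() - 55.0) / 8.0
                      + cov["sex"].to_numpy())
    liability = g + noise_sd * rng.standard_normal(n)

    truth = {
        "causal_idx": causal_idx.tolist(),
        "betas": betas.tolist(),
        "heritability": h2,
        "kind": kind,
    }
    if kind == "continuous":
        values = liability + cov_effect
    elif kind == "binary":
        total = liability + cov_effect
        thresh = np.quantile(total, 1.0 - config.prevalence)
        values = (total >= thresh).astype(float)
        truth["prevalence"] = config.prevalence
    else:
        raise ValueError(f"unknown phenotype kind {kind!r}")

    pheno = PhenotypeDefinition(
        name=name or f"sim_{kind}", kind=kind,
        values=pd.Series(values, index=index),
    )
    return pheno, CovariateSet(cov), truth


@dataclass
class MRScenario:
    """A simulated gene -> exposure -> outcome causal chain."""

    dosages: DosageMatrix
    exposure: PhenotypeDefinition
    outcome: PhenotypeDefinition
    covariates: CovariateSet
    true_beta: float
    first_stage_betas: np.ndarray = field(repr=False)


def simulate_mr_scenario(
    config: SimulationConfig, binary_outcome: bool = False
) -> MRScenario:
    """Valid-instrument MR scenario with known causal effect.

    Variants drive the exposure with total first-stage variance
    ``first_stage_h2``; the outcome is causal_beta x exposure plus
    independent noise (continuous) or a logistic draw on that linear
    predictor (binary).  A nonzero ``pleiotropy`` adds a direct
    variant -> outcome path, violating the exclusion assumption.
    """
    dm = simulate_genotypes(config)
    rng = np.random.default_rng(config.seed + 2)
    index = pd.Index(dm.sample_ids, name="sample_id")
    cov = _covariates(rng, index)
    n = dm.n_samples

    X = np.nan_to_num(dm.dosages, nan=0.0)
    gammas = rng.normal(0.0, 1.0, size=dm.n_variants)
    gx = X @ gammas
    var_gx = gx.var()
    h2 = config.first_stage_h2
    noise_sd = np.sqrt(var_gx * (1 - h2) / h2) if var_gx > 0 else 1.0
    exposure = gx + noise_sd * rng.standard_normal(n)
    exposure = (exposure - exposure.mean()) / exposure.std()

    linear = config.causal_beta * exposure
    if config.pleiotropy > 0:
        direct = X @ rng.normal(0.0, config.pleiotropy, size=dm.n_variants)
        linear = linear + direct
    if binary_outcome:
        logit = linear + np.log(config.prevalence / (1 - config.prevalence))
        prob = 1.0 / (1.0 + np.exp(-logit))
        outcome_values = (rng.random(n) < prob).astype(float)
        okind = "binary"
    else:
        outcome_values = linear + rng.standard_normal(n)
        okind = "continuous"

    return MRScenario(
        dosages=dm,
        exposure=PhenotypeDefinition(
            "exposure", "continuous", pd.Series(exposure, index=index)),
        outcome=PhenotypeDefinition(
            "outcome", okind, pd.Series(outcome_values, index=index)),
        covariates=CovariateSet(cov),
        true_beta=config.causal_beta,
        first_stage_betas=gammas,
    )


def simulate_pvalue_mixture(
    m_tests: int, frac_nonnull: float, effect_shift: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two-group p-value mixture with truth labels.

    Null p-values are Uniform(0, 1]; non-null p-values are two-sided normal
    tail probabilities of draws from Normal(effect_shift, 1).  Returns
    (p, is_nonnull).
    """
    if not 0 <= frac_nonnull <= 1:
        raise ValueError("frac_nonnull must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_nonnull = int(round(m_tests * frac_nonnull))
    n_null = m_tests - n_nonnull
    p_null = 1.0 - rng.random(n_null)          # Uniform(0, 1]
    z = rng.normal(effect_shift, 1.0, size=n_nonnull)
    p_alt = 2.0 * stats.norm.sf(np.abs(z))
    p = np.concatenate([p_null, np.maximum(p_alt, np.nextafter(0, 1))])
    labels = np.concatenate([np.zeros(n_null, bool), np.ones(n_nonnull, bool)])
    perm = rng.permutation(m_tests)
    return p[perm], labels[perm]


def simulate_kinship_pairs(
    sample_ids: list[str],
    n_related: int,
    seed: int,
    coefficient: float = 0.25,
    n_unrelated_pairs: int = 0,
) -> list[KinshipPair]:
    """Disjoint related pairs at a given kinship, plus background pairs
    below the third-degree cutoff."""
    rng = np.random.default_rng(seed)
    ids = list(sample_ids)
    if 2 * n_related > len(ids):
        raise ValueError("not enough samples for the requested related pairs")
    chosen = rng.choice(len(ids), size=2 * n_related, replace=False)
    pairs = [
        KinshipPair(ids[chosen[2 * i]], ids[chosen[2 * i + 1]], coefficient)
        for i in range(n_related)
    ]
    for _ in range(n_unrelated_pairs):
        i, j = rng.choice(len(ids), size=2, replace=False)
        pairs.append(KinshipPair(ids[i], ids[j],
                                 float(rng.uniform(0.0, 0.04))))
    return pairs
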