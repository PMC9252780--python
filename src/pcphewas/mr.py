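"""cis-Mendelian randomization with gene PCs as instruments.

The causal effect of an exposure X on an outcome Y is estimated using a
gene's principal components as instrumental variables.  For each PC k a
covariate-adjusted marginal regression gives its effect on the exposure
(beta_Xk) and on the outcome (beta_Yk; log-odds scale for binary outcomes).
PCs not associated with the exposure (P > 0.05) are removed to satisfy the
relevance assumption, and the remaining per-instrument estimates are
combined with the inverse-variance-weighted (IVW) estimator

    beta_IVW = sum_k beta_Xk beta_Yk se(beta_Yk)^-2
             / sum_k beta_Xk^2 se(beta_Yk)^-2,

a precision-weighted mean of per-instrument Wald ratios in the style of a
fixed-effect meta-analysis, with se_IVW = (sum_k beta_Xk^2 se(beta_Yk)^-2)^-1/2.
First-stage uncertainty (se of beta_Xk) does not enter the estimator.

This is one-sample MR: exposure and outcome effects are estimated on the
same individuals, with no sample-overlap correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .association import CovariateSet, GeneAssociation, PhenotypeDefinition

DEFAULT_RELEVANCE_P_MAX = 0.05


@dataclass
class InstrumentEffect:
    """Per-PC effects on exposure and outcome from marginal regressions."""

    pc_index: int            # 1-based
    beta_x: float
    se_x: float
    p_x: float
    beta_y: float
    se_y: float
    p_y: float

    def __post_init__(self) -> None:
        if self.se_x <= 0 or self.se_y <= 0:
            raise ValueError(f"PC{self.pc_index}: standard errors must be > 0")

    @property
    def wald_ratio(self) -> float:
        return self.beta_y / self.beta_x


@dataclass
class MRResult:
    """IVW causal estimate with per-instrument detail."""

    gene_id: str
    exposure_name: str
    outcome_name: str
    beta_ivw: float
    se_ivw: float
    p_ivw: float
    n_instruments_total: int
    n_instruments_used: int
    excluded_pcs: list[int]
    instrument_effects: list[InstrumentEffect] = field(default_factory=list)
    gene_exposure_p: float | None = None

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        z = stats.norm.isf(alpha / 2)
        return self.beta_ivw - z * self.se_ivw, self.beta_ivw + z * self.se_ivw

    def to_dict(self) -> dict:
        lo, hi = self.conf_int()
        return {
            "gene": self.gene_id,
            "exposure": self.exposure_name,
            "outcome": self.outcome_name,
            "beta_ivw": self.beta_ivw,
            "se_ivw": self.se_ivw,
            "p_ivw": self.p_ivw,
            "ci_low": lo,
            "ci_high": hi,
            "n_instruments_total": self.n_instruments_total,
            "n_instruments_used": self.n_instruments_used,
            "excluded_pcs": list(self.excluded_pcs),
            "gene_exposure_p": self.gene_exposure_p,
            "instruments": [
                {
                    "pc": e.pc_index, "beta_x": e.beta_x, "se_x": e.se_x,
                    "p_x": e.p_x, "beta_y": e.beta_y, "se_y": e.se_y,
                    "p_y": e.p_y,
                    "included": e.pc_index not in set(self.excluded_pcs),
                }
                for e in self.instrument_effects
            ],
        }

    def scatter_data(self) -> pd.DataFrame:
        """(beta_x, beta_y) pairs with inclusion flags, for effect plots."""
        rows = self.to_dict()["instruments"]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            f"cis-MR (IVW): {self.exposure_name} -> {self.outcome_name} "
            f"via {self.gene_id} PCs",
            f"  beta_IVW    : {self.beta_ivw:.6g}  (se {self.se_ivw:.4g})",
            f"  95% CI      : [{lo:.6g}, {hi:.6g}]",
            f"  p-value     : {self.p_ivw:.4g}",
            f"  instruments : {self.n_instruments_used}/"
            f"{self.n_instruments_total} (excluded PCs: {self.excluded_pcs})",
        ]
        if self.gene_exposure_p is not None:
            lines.append(f"  gene-exposure association p: "
                         f"{self.gene_exposure_p:.4g}")
        return "\n".join(lines)


def _marginal_effect(
    y: np.ndarray, pc: np.ndarray, Xcov: np.ndarray, binary: bool
) -> tuple[float, float, float, bool]:
    """Effect of one PC on an outcome, adjusted for covariates."""
    X = np.column_stack([Xcov, pc])
    if binary:
        from .association import _fit_logistic

        fit, converged = _fit_logistic(y, X)
        if fit is None:
            return math.nan, 1.0, 1.0, False
    else:
        fit = sm.OLS(y, X).fit()
        converged = True
    beta = float(fit.params[-1])
    se = float(fit.bse[-1])
    p = float(fit.pvalues[-1])
    return beta, se, p, converged


def instrument_effects(
    scores: pd.DataFrame,
    exposure: PhenotypeDefinition,
    outcome: PhenotypeDefinition,
    covariates: CovariateSet,
) -> list[InstrumentEffect]:
    """Estimate each PC's marginal effect on exposure and outcome.

    The exposure must be continuous; the outcome may be continuous (linear
    regression) or binary (logistic regression; beta_y on the log-odds
    scale).  PCs whose outcome regression fails to converge are dropped.
    """
    if exposure.kind != "continuous":
        raise ValueError("the exposure must be continuous")
    scores = pd.DataFrame(scores, dtype=float)
    idx = scores.index.intersection(exposure.values.index)
    idx = idx.intersection(outcome.values.index)
    idx = idx.intersection(covariates.data.index)
    x = exposure.values.loc[idx]
    y = outcome.values.loc[idx]
    cov = covariates.data.loc[idx]
    ok = x.notna() & y.notna() & scores.loc[idx].notna().all(axis=1)
    if len(cov.columns):
        ok &= cov.notna().all(axis=1)
    idx = idx[ok]
    if len(idx) < len(covariates.columns) + 2:
        raise ValueError("too few complete cases for instrument regressions")
    binary = outcome.kind == "binary"
    if binary and outcome.values.loc[idx].nunique() < 2:
        raise ValueError("degenerate outcome: single class among complete cases")

    Xcov = covariates.design(idx).to_numpy(float)
    xv = exposure.values.loc[idx].to_numpy(float)
    yv = outcome.values.loc[idx].to_numpy(float)
    effects: list[InstrumentEffect] = []
    for j, col in enumerate(scores.columns, start=1):
        pc = scores.loc[idx, col].to_numpy(float)
        bx, sx, px, _ = _marginal_effect(xv, pc, Xcov, binary=False)
        by, sy, py, conv = _marginal_effect(yv, pc, Xcov, binary=binary)
        if not conv:
            continue  # non-converged outcome fit: PC excluded downstream
        effects.append(InstrumentEffect(j, bx, sx, px, by, sy, py))
    return effects


def filter_relevance(
    effects: list[InstrumentEffect],
    p_max: float = DEFAULT_RELEVANCE_P_MAX,
) -> tuple[list[InstrumentEffect], list[int]]:
    """Drop PCs not associated with the exposure (p_x > p_max).

    The removal is strict: a PC with p_x exactly at the threshold is kept.
    Raises if no instrument survives, since the IVW is then not estimable.
    """
    kept = [e for e in effects if e.p_x <= p_max]
    excluded = [e.pc_index for e in effects if e.p_x > p_max]
    if not kept:
        raise ValueError("no relevant instruments (all exposure p > "
                         f"{p_max})")
    return kept, excluded


def ivw(effects: list[InstrumentEffect]) -> tuple[float, float, float]:
    """Inverse-variance-weighted estimate over instruments.

    Returns (beta_ivw, se_ivw, p_ivw).  With a single instrument the
    estimator collapses to the Wald ratio beta_y / beta_x.
    """
    if not effects:
        raise ValueError("ivw requires at least one instrument")
    bx = np.array([e.beta_x for e in effects])
    by = np.array([e.beta_y for e in effects])
    w = np.array([e.se_y for e in effects]) ** -2.0
    denom = float((bx ** 2 * w).sum())
    if denom <= 0:
        raise ValueError("degenerate instruments: zero exposure effects")
    beta = float((bx * by * w).sum() / denom)
    se = denom ** -0.5
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return beta, se, max(p, np.nextafter(0, 1))


class CisMR:
    """cis-MR model: exposure -> outcome through one gene's PC instruments.

    ``fit()`` composes the per-PC instrument regressions, the relevance
    filter and the IVW estimator, and attaches the gene-vs-exposure
    association p-value as a relevance diagnostic.
    """

    def __init__(
        self,
        pcs,
        exposure: PhenotypeDefinition,
        outcome: PhenotypeDefinition,
        covariates: CovariateSet,
        p_max: float = DEFAULT_RELEVANCE_P_MAX,
    ) -> None:
        self.pcs = pcs
        self.exposure = exposure
        self.outcome = outcome
        self.covariates = covariates
        self.p_max = p_max

    def _scores(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pcs.scores,
            index=pd.Index(self.pcs.sample_ids, name="sample_id"),
            columns=[f"PC{i + 1}" for i in range(self.pcs.k)],
        )

    def fit(self) -> MRResult:
        scores = self._scores()
        effects = instrument_effects(scores, self.exposure, self.outcome,
                                     self.covariates)
        kept, excluded = filter_relevance(effects, self.p_max)
        beta, se, p = ivw(kept)
        gene_exposure_p = GeneAssociation(
            scores, self.exposure, self.covariates, gene_id=self.pcs.gene_id
        ).fit().p
        return MRResult(
            gene_id=self.pcs.gene_id,
            exposure_name=self.exposure.name,
            outcome_name=self.outcome.name,
            beta_ivw=beta, se_ivw=se, p_ivw=p,
            n_instruments_total=len(effects),
            n_instruments_used=len(kept),
            excluded_pcs=excluded,
            instrument_effects=effects,
            gene_exposure_p=gene_exposure_p,
        )


def run_cis_mr(
    gene,
    exposure: PhenotypeDefinition,
    outcome: PhenotypeDefinition,
    covariates: CovariateSet,
    p_max: float = DEFAULT_RELEVANCE_P_MAX,
) -> MRResult:
    """Functional wrapper around :class:`CisMR`."""
    return CisMR(gene, exposure, outcome, covariates, p_max).fit()
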