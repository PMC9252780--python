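"""Nested-model gene-based association tests.

A gene is tested against a phenotype by comparing a null model (outcome ~
covariates) with a full model that adds the gene's PC scores.  For
continuous outcomes the comparison is the F-test

    F = ((RSS1 - RSS2) / (|P2| - |P1|)) / (RSS2 / (n - |P2|)),

which follows an F distribution with (|P2| - |P1|, n - |P2|) degrees of
freedom under the null that the PCs do not improve the fit.  Parameter
counts include the intercept, so df1 equals the number of PCs exactly.  For
binary outcomes the nested logistic models are compared by analysis of
deviance: the deviance difference follows a chi-square distribution with
|P2| - |P1| degrees of freedom (equivalently, a likelihood-ratio test).

The module is organised statsmodels-style: :class:`GeneAssociation` is the
model object, ``fit()`` returns an :class:`AssociationResult` carrying the
statistic, degrees of freedom, p-value and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

#: Logistic-regression controls: IRLS iteration cap, relative deviance
#: tolerance, and the coefficient magnitude (logit scale) beyond which the
#: fit is flagged as separated.
LOGISTIC_MAX_ITER = 25
LOGISTIC_TOL = 1e-8
SEPARATION_COEF_LIMIT = 30.0

DEFAULT_MIN_CASES = 50


@dataclass
class PhenotypeDefinition:
    """A named outcome: continuous, or binary coded 0/1 (missing allowed)."""

    name: str
    kind: str
    values: pd.Series

    def __post_init__(self) -> None:
        if self.kind not in {"continuous", "binary"}:
            raise ValueError(f"{self.name}: kind must be continuous or binary")
        self.values = pd.Series(self.values, dtype=float)
        obs = self.values.dropna()
        if obs.nunique() < 2:
            raise ValueError(f"{self.name}: degenerate phenotype "
                             "(fewer than 2 distinct values)")
        if self.kind == "binary" and not set(obs.unique()) <= {0.0, 1.0}:
            raise ValueError(f"{self.name}: binary values must be 0/1")


@dataclass
class CovariateSet:
    """Per-sample covariates (e.g. age, sex, genome-wide PCs)."""

    data: pd.DataFrame
    add_intercept: bool = True

    def __post_init__(self) -> None:
        self.data = pd.DataFrame(self.data, dtype=float)

    def design(self, index: pd.Index, drop: tuple[str, ...] = ()) -> pd.DataFrame:
        cols = [c for c in self.data.columns if c not in drop]
        X = self.data.loc[index, cols].copy()
        if self.add_intercept:
            X.insert(0, "const", 1.0)
        return X

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class AssociationResult:
    """Result of one gene x phenotype nested-model test."""

    gene_id: str
    phenotype_name: str
    test: str                      # "f_test" or "deviance"
    statistic: float
    df1: int
    df2: int | None                # residual df (continuous only)
    n: int
    n_pcs: int
    p: float
    converged: bool = True
    stratum: str = "combined"

    def to_dict(self) -> dict:
        return {
            "gene": self.gene_id,
            "phenotype": self.phenotype_name,
            "stratum": self.stratum,
            "test": self.test,
            "statistic": self.statistic,
            "df1": self.df1,
            "df2": self.df2,
            "n": self.n,
            "n_pcs": self.n_pcs,
            "p": self.p,
            "converged": self.converged,
        }

    def summary(self) -> str:
        stat_name = "F" if self.test == "f_test" else "chi2"
        df = (f"df = ({self.df1}, {self.df2})" if self.df2 is not None
              else f"df = {self.df1}")
        lines = [
            f"Gene-based association: {self.gene_id} ~ {self.phenotype_name}"
            f" [{self.stratum}]",
            f"  test        : {self.test}",
            f"  {stat_name:<12}: {self.statistic:.6g}  ({df})",
            f"  n           : {self.n}   PCs: {self.n_pcs}",
            f"  p-value     : {self.p:.4g}",
            f"  converged   : {self.converged}",
        ]
        return "\n".join(lines)


def f_statistic(
    rss1: float, rss2: float, p1: int, p2: int, n: int
) -> tuple[float, int, int]:
    """Nested-model F statistic from residual sums of squares.

    ``rss1``/``p1`` belong to the null model, ``rss2``/``p2`` to the full
    model (parameter counts include the intercept).  Returns
    ``(F, df1, df2)`` with df1 = p2 - p1 and df2 = n - p2.  A perfect full
    fit (rss2 = 0) yields ``F = inf``.
    """
    if rss1 < 0 or rss2 < 0:
        raise ValueError("residual sums of squares must be >= 0")
    if not p1 < p2:
        raise ValueError("the full model must have more parameters (p1 < p2)")
    if p2 >= n:
        raise ValueError("saturated model: p2 >= n")
    df1, df2 = p2 - p1, n - p2
    if rss2 == 0.0:
        return math.inf, df1, df2
    F = ((rss1 - rss2) / df1) / (rss2 / df2)
    return F, df1, df2


def _fit_logistic(y: np.ndarray, X: np.ndarray):
    """IRLS logistic fit returning (results | None, converged flag).

    Separation — detected by statsmodels or by a coefficient exceeding
    ``SEPARATION_COEF_LIMIT`` on the logit scale — marks the fit
    non-converged instead of aborting a scan.
    """
    import warnings

    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=LOGISTIC_MAX_ITER, tol=LOGISTIC_TOL)
            fit.deviance  # force lazy evaluation inside the filter
    except PerfectSeparationError:
        return None, False
    converged = bool(getattr(fit, "converged", True))
    if not np.all(np.isfinite(fit.params)) or \
            np.abs(fit.params).max() > SEPARATION_COEF_LIMIT:
        converged = False
    return fit, converged


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify columns that do not increase rank
        bad: list[str] = []
        r = 0
        kept: list[int] = []
        for j, name in enumerate(X.columns):
            sub = arr[:, kept + [j]]
            if np.linalg.matrix_rank(sub) > r:
                kept.append(j)
                r += 1
            else:
                bad.append(str(name))
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


class GeneAssociation:
    """Nested-model association test of one gene against one phenotype.

    Parameters
    ----------
    scores : DataFrame (samples x k)
        Gene PC scores, indexed by sample id, one column per PC.
    phenotype : PhenotypeDefinition
    covariates : CovariateSet
    gene_id : str
    """

    def __init__(
        self,
        scores: pd.DataFrame,
        phenotype: PhenotypeDefinition,
        covariates: CovariateSet,
        gene_id: str = "gene",
    ) -> None:
        self.scores = pd.DataFrame(scores, dtype=float)
        self.phenotype = phenotype
        self.covariates = covariates
        self.gene_id = gene_id

    @classmethod
    def from_gene_pcs(cls, pcs, phenotype, covariates) -> "GeneAssociation":
        scores = pd.DataFrame(
            pcs.scores, index=pd.Index(pcs.sample_ids, name="sample_id"),
            columns=[f"PC{i + 1}" for i in range(pcs.k)],
        )
        return cls(scores, phenotype, covariates, gene_id=pcs.gene_id)

    # -- alignment --------------------------------------------------------
    def _complete_cases(
        self, drop_covariates: tuple[str, ...] = ()
    ) -> tuple[pd.Index, pd.Series]:
        y = self.phenotype.values
        idx = self.scores.index.intersection(y.index)
        idx = idx.intersection(self.covariates.data.index)
        y = y.loc[idx]
        cov = self.covariates.data.loc[
            idx, [c for c in self.covariates.columns if c not in drop_covariates]
        ]
        ok = y.notna() & self.scores.loc[idx].notna().all(axis=1)
        if len(cov.columns):
            ok &= cov.notna().all(axis=1)
        return idx[ok], y[ok]

    def fit(self, drop_covariates: tuple[str, ...] = ()) -> AssociationResult:
        if self.phenotype.kind == "continuous":
            return self._fit_continuous(drop_covariates)
        return self._fit_binary(drop_covariates)

    def _designs(
        self, idx: pd.Index, drop: tuple[str, ...]
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        X0 = self.covariates.design(idx, drop=drop)
        X1 = pd.concat([X0, self.scores.loc[idx]], axis=1)
        _check_rank(X1)
        return X0, X1

    def _fit_continuous(self, drop: tuple[str, ...]) -> AssociationResult:
        idx, y = self._complete_cases(drop)
        X0, X1 = self._designs(idx, drop)
        n, p2 = X1.shape
        if n < p2 + 1:
            raise ValueError(
                f"{self.gene_id}/{self.phenotype.name}: too few complete "
                f"cases ({n}) for {p2} parameters"
            )
        m0 = sm.OLS(y.to_numpy(), X0.to_numpy()).fit()
        m1 = sm.OLS(y.to_numpy(), X1.to_numpy()).fit()
        rss1, rss2 = float(m0.ssr), float(m1.ssr)
        # guard against roundoff making the nested RSS marginally larger
        rss2 = min(rss2, rss1)
        F, df1, df2 = f_statistic(rss1, rss2, X0.shape[1], p2, n)
        p = float(stats.f.sf(F, df1, df2)) if math.isfinite(F) else 0.0
        return AssociationResult(
            gene_id=self.gene_id, phenotype_name=self.phenotype.name,
            test="f_test", statistic=F, df1=df1, df2=df2, n=n,
            n_pcs=self.scores.shape[1], p=max(p, 0.0) or np.nextafter(0, 1),
            converged=True,
        )

    def _fit_binary(self, drop: tuple[str, ...]) -> AssociationResult:
        idx, y = self._complete_cases(drop)
        if y.nunique() < 2:
            raise ValueError(
                f"{self.gene_id}/{self.phenotype.name}: degenerate phenotype "
                "(single class among complete cases)"
            )
        X0, X1 = self._designs(idx, drop)
        yv = y.to_numpy()
        m0, ok0 = _fit_logistic(yv, X0.to_numpy())
        m1, ok1 = _fit_logistic(yv, X1.to_numpy())
        if m0 is None or m1 is None:
            return AssociationResult(
                gene_id=self.gene_id, phenotype_name=self.phenotype.name,
                test="deviance", statistic=math.nan,
                df1=self.scores.shape[1], df2=None, n=len(idx),
                n_pcs=self.scores.shape[1], p=math.nan, converged=False,
            )
        converged = ok0 and ok1
        statistic = float(m0.deviance - m1.deviance)
        statistic = max(statistic, 0.0)
        k = self.scores.shape[1]
        p = float(stats.chi2.sf(statistic, k)) if converged else math.nan
        return AssociationResult(
            gene_id=self.gene_id, phenotype_name=self.phenotype.name,
            test="deviance", statistic=statistic, df1=k, df2=None,
            n=len(idx), n_pcs=k, p=p, converged=converged,
        )


def test_gene_continuous(
    scores: pd.DataFrame,
    phenotype: PhenotypeDefinition,
    covariates: CovariateSet,
    gene_id: str = "gene",
) -> AssociationResult:
    """F-test of a continuous phenotype on a gene's PC scores."""
    return GeneAssociation(scores, phenotype, covariates, gene_id).fit()


def test_gene_binary(
    scores: pd.DataFrame,
    phenotype: PhenotypeDefinition,
    covariates: CovariateSet,
    gene_id: str = "gene",
) -> AssociationResult:
    """Analysis-of-deviance test of a binary phenotype on PC scores."""
    return GeneAssociation(scores, phenotype, covariates, gene_id).fit()


def run_phewas(
    genes: list,
    phenotypes: list[PhenotypeDefinition],
    covariates: CovariateSet,
    sex_stratum: str = "combined",
    sex_column: str = "sex",
    male_code: float = 1.0,
    min_cases: int = DEFAULT_MIN_CASES,
) -> list[AssociationResult]:
    """Scan every gene against every phenotype.

    ``genes`` is a list of :class:`~pcphewas.pca.GenePCs`.  In the female or
    male stratum the sex covariate is dropped and samples are filtered on
    ``sex_column`` (``male_code`` marks males; every other non-missing value
    is treated as female).  Binary phenotypes with fewer than ``min_cases``
    cases among complete cases are skipped with a logged reason.
    """
    if sex_stratum not in {"combined", "female", "male"}:
        raise ValueError(f"unknown stratum {sex_stratum!r}")
    drop: tuple[str, ...] = ()
    cov = covariates
    if sex_stratum != "combined":
        if sex_column not in covariates.data.columns:
            raise ValueError(f"stratified run needs covariate {sex_column!r}")
        sex = covariates.data[sex_column]
        keep = (sex == male_code) if sex_stratum == "male" else \
               (sex.notna() & (sex != male_code))
        cov = CovariateSet(covariates.data.loc[keep],
                           add_intercept=covariates.add_intercept)
        drop = (sex_column,)

    results: list[AssociationResult] = []
    for pheno in phenotypes:
        if pheno.kind == "binary":
            idx = pheno.values.index.intersection(cov.data.index)
            n_cases = float(pheno.values.loc[idx].sum())
            if n_cases < min_cases:
                logger.info("skipping %s in stratum %s: %d cases < %d",
                            pheno.name, sex_stratum, int(n_cases), min_cases)
                continue
        for pcs in genes:
            model = GeneAssociation.from_gene_pcs(pcs, pheno, cov)
            try:
                res = model.fit(drop_covariates=drop)
            except ValueError as exc:
                logger.info("skipping %s x %s: %s", pcs.gene_id, pheno.name, exc)
                continue
            res.stratum = sex_stratum
            results.append(res)
        logger.debug("phenotype %s done (%d genes)", pheno.name, len(genes))
    return results


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabulate association results, one row per gene x phenotype x stratum."""
    return pd.DataFrame([r.to_dict() for r in results])
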