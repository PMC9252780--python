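"""Multiplicity control over association scans.

Implements the Storey q-value procedure (calling all q <= alpha significant
bounds the expected false-discovery proportion by alpha), Bonferroni
correction, the genomic inflation factor lambda (ratio of the median
observed association statistic to its null expectation, computed on 1-df
chi-square transforms of the p-values so genes with different PC counts are
comparable), and QQ-plot coordinates.

q-values can be computed along either browsing axis: per gene (across the
phenotype set) or per phenotype (across the gene set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: Median of the 1-df chi-square distribution, the null expectation in the
#: lambda inflation factor.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # ~0.4549

_PI0_GRID = np.arange(0.05, 0.951, 0.05)
_PI0_EVAL = 0.95


@dataclass
class MultiplicityResult:
    """q-values, Bonferroni-adjusted p-values and inflation diagnostics."""

    p: np.ndarray
    q: np.ndarray
    bonferroni: np.ndarray
    m: int
    pi0: float
    lambda_gc: float
    axis: str = "per_gene"

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.q <= alpha


def _validate_p(p) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        raise ValueError("empty p-value list")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return arr


def estimate_pi0(
    p: np.ndarray,
    grid: np.ndarray = _PI0_GRID,
    eval_at: float = _PI0_EVAL,
) -> float:
    """Estimate the null proportion pi0 with the cubic-smoother method.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed on the grid
    and a cubic polynomial fit is evaluated at ``eval_at``; the estimate is
    clipped to (0, 1].
    """
    m = p.size
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
    coeffs = np.polyfit(grid, pi0_lambda, deg=3)
    pi0 = float(np.polyval(coeffs, eval_at))
    return float(min(max(pi0, 1.0 / m), 1.0))


def qvalues(p, pi0_method: str = "smoother", axis: str = "per_gene") -> MultiplicityResult:
    """Storey q-values for a set of p-values.

    With ``pi0_method="fixed_one"`` (pi0 = 1) the q-values coincide with
    Benjamini-Hochberg adjusted p-values; ``"smoother"`` estimates pi0 from
    the p-value distribution, giving uniformly smaller (more powerful)
    q-values.  q_i = min over p_j >= p_i of pi0 * m * p_j / rank(p_j),
    clipped to (0, 1].
    """
    arr = _validate_p(p)
    m = arr.size
    if pi0_method == "fixed_one":
        pi0 = 1.0
    elif pi0_method == "smoother":
        pi0 = estimate_pi0(arr)
    else:
        raise ValueError(f"unknown pi0_method {pi0_method!r}")

    order = np.argsort(arr, kind="stable")
    ranked = arr[order]
    raw = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return MultiplicityResult(
        p=arr, q=q, bonferroni=bonferroni(arr, m), m=m, pi0=pi0,
        lambda_gc=inflation_lambda(arr), axis=axis,
    )


def bonferroni(p, m: int) -> np.ndarray:
    """Bonferroni correction: min(p * m, 1) elementwise.

    ``m`` is the test count of the browsing axis and may exceed len(p).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    arr = _validate_p(p)
    return np.minimum(arr * m, 1.0)


def inflation_lambda(p) -> float:
    """Genomic inflation factor lambda.

    Each p-value is converted to the equivalent 1-df chi-square statistic;
    lambda is the ratio of their median to the null median (~0.4549).
    lambda near 1 indicates a well-calibrated scan; lambda > 1 is
    characteristic of pleiotropic genes (or residual confounding).
    """
    arr = _validate_p(p)
    chi2 = stats.chi2.isf(arr, df=1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


def qq_points(p) -> np.ndarray:
    """(expected, observed) -log10 p coordinates for a QQ plot.

    Observed p-values are sorted ascending; expected quantiles use the
    (i - 0.5)/m convention.  Returns an array of shape (m, 2).
    """
    arr = _validate_p(p)
    m = arr.size
    # i-th smallest p pairs with expected quantile (i - 0.5)/m; points are
    # returned with the expected coordinate increasing.
    observed = -np.log10(np.sort(arr)[::-1])
    expected = -np.log10((np.arange(m, 0, -1) - 0.5) / m)
    return np.column_stack([expected, observed])
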